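"""Sign-weighted gene signatures and per-patient risk scores.

The signature freezes the discovery-cohort fold changes of a set of genes;
each gene's weight is ``sgn(log2 fc)``: +1 for genes up-regulated in the
discovery contrast, -1 for down-regulated ones.  A patient's risk score is

    s = sum_i w_i * (e_i - mu_i) / tau_i

over signature genes present in the scored cohort, where ``e_i`` is the
patient's log2 expression of gene i and ``mu_i``, ``tau_i`` are the mean and
(sample) standard deviation of that gene across all scored samples.  Because
each standardized gene sums to zero over samples, the cohort mean score is
exactly zero and the median is near zero, so dichotomizing at the median
splits the cohort into score-positive and score-negative halves.

Standardization statistics are always recomputed inside the scored cohort;
discovery-cohort statistics are never carried across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .cohort import ExpressionCohort

__all__ = [
    "Signature",
    "RiskScoreResult",
    "build_signature",
    "score",
    "dichotomize",
    "read_signature",
    "write_signature",
    "ilas_signature",
    "subtype_signature",
    "load_discovery_table",
]


@dataclass
class Signature:
    """An ordered gene list with frozen +/-1 weights and discovery fold changes."""

    genes: list[str]
    weights: pd.Series        # gene -> {+1, -1, 0}
    discovery_fc: pd.Series   # gene -> linear-scale fold change
    source_cohort: str = ""
    n_zero_weight: int = 0    # genes with fc == 1, flagged and never scored

    def __post_init__(self) -> None:
        self.weights = self.weights.reindex(self.genes)
        self.discovery_fc = self.discovery_fc.reindex(self.genes)
        expected = np.sign(np.log2(self.discovery_fc.to_numpy(dtype=float)))
        if not np.array_equal(self.weights.to_numpy(dtype=float), expected):
            raise ValueError("weights must equal sign(log2 discovery_fc)")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def n_positive(self) -> int:
        return int((self.weights == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.weights == -1).sum())

    def scored_genes(self) -> list[str]:
        """Genes carrying a nonzero weight."""
        return [g for g in self.genes if self.weights[g] != 0]


@dataclass
class RiskScoreResult:
    """Per-patient risk scores and (optionally) dichotomized status."""

    scores: pd.Series                 # sample -> s
    gene_stats: pd.DataFrame          # per gene: weight, mu, tau
    status: pd.Series | None = None   # sample -> "positive"/"negative"
    dropped_genes: list[str] = field(default_factory=list)
    cohort_name: str = ""

    @property
    def n_genes_used(self) -> int:
        return len(self.gene_stats)

    @property
    def median(self) -> float:
        return float(self.scores.median())

    def status_indicator(self) -> pd.Series:
        """Status as a 0/1 indicator (1 = positive)."""
        if self.status is None:
            raise ValueError("result is not dichotomized yet")
        return (self.status == "positive").astype(int)


def build_signature(de_table: pd.DataFrame, source_cohort: str = "") -> Signature:
    """Build a sign-weighted signature from a differential-expression table.

    ``de_table`` must be indexed by gene and carry a positive ``fold_change``
    column.  Weight is +1 for fold change > 1, -1 for < 1; genes with fold
    change exactly 1 get weight 0, are flagged with a warning, and are
    excluded from scoring.
    """
    if len(de_table) == 0:
        raise ValueError("cannot build a signature from an empty table")
    fc = de_table["fold_change"].astype(float)
    if (fc <= 0).any():
        bad = fc.index[fc <= 0].tolist()
        raise ValueError(f"non-positive fold changes for {bad}")
    weights = pd.Series(np.sign(np.log2(fc.to_numpy())), index=fc.index)
    n_zero = int((weights == 0).sum())
    if n_zero:
        flagged = weights.index[weights == 0].tolist()
        warnings.warn(
            f"{n_zero} gene(s) with fold change exactly 1 get weight 0 and "
            f"are excluded from scoring: {flagged}",
            UserWarning, stacklevel=2,
        )
    return Signature(
        genes=list(fc.index), weights=weights, discovery_fc=fc,
        source_cohort=source_cohort, n_zero_weight=n_zero,
    )


def score(cohort: ExpressionCohort, sig: Signature) -> RiskScoreResult:
    """Compute the sign-weighted standardized risk score for every sample.

    Signature genes absent from the cohort's platform are dropped (and
    recorded) without rescaling the remaining sum, so scores computed on
    reduced gene sets are comparable only within, not across, cohorts.
    """
    scored = sig.scored_genes()
    present = [g for g in scored if g in cohort.gene_ids]
    dropped = [g for g in scored if g not in cohort.gene_ids]
    if not present:
        raise ValueError(
            f"no signature gene present in cohort {cohort.cohort_name!r}"
        )
    if dropped:
        warnings.warn(
            f"{len(dropped)} signature gene(s) absent from cohort "
            f"{cohort.cohort_name!r}; scoring the remaining {len(present)}",
            UserWarning, stacklevel=2,
        )
    sub = cohort.matrix.loc[present]
    mu = sub.mean(axis=1)
    tau = sub.std(axis=1, ddof=1)
    if (tau == 0).any():
        bad = tau.index[tau == 0][0]
        raise ValueError(f"signature gene {bad!r} has zero variance in cohort")
    w = sig.weights.loc[present]
    z = sub.sub(mu, axis=0).div(tau, axis=0)
    s = z.mul(w, axis=0).sum(axis=0)
    s.name = "score"
    stats = pd.DataFrame({"weight": w, "mu": mu, "tau": tau})
    stats.index.name = "gene"
    return RiskScoreResult(scores=s, gene_stats=stats, dropped_genes=dropped,
                           cohort_name=cohort.cohort_name)


def dichotomize(result: RiskScoreResult) -> RiskScoreResult:
    """Assign positive/negative status by the cohort-median rule.

    A patient is positive iff their score is strictly greater than the
    cohort median; ties at the median are negative.
    """
    if len(result.scores) < 2:
        raise ValueError("need at least 2 patients to dichotomize")
    med = result.scores.median()
    status = pd.Series(
        np.where(result.scores > med, "positive", "negative"),
        index=result.scores.index, name="status",
    )
    return RiskScoreResult(
        scores=result.scores, gene_stats=result.gene_stats, status=status,
        dropped_genes=result.dropped_genes, cohort_name=result.cohort_name,
    )


# ---------------------------------------------------------------------------
# persistence and packaged discovery tables


def write_signature(sig: Signature, path) -> None:
    df = pd.DataFrame(
        {
            "gene": sig.genes,
            "weight": sig.weights.astype(int).to_numpy(),
            "discovery_fc": sig.discovery_fc.to_numpy(),
            "source_cohort": sig.source_cohort,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_signature(path) -> Signature:
    df = pd.read_csv(path, sep="\t")
    fc = pd.Series(df["discovery_fc"].to_numpy(), index=df["gene"])
    source = str(df["source_cohort"].iloc[0]) if len(df) else ""
    sig = build_signature(pd.DataFrame({"fold_change": fc}), source_cohort=source)
    stored = pd.Series(df["weight"].to_numpy(dtype=float), index=df["gene"])
    if not stored.equals(sig.weights.astype(float)):
        raise ValueError("stored weights violate the sign rule")
    return sig


def load_discovery_table(which: str) -> pd.DataFrame:
    """Load a packaged discovery table.

    ``which="ilas"`` is the 37-gene normal-vs-tumor contrast;
    ``which="subtype"`` is the 30-gene adenocarcinoma-vs-squamous contrast.
    Columns: ``fold_change``, ``p_adj``; gene symbols in the index.
    """
    names = {"ilas": "ilas_discovery.tsv", "subtype": "subtype_discovery.tsv"}
    if which not in names:
        raise ValueError(f"unknown table {which!r}; use 'ilas' or 'subtype'")
    ref = resources.files("ionsig.data").joinpath(names[which])
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col="gene")


def ilas_signature() -> Signature:
    """The packaged 37-gene ion-channel lung-adenocarcinoma signature (iLAS)."""
    return build_signature(load_discovery_table("ilas"), source_cohort="TWN")


def subtype_signature() -> Signature:
    """The packaged 30-gene adenocarcinoma-vs-squamous contrast signature."""
    return build_signature(load_discovery_table("subtype"), source_cohort="SWE")
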