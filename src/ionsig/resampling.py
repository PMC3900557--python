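"""Random-signature resampling null for signature/survival association.

The association between a signature and survival is summarized by

    Z = sum over cohorts of the univariate Cox coefficient for the
        dichotomized (positive vs negative) signature status,

and referenced against the same statistic computed for ``B`` random gene
signatures of identical size, sampled without replacement from a gene
universe.  Each random signature is weighted by the same sign rule as the
real one — the sign of the sampled gene's discovery-cohort fold change — so
the null preserves the construction procedure, not just the gene count.
The empirical p-value uses the standard permutation pseudo-count,
``p = (1 + #{Z_null >= Z_obs}) / (B + 1)``, one-sided in the poor-survival
direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ClinicalTable, ExpressionCohort
from .signature import Signature, build_signature, dichotomize, score
from .survival import cox_coef_fast

__all__ = [
    "ResamplingResult",
    "signature_z",
    "null_distribution",
    "empirical_p",
    "non_randomicity_test",
]

#: a scored survival cohort: (expression, clinical, outcome name)
Cohort = tuple[ExpressionCohort, ClinicalTable, str]


@dataclass
class ResamplingResult:
    """Observed Z, the resampled null, and the empirical p-value."""

    z_observed: float
    z_null: np.ndarray
    p_empirical: float
    B: int
    seed: int
    universe_size: int
    weight_rule: str = "sign-of-discovery-fold-change"

    def __post_init__(self) -> None:
        if len(self.z_null) != self.B:
            raise ValueError("z_null length must equal B")
        if not (1.0 / (self.B + 1) <= self.p_empirical <= 1.0):
            raise ValueError("empirical p outside [1/(B+1), 1]")


def _cohort_coef(expr: ExpressionCohort, clin: ClinicalTable, outcome: str,
                 sig: Signature) -> float:
    """score -> dichotomize -> univariate Cox coefficient for status."""
    result = dichotomize(score(expr, sig))
    times, events = clin.outcome(outcome)
    common = result.scores.index.intersection(times.index)
    if len(common) == 0:
        raise ValueError("no overlap between expression and clinical samples")
    status = result.status_indicator().loc[common]
    return cox_coef_fast(times.loc[common], events.loc[common], status)


def signature_z(cohorts: list[Cohort], sig: Signature) -> float:
    """Sum over cohorts of the Cox coefficient for dichotomized status."""
    total = 0.0
    for expr, clin, outcome in cohorts:
        try:
            total += _cohort_coef(expr, clin, outcome, sig)
        except Exception as err:
            name = expr.cohort_name or "<unnamed>"
            raise RuntimeError(
                f"cohort {name!r} failed scoring/fitting: {err}"
            ) from err
    return total


def null_distribution(
    cohorts: list[Cohort],
    discovery_fc: pd.Series,
    size: int,
    B: int,
    seed: int,
    universe=None,
) -> np.ndarray:
    """Z statistics for ``B`` random signatures of ``size`` genes.

    ``discovery_fc`` maps every candidate gene to its discovery-cohort fold
    change (used to assign weights by the sign rule).  ``universe`` defaults
    to all genes in ``discovery_fc``; sampling is uniform without
    replacement and deterministic under ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    discovery_fc = pd.Series(discovery_fc)
    universe = (
        list(discovery_fc.index) if universe is None else list(universe)
    )
    missing = [g for g in universe if g not in discovery_fc.index]
    if missing:
        raise ValueError(
            f"{len(missing)} universe gene(s) lack a discovery fold change"
        )
    if size > len(universe):
        raise ValueError(
            f"signature size {size} exceeds universe size {len(universe)}"
        )
    rng = np.random.default_rng(seed)
    universe_arr = np.asarray(universe, dtype=object)
    z_null = np.empty(B)
    for b in range(B):
        genes = rng.choice(universe_arr, size=size, replace=False)
        table = pd.DataFrame(
            {"fold_change": discovery_fc.loc[genes].to_numpy()},
            index=pd.Index(genes, name="gene"),
        )
        # genes with fc exactly 1 would get weight 0; the sampled universe
        # comes from a continuous screen so this is vanishingly rare
        rand_sig = build_signature(table, source_cohort="random")
        z_null[b] = signature_z(cohorts, rand_sig)
    return z_null


def empirical_p(z_observed: float, z_null) -> float:
    """One-sided pseudo-count empirical p: (1 + #{null >= obs}) / (B + 1)."""
    z_null = np.asarray(z_null, dtype=float)
    if z_null.size < 1:
        raise ValueError("need at least one null draw")
    return float((1 + np.sum(z_null >= z_observed)) / (z_null.size + 1))


def non_randomicity_test(
    cohorts: list[Cohort],
    sig: Signature,
    discovery_fc: pd.Series,
    B: int = 1000,
    seed: int = 0,
    universe=None,
) -> ResamplingResult:
    """Full resampling test: observed Z, B-signature null, empirical p."""
    z_obs = signature_z(cohorts, sig)
    z_null = null_distribution(cohorts, discovery_fc, size=len(sig.scored_genes()),
                               B=B, seed=seed, universe=universe)
    p = empirical_p(z_obs, z_null)
    uni = len(discovery_fc) if universe is None else len(list(universe))
    return ResamplingResult(z_observed=z_obs, z_null=z_null, p_empirical=p,
                            B=B, seed=seed, universe_size=uni)
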