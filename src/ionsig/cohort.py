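"""Cohort containers and file I/O.

Expression matrices are log2-scale, genes in rows and samples in columns,
stored as tab-separated text with a ``gene_id`` header for the first column.
Linear-scale input is not accepted: a single declared scale removes the risk
of silently double-logging data that was already transformed upstream.

Clinical tables are one row per sample.  Survival times may be recorded in
days or months; the unit is declared in a ``#unit:`` comment on the first
line of the file and normalized to days on load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionCohort",
    "ClinicalTable",
    "PresenceCalls",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_pairing",
    "read_presence_calls",
    "filter_present",
    "exclude_sex_chromosomes",
]

DAYS_PER_MONTH = 30.44  # mean Gregorian month

#: clinical columns with a controlled vocabulary
_CATEGORICAL_LEVELS = {
    "gender": {"M", "F"},
    "smoking": {"ever", "never"},
    "myc": {"high", "low"},
    "mutation": {"+", "-"},
    "subtype": {"AC", "SCC"},
}
_TIME_COLS = ("overall_time", "recurrence_time")
_EVENT_COLS = ("overall_event", "recurrence_event")


@dataclass
class ExpressionCohort:
    """A log2 expression matrix (genes x samples) with optional paired design.

    Parameters
    ----------
    matrix
        Genes in rows, samples in columns, float log2 expression. No missing
        values are allowed; duplicated gene or sample identifiers are errors.
    pairing
        Optional map ``patient -> (normal_sample_id, tumor_sample_id)`` for
        paired normal/tumor designs.
    cohort_name
        Free-text label used in messages and output metadata.
    """

    matrix: pd.DataFrame
    pairing: dict[str, tuple[str, str]] | None = None
    cohort_name: str = ""

    def __post_init__(self) -> None:
        idx = self.matrix.index
        cols = self.matrix.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dup}")
        if not all(np.issubdtype(dt, np.number) for dt in self.matrix.dtypes):
            raise ValueError("expression matrix must be numeric")
        if self.matrix.isna().any().any():
            where = np.argwhere(self.matrix.isna().to_numpy())
            g, s = where[0]
            raise ValueError(
                f"missing expression value at gene {idx[g]!r}, sample {cols[s]!r}"
            )
        self.matrix = self.matrix.astype(float)
        if self.pairing is not None:
            samples = set(cols)
            for patient, (normal, tumor) in self.pairing.items():
                for sid in (normal, tumor):
                    if sid not in samples:
                        raise ValueError(
                            f"pairing for patient {patient!r} references "
                            f"unknown sample {sid!r}"
                        )

    @property
    def gene_ids(self) -> pd.Index:
        return self.matrix.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.matrix.columns

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def subset_genes(self, genes) -> "ExpressionCohort":
        """Restrict to the given genes (order preserved, all must exist)."""
        missing = [g for g in genes if g not in self.matrix.index]
        if missing:
            raise KeyError(f"genes not in cohort: {missing}")
        return ExpressionCohort(
            self.matrix.loc[list(genes)], pairing=self.pairing,
            cohort_name=self.cohort_name,
        )


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates and survival outcomes.

    Times are stored in days.  Each covariate column is either present for
    every sample or absent from the table entirely (partially missing
    covariates are rejected so downstream models never silently drop rows).
    """

    data: pd.DataFrame
    cohort_name: str = ""

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dup}")
        for col in _TIME_COLS:
            if col in df.columns:
                t = pd.to_numeric(df[col])
                if (t < 0).any():
                    raise ValueError(f"negative times in column {col!r}")
                df[col] = t.astype(float)
        for col in _EVENT_COLS:
            if col in df.columns:
                e = df[col]
                if not set(pd.unique(e)) <= {0, 1}:
                    raise ValueError(f"events in column {col!r} must be 0/1")
                df[col] = e.astype(int)
        for col, levels in _CATEGORICAL_LEVELS.items():
            if col in df.columns:
                bad = set(df[col].unique()) - levels
                if bad:
                    raise ValueError(
                        f"column {col!r} has values outside {sorted(levels)}: "
                        f"{sorted(map(str, bad))}"
                    )
        if df.isna().any().any():
            partial = df.columns[df.isna().any()].tolist()
            raise ValueError(
                "covariates must be present for all samples or absent for "
                f"the cohort; partially missing: {partial}"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def has(self, column: str) -> bool:
        return column in self.data.columns

    def outcome(self, which: str) -> tuple[pd.Series, pd.Series]:
        """Return (times, events) in days for ``which`` in {overall, recurrence}."""
        if which not in ("overall", "recurrence"):
            raise ValueError(f"unknown outcome {which!r}")
        tcol, ecol = f"{which}_time", f"{which}_event"
        if tcol not in self.data.columns or ecol not in self.data.columns:
            raise ValueError(f"cohort lacks {which} survival columns")
        return self.data[tcol], self.data[ecol]


@dataclass
class PresenceCalls:
    """Boolean detected/not-detected calls with the expression layout."""

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = self.calls.astype(bool)

    def covers(self, cohort: ExpressionCohort) -> bool:
        return cohort.gene_ids.isin(self.calls.index).all() and (
            cohort.sample_ids.isin(self.calls.columns).all()
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path, cohort_name: str = "", pairing_path=None) -> ExpressionCohort:
    """Read a tab-separated log2 expression matrix.

    First column holds gene symbols (header ``gene_id``), remaining columns
    one sample each.  Duplicate gene symbols and non-numeric cells are
    reported as errors with the offending symbol / coordinates.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    idx = raw.index.astype(str)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene symbol(s) in {path}: {dup}")
    try:
        # numpy's parser is correctly rounded, so write->read is exact
        mat = raw.astype(float)
    except (ValueError, TypeError):
        for gene in raw.index:
            for sample in raw.columns:
                try:
                    float(raw.at[gene, sample])
                except (ValueError, TypeError):
                    raise ValueError(
                        f"non-numeric cell at gene {gene!r}, sample "
                        f"{sample!r} in {path}"
                    ) from None
        raise
    mat.index = idx
    pairing = read_pairing(pairing_path) if pairing_path is not None else None
    return ExpressionCohort(mat, pairing=pairing, cohort_name=cohort_name)


def write_expression(cohort: ExpressionCohort, path) -> None:
    """Write a cohort matrix in the format :func:`read_expression` accepts."""
    out = cohort.matrix.copy()
    out.index.name = "gene_id"
    # repr-based float formatting keeps a read/write round trip exact
    out.to_csv(path, sep="\t", float_format=None)


def read_clinical(path, cohort_name: str = "") -> ClinicalTable:
    """Read a per-sample clinical TSV.

    An optional first line ``#unit: days`` or ``#unit: months`` declares the
    survival-time unit; months are converted to days on load (days is the
    default).
    """
    unit = "days"
    with open(path, "rt", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            decl = first.lstrip("#").strip().lower()
            if decl.startswith("unit:"):
                unit = decl.split(":", 1)[1].strip()
            df = pd.read_csv(fh, sep="\t", index_col=0)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0)
    if unit not in ("days", "months"):
        raise ValueError(f"unknown time unit {unit!r} (use days or months)")
    if unit == "months":
        for col in _TIME_COLS:
            if col in df.columns:
                df[col] = df[col] * DAYS_PER_MONTH
    return ClinicalTable(df, cohort_name=cohort_name)


def write_clinical(table: ClinicalTable, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#unit: days\n")
        out = table.data.copy()
        out.index.name = "sample_id"
        out.to_csv(fh, sep="\t")


def read_pairing(path) -> dict[str, tuple[str, str]]:
    """Read a two-column (normal_sample_id, tumor_sample_id) TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError("pairing file must have exactly two columns")
    return {
        f"patient_{i}": (row.iloc[0], row.iloc[1])
        for i, (_, row) in enumerate(df.iterrows())
    }


def write_pairing(pairing: Mapping[str, tuple[str, str]], path) -> None:
    rows = [{"normal_sample_id": n, "tumor_sample_id": t} for n, t in pairing.values()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_presence_calls(path) -> PresenceCalls:
    """Read a 0/1 detection-call TSV with the expression layout."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not df.isin([0, 1]).all().all():
        raise ValueError("presence calls must be 0/1")
    return PresenceCalls(df)


# ---------------------------------------------------------------------------
# gene-retention filters


def filter_present(
    cohort: ExpressionCohort, calls: PresenceCalls, fraction: float = 2.0 / 3.0
) -> ExpressionCohort:
    """Retain genes detected in at least ``fraction`` of the cohort's samples.

    The comparison is inclusive (a gene detected in exactly ``fraction`` of
    samples is retained), matching the at-least-two-thirds retention rule
    used for microarray present calls. The sample set is unchanged.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not calls.covers(cohort):
        raise ValueError("presence calls do not cover the cohort")
    sub = calls.calls.loc[cohort.gene_ids, cohort.sample_ids]
    detected_frac = sub.mean(axis=1)
    # tolerate float representation of ratios like 2/3
    keep = detected_frac.to_numpy() >= fraction - 1e-12
    return ExpressionCohort(
        cohort.matrix.loc[keep], pairing=cohort.pairing,
        cohort_name=cohort.cohort_name,
    )


def exclude_sex_chromosomes(
    cohort: ExpressionCohort, annotation: Mapping[str, str]
) -> ExpressionCohort:
    """Drop genes annotated to chromosome X or Y.

    Sex-chromosome genes are removed to avoid confounding by patient gender.
    Genes missing from ``annotation`` are retained, each with a warning:
    silently dropping them would hide annotation gaps.
    """
    keep = []
    for gene in cohort.gene_ids:
        chrom = annotation.get(gene)
        if chrom is None:
            warnings.warn(
                f"gene {gene!r} has no chromosome annotation; retained",
                UserWarning,
                stacklevel=2,
            )
            keep.append(gene)
            continue
        norm = str(chrom).removeprefix("chr").upper()
        if norm not in ("X", "Y"):
            keep.append(gene)
    return ExpressionCohort(
        cohort.matrix.loc[keep], pairing=cohort.pairing,
        cohort_name=cohort.cohort_name,
    )
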