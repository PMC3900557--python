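"""Differential expression between paired tissues or two sample groups.

A paired t-test is used for normal-vs-tumor contrasts on matched tissue from
the same patients; Welch's two-sample t-test is used for subtype contrasts.
P-values are adjusted by the Benjamini–Hochberg step-up procedure within the
tested gene family, and fold changes are ratios of geometric means on the
linear scale (i.e. 2 to the difference of log2 group means).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import ExpressionCohort

__all__ = ["paired_t", "two_sample_t", "fold_change", "bh_adjust", "de_screen"]

#: columns of a differential-expression table (gene symbols in the index)
DE_COLUMNS = ["fold_change", "log2_fc", "p_raw", "p_adj", "test"]


def paired_t(tumor, normal) -> tuple[float, float]:
    """Paired t-test on per-pair (tumor - normal) differences.

    Returns the t statistic and two-sided p from the t distribution with
    (n_pairs - 1) degrees of freedom.
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumor.shape != normal.shape or tumor.ndim != 1:
        raise ValueError("tumor and normal must be 1-d of equal length")
    if len(tumor) < 2:
        raise ValueError("need at least 2 pairs")
    diff = tumor - normal
    if np.std(diff, ddof=1) == 0.0:
        raise ValueError("degenerate pairs: zero variance of differences")
    res = stats.ttest_rel(tumor, normal)
    return float(res.statistic), float(res.pvalue)


def two_sample_t(group_a, group_b) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t-test, two-sided."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.std(a, ddof=1) == 0.0 and np.std(b, ddof=1) == 0.0:
        raise ValueError("degenerate groups: both constant")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def fold_change(group_num, group_den) -> float:
    """Linear-scale fold change from log2 group means.

    Equals the ratio of geometric means: ``2 ** (mean(num) - mean(den))``.
    """
    num = np.asarray(group_num, dtype=float)
    den = np.asarray(group_den, dtype=float)
    if num.size == 0 or den.size == 0:
        raise ValueError("groups must be nonempty")
    return float(2.0 ** (num.mean() - den.mean()))


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a nonempty 1-d array")
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_screen(
    cohort: ExpressionCohort,
    design: str,
    alpha: float = 0.001,
    genes=None,
    groups: pd.Series | None = None,
    group_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Screen for differentially expressed genes.

    Parameters
    ----------
    cohort
        Expression cohort. For ``design="paired"`` it must carry a pairing.
    design
        ``"paired"`` (tumor vs matched normal) or ``"two_group"``.
    alpha
        Strict adjusted-p threshold; rows with ``p_adj < alpha`` are kept.
    genes
        Optional gene panel; testing and BH adjustment are restricted to it
        (genes absent from the cohort are ignored with a warning).
    groups
        For two-group designs, per-sample labels with exactly two levels.
    group_order
        ``(numerator_label, denominator_label)`` for the fold change; by
        default the two levels sorted, first over second.

    Returns
    -------
    DataFrame indexed by gene with columns
    ``fold_change, log2_fc, p_raw, p_adj, test``, restricted to significant
    genes and sorted by gene symbol.  The BH family is the set of genes
    actually tested.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    mat = cohort.matrix
    if genes is not None:
        genes = list(genes)
        missing = [g for g in genes if g not in mat.index]
        if missing:
            warnings.warn(
                f"{len(missing)} panel gene(s) absent from cohort; ignored",
                UserWarning, stacklevel=2,
            )
        mat = mat.loc[[g for g in genes if g in mat.index]]

    if design == "paired":
        if cohort.pairing is None:
            raise ValueError("paired design requires a cohort pairing")
        normal_ids = [n for n, _ in cohort.pairing.values()]
        tumor_ids = [t for _, t in cohort.pairing.values()]
        tum = mat[tumor_ids].to_numpy()
        nor = mat[normal_ids].to_numpy()
        diff = tum - nor
        ok = np.std(diff, axis=1, ddof=1) > 0.0
        res = stats.ttest_rel(tum[ok], nor[ok], axis=1)
        log2_fc = diff[ok].mean(axis=1)
        test_name = "paired_t"
    elif design == "two_group":
        if groups is None:
            raise ValueError("two_group design requires group labels")
        groups = groups.reindex(mat.columns)
        if groups.isna().any():
            raise ValueError("group labels missing for some samples")
        levels = sorted(groups.unique())
        if len(levels) != 2:
            raise ValueError(f"need exactly 2 group levels, got {levels}")
        if group_order is None:
            group_order = (levels[0], levels[1])
        num_label, den_label = group_order
        if {num_label, den_label} != set(levels):
            raise ValueError("group_order labels do not match the data")
        a = mat.loc[:, (groups == num_label).to_numpy()].to_numpy()
        b = mat.loc[:, (groups == den_label).to_numpy()].to_numpy()
        ok = ~((np.std(a, axis=1, ddof=1) == 0) & (np.std(b, axis=1, ddof=1) == 0))
        res = stats.ttest_ind(a[ok], b[ok], axis=1, equal_var=False)
        log2_fc = a[ok].mean(axis=1) - b[ok].mean(axis=1)
        test_name = "two_sample_t"
    else:
        raise ValueError(f"unknown design {design!r}")

    tested = mat.index[ok]
    n_skipped = int((~ok).sum())
    if n_skipped:
        warnings.warn(
            f"{n_skipped} gene(s) skipped (degenerate variance)",
            UserWarning, stacklevel=2,
        )
    if len(tested) == 0:
        warnings.warn("no gene passed test preconditions; empty table",
                      UserWarning, stacklevel=2)
        return pd.DataFrame(columns=DE_COLUMNS, index=pd.Index([], name="gene"))

    p_raw = np.asarray(res.pvalue, dtype=float)
    table = pd.DataFrame(
        {
            "fold_change": 2.0 ** log2_fc,
            "log2_fc": log2_fc,
            "p_raw": p_raw,
            "p_adj": bh_adjust(p_raw),
            "test": test_name,
        },
        index=pd.Index(tested, name="gene"),
    )
    return table[table["p_adj"] < alpha].sort_index()
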