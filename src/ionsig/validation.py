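"""Cross-cohort reproducibility and subtype-separation analyses.

Covers the validation toolbox: correlating discovery and validation
differential-expression tables (log10 p and log2 fold change), principal-
component projection of samples on a gene subset, Ward/Manhattan
hierarchical clustering for heatmap layout, and a contingency chi-square
for comparing categorical (e.g. stage) distributions between cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .cohort import ExpressionCohort

__all__ = [
    "CohortComparison",
    "compare_de_tables",
    "pca_project",
    "hier_cluster",
    "categorical_chisq",
]


@dataclass
class CohortComparison:
    """Agreement between two differential-expression tables."""

    pearson_r_logp: float
    pearson_r_logfc: float
    direction_agreement: float
    n_common: int


def compare_de_tables(a: pd.DataFrame, b: pd.DataFrame,
                      p_col: str = "p_raw") -> CohortComparison:
    """Correlate two DE tables over their common genes.

    Pearson r between log10-transformed p-values (column ``p_col``; the raw
    paired/two-sample t-test p by default) and between log2 fold changes,
    plus the fraction of common genes whose fold-change direction matches.
    """
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError(f"need >= 3 common genes, got {len(common)}")
    pa = np.log10(a.loc[common, p_col].astype(float).to_numpy())
    pb = np.log10(b.loc[common, p_col].astype(float).to_numpy())
    fa = a.loc[common, "log2_fc"].astype(float).to_numpy()
    fb = b.loc[common, "log2_fc"].astype(float).to_numpy()
    r_p = float(stats.pearsonr(pa, pb).statistic)
    r_fc = float(stats.pearsonr(fa, fb).statistic)
    agree = float(np.mean(np.sign(fa) == np.sign(fb)))
    return CohortComparison(
        pearson_r_logp=r_p, pearson_r_logfc=r_fc,
        direction_agreement=agree, n_common=len(common),
    )


def pca_project(cohort: ExpressionCohort, genes=None,
                scale: bool = True) -> pd.DataFrame:
    """Project samples onto the first two principal components.

    The sample cloud is restricted to ``genes`` (all cohort genes by
    default); each gene is centered and, with ``scale=True``, divided by its
    standard deviation before the decomposition.  Zero-variance genes are
    dropped with a warning.  Component signs follow a fixed convention (the
    largest-magnitude gene loading of each component is positive) so that
    projections are reproducible.

    Returns a DataFrame indexed by sample with columns ``PC1``/``PC2`` and
    the explained variance ratios in ``df.attrs["explained_variance_ratio"]``.
    """
    genes = list(cohort.gene_ids) if genes is None else list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    if cohort.n_samples < 3:
        raise ValueError("need at least 3 samples")
    sub = cohort.matrix.loc[genes]
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).any():
        dropped = sd.index[sd == 0].tolist()
        warnings.warn(f"dropping zero-variance gene(s): {dropped}",
                      UserWarning, stacklevel=2)
        sub = sub.loc[sd > 0]
        sd = sd[sd > 0]
        if len(sub) < 2:
            raise ValueError("fewer than 2 genes with variance")
    X = sub.sub(sub.mean(axis=1), axis=0)
    if scale:
        X = X.div(sd, axis=0)
    # samples as observations, genes as features
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X.T.to_numpy())
    for k in range(coords.shape[1]):
        loading = pca.components_[k]
        if loading[np.argmax(np.abs(loading))] < 0:
            coords[:, k] *= -1
    out = pd.DataFrame(coords, index=cohort.sample_ids, columns=["PC1", "PC2"])
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.copy()
    return out


def hier_cluster(cohort: ExpressionCohort, genes=None) -> dict:
    """Agglomerative clustering with Ward linkage on Manhattan distances.

    Clusters both axes (samples and genes) for heatmap layout.  Returns a
    dict with ``sample_order`` / ``gene_order`` (leaf orders) and the scipy
    linkage matrices ``sample_linkage`` / ``gene_linkage`` (``None`` for a
    degenerate single-item axis, whose order is the identity).
    """
    genes = list(cohort.gene_ids) if genes is None else list(genes)
    sub = cohort.matrix.loc[genes]

    def _axis(data: np.ndarray, labels) -> tuple[list, np.ndarray | None]:
        if data.shape[0] < 2:
            return list(labels), None
        dist = pdist(data, metric="cityblock")
        Z = linkage(dist, method="ward")
        order = leaves_list(Z)
        return [labels[i] for i in order], Z

    sample_order, sample_Z = _axis(sub.to_numpy().T, list(sub.columns))
    gene_order, gene_Z = _axis(sub.to_numpy(), list(sub.index))
    return {
        "sample_order": sample_order,
        "gene_order": gene_order,
        "sample_linkage": sample_Z,
        "gene_linkage": gene_Z,
    }


def cut_clusters(linkage_matrix: np.ndarray, k: int, labels) -> dict:
    """Cut a linkage at ``k`` clusters; returns label -> cluster id."""
    assignment = fcluster(linkage_matrix, t=k, criterion="maxclust")
    return dict(zip(labels, assignment.tolist()))


def categorical_chisq(counts_a, counts_b) -> tuple[float, float]:
    """Classical contingency chi-square comparing two count distributions.

    ``counts_a``/``counts_b`` are per-category counts over the same
    categories (e.g. stage distributions of two cohorts).  No continuity
    correction is applied.
    """
    a = pd.Series(counts_a, dtype=float)
    b = pd.Series(counts_b, dtype=float)
    if set(a.index) != set(b.index):
        raise ValueError("count tables must share the same categories")
    b = b.reindex(a.index)
    table = np.vstack([a.to_numpy(), b.to_numpy()])
    if table.sum() <= 0 or (table.sum(axis=1) <= 0).any():
        raise ValueError("each cohort must have positive total counts")
    if (table.sum(axis=0) <= 0).any():
        raise ValueError("expected count of zero in some category")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)
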