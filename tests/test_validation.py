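"""Cross-cohort comparison, PCA projection, Ward/Manhattan clustering, chi-square."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist, pdist, squareform

import ionsig as isg
from ionsig.validation import cut_clusters


def _de_table(genes, log2_fc, p_raw):
    return pd.DataFrame(
        {"fold_change": 2.0 ** np.asarray(log2_fc), "log2_fc": log2_fc,
         "p_raw": p_raw, "p_adj": p_raw},
        index=pd.Index(genes, name="gene"))


def _cohort(mat, genes=None, samples=None):
    genes = genes or [f"G{i}" for i in range(mat.shape[0])]
    samples = samples or [f"S{j}" for j in range(mat.shape[1])]
    return isg.ExpressionCohort(pd.DataFrame(mat, index=genes, columns=samples))


class TestCompareDETables:
    def test_identity(self):
        a = _de_table(["A", "B", "C", "D"], [1.0, -0.5, 2.0, -1.5],
                      [0.01, 0.2, 0.001, 0.05])
        cmp_ = isg.compare_de_tables(a, a)
        assert cmp_.pearson_r_logp == pytest.approx(1.0)
        assert cmp_.pearson_r_logfc == pytest.approx(1.0)
        assert cmp_.direction_agreement == 1.0
        assert cmp_.n_common == 4

    def test_negated_fold_changes(self):
        a = _de_table(["A", "B", "C"], [1.0, -0.5, 2.0], [0.01, 0.2, 0.001])
        b = _de_table(["A", "B", "C"], [-1.0, 0.5, -2.0], [0.01, 0.2, 0.001])
        cmp_ = isg.compare_de_tables(a, b)
        assert cmp_.pearson_r_logfc == pytest.approx(-1.0)
        assert cmp_.direction_agreement == 0.0

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        a = _de_table([f"G{i}" for i in range(20)], rng.normal(size=20),
                      rng.uniform(1e-6, 1, 20))
        b = _de_table([f"G{i}" for i in range(5, 25)], rng.normal(size=20),
                      rng.uniform(1e-6, 1, 20))
        ab = isg.compare_de_tables(a, b)
        ba = isg.compare_de_tables(b, a)
        assert ab.pearson_r_logp == pytest.approx(ba.pearson_r_logp)
        assert ab.direction_agreement == pytest.approx(ba.direction_agreement)
        assert ab.n_common == ba.n_common == 15

    def test_replicated_screens_agree_on_planted_genes(self):
        base = isg.SimulationConfig(n_genes=200, n_de=25, n_pairs=50,
                                    log2fc_range=(1.0, 2.0), sigma_gene=0.5,
                                    seed=5)
        # two cohorts drawn around the same planted truth (different noise)
        c1, truth = isg.generate_paired(base)
        rng = np.random.default_rng(99)
        noise = rng.normal(0, base.sigma_gene, c1.matrix.shape)
        c2 = isg.ExpressionCohort(c1.matrix + noise, pairing=c1.pairing)
        t1 = isg.de_screen(c1, design="paired", alpha=1.0)
        t2 = isg.de_screen(c2, design="paired", alpha=1.0)
        planted = truth.index[truth.planted_log2fc != 0]
        cmp_ = isg.compare_de_tables(t1.loc[planted], t2.loc[planted])
        assert cmp_.direction_agreement >= 0.9
        assert cmp_.pearson_r_logfc > 0.5

    def test_too_few_common_genes(self):
        a = _de_table(["A", "B"], [1.0, 2.0], [0.1, 0.2])
        with pytest.raises(ValueError, match="common genes"):
            isg.compare_de_tables(a, a)


class TestPCAProject:
    def test_separates_planted_subtypes(self):
        cfg = isg.SimulationConfig(n_genes=100, n_de=30, n_pairs=50,
                                   n_group_b=28, log2fc_range=(1.0, 2.0),
                                   sigma_gene=0.7, seed=13)
        cohort, labels, truth = isg.generate_two_subtypes(cfg)
        genes = list(truth.index[truth.planted_log2fc != 0])
        coords = isg.pca_project(cohort, genes=genes)
        # best 1-d threshold on PC1 must separate the groups >= 95%
        pc1 = coords["PC1"].to_numpy()
        y = (labels.to_numpy() == "AC").astype(int)
        best = max(
            max(np.mean((pc1 > thr) == y), np.mean((pc1 <= thr) == y))
            for thr in pc1
        )
        assert best >= 0.95

    def test_duplicating_samples_duplicates_coordinates(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(size=(10, 6))
        c1 = _cohort(mat)
        c2 = _cohort(np.hstack([mat, mat]),
                     samples=[f"S{j}" for j in range(12)])
        a = isg.pca_project(c1)
        b = isg.pca_project(c2)
        assert b.iloc[:6].to_numpy() == pytest.approx(
            b.iloc[6:].to_numpy(), abs=1e-9)
        # same subspace: |correlation| of PC1 across the two fits is 1
        r = np.corrcoef(a["PC1"], b["PC1"].iloc[:6])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_explained_variance_non_increasing(self):
        rng = np.random.default_rng(3)
        coords = isg.pca_project(_cohort(rng.normal(size=(20, 15))))
        ratios = coords.attrs["explained_variance_ratio"]
        assert ratios[0] >= ratios[1]

    def test_sample_order_invariance_up_to_sign(self):
        rng = np.random.default_rng(4)
        mat = rng.normal(size=(12, 9))
        c1 = _cohort(mat)
        perm = rng.permutation(9)
        c2 = isg.ExpressionCohort(c1.matrix.iloc[:, perm])
        a = isg.pca_project(c1)
        b = isg.pca_project(c2).loc[a.index]
        for pc in ("PC1", "PC2"):
            assert (b[pc].to_numpy() == pytest.approx(a[pc].to_numpy(), abs=1e-9)
                    or b[pc].to_numpy() == pytest.approx(-a[pc].to_numpy(),
                                                         abs=1e-9))

    def test_zero_variance_gene_dropped_with_warning(self):
        mat = np.vstack([np.ones(5), np.random.default_rng(1).normal(size=(3, 5))])
        cohort = _cohort(mat)
        with pytest.warns(UserWarning, match="zero-variance"):
            coords = isg.pca_project(cohort)
        assert coords.shape == (5, 2)


def generalized_ward_cost(points, clusters):
    """Within-cluster Ward-style cost on Manhattan distances.

    For each cluster: (1/|c|) * sum over unordered pairs of the squared
    Manhattan distance (reduces to the within-cluster sum of squares when
    the metric is Euclidean).
    """
    total = 0.0
    for members in clusters:
        if len(members) < 2:
            continue
        d = cdist(points[members], points[members], metric="cityblock")
        total += (d ** 2).sum() / (2 * len(members))
    return total


class TestHierCluster:
    def test_recovers_well_separated_clusters(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 0.3, (5, 8))
        b = rng.normal(8, 0.3, (3, 8))
        mat = np.vstack([a, b]).T  # samples in columns
        cohort = _cohort(mat, samples=[f"A{i}" for i in range(5)]
                         + [f"B{i}" for i in range(3)])
        res = isg.hier_cluster(cohort)
        parts = cut_clusters(res["sample_linkage"], 2,
                             list(cohort.sample_ids))
        groups = {}
        for label, cl in parts.items():
            groups.setdefault(cl, set()).add(label[0])
        assert sorted(len(v) for v in groups.values()) == [1, 1]

    def test_three_point_merge_heights_match_lance_williams(self):
        # 1-d points 0, 1, 5 under Manhattan distance
        cohort = _cohort(np.array([[0.0], [1.0], [5.0]]).T,
                         samples=["a", "b", "c"])
        res = isg.hier_cluster(cohort)
        Z = res["sample_linkage"]
        # first merge: the closest pair (a, b) at distance 1; second merge
        # height from the Ward update:
        # sqrt(((1+1)*5^2 + (1+1)*4^2 - 1*1^2) / 3) = sqrt(81/3)
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(np.sqrt((2 * 25 + 2 * 16 - 1) / 3))

    def test_cut_at_two_matches_exhaustive_bipartition(self):
        rng = np.random.default_rng(8)
        pts = np.vstack([rng.normal(0, 0.5, (4, 3)),
                         rng.normal(6, 0.5, (4, 3))])
        labels = [f"P{i}" for i in range(8)]
        cohort = _cohort(pts.T, samples=labels)
        res = isg.hier_cluster(cohort)
        parts = cut_clusters(res["sample_linkage"], 2, labels)
        got = frozenset(
            frozenset(i for i, l in enumerate(labels) if parts[l] == cl)
            for cl in set(parts.values()))
        best_cost, best = np.inf, None
        for r in range(1, 8):
            for combo in itertools.combinations(range(8), r):
                clusters = [list(combo),
                            [i for i in range(8) if i not in combo]]
                cost = generalized_ward_cost(pts, clusters)
                if cost < best_cost:
                    best_cost = cost
                    best = frozenset(frozenset(c) for c in clusters)
        assert got == best

    def test_partition_invariant_to_input_order(self):
        rng = np.random.default_rng(9)
        pts = np.vstack([rng.normal(0, 0.5, (4, 4)),
                         rng.normal(5, 0.5, (4, 4))])
        labels = [f"P{i}" for i in range(8)]
        c1 = _cohort(pts.T, samples=labels)
        perm = rng.permutation(8)
        c2 = isg.ExpressionCohort(c1.matrix.iloc[:, perm])
        p1 = cut_clusters(isg.hier_cluster(c1)["sample_linkage"], 2, labels)
        p2 = cut_clusters(isg.hier_cluster(c2)["sample_linkage"], 2,
                          list(c2.sample_ids))
        part1 = frozenset(frozenset(l for l in labels if p1[l] == c)
                          for c in set(p1.values()))
        part2 = frozenset(frozenset(l for l in labels if p2[l] == c)
                          for c in set(p2.values()))
        assert part1 == part2

    def test_single_item_axis_identity_order(self):
        cohort = _cohort(np.array([[1.0, 2.0, 3.0]]), genes=["G0"])
        res = isg.hier_cluster(cohort)
        assert res["gene_order"] == ["G0"]
        assert res["gene_linkage"] is None


class TestCategoricalChisq:
    def test_proportional_counts_statistic_zero(self):
        stat, p = isg.categorical_chisq({"I": 10, "II": 20, "III": 30},
                                        {"I": 5, "II": 10, "III": 15})
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_by_two_hand_value(self):
        stat, _ = isg.categorical_chisq({"a": 10, "b": 0}, {"a": 0, "b": 10})
        assert stat == pytest.approx(20.0)

    def test_symmetric_in_cohorts(self):
        a, b = {"I": 12, "II": 30, "III": 8}, {"I": 20, "II": 25, "III": 9}
        s1, p1 = isg.categorical_chisq(a, b)
        s2, p2 = isg.categorical_chisq(b, a)
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_mismatched_categories_rejected(self):
        with pytest.raises(ValueError, match="categories"):
            isg.categorical_chisq({"a": 1}, {"b": 1})

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(ValueError):
            isg.categorical_chisq({"a": 0, "b": 5}, {"a": 0, "b": 7})
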