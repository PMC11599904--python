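"""Distances, classical MDS and PERMANOVA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import squareform, pdist

import glucovar as gv
from glucovar.divergence import DistanceMatrix


def _dm(points, metric="euclidean", labels=None):
    return gv.distance_matrix(np.asarray(points, dtype=float), metric=metric, labels=labels)


class TestDistanceMatrix:
    def test_identical_rows_distance_zero(self):
        D = _dm([[1, 2, 3], [1, 2, 3]])
        assert D.d[0, 1] == 0.0

    def test_three_four_five_triangle(self):
        D = _dm([[0, 0], [3, 4]])
        assert D.d[0, 1] == pytest.approx(5.0)

    @pytest.mark.parametrize("metric", ["euclidean", "manhattan", "bray-curtis"])
    def test_matches_double_loop_oracle(self, rng, metric):
        X = rng.random((6, 8))
        D = gv.distance_matrix(X, metric=metric)
        for i in range(6):
            for j in range(6):
                x, y = X[i], X[j]
                if metric == "euclidean":
                    ref = math.sqrt(((x - y) ** 2).sum())
                elif metric == "manhattan":
                    ref = np.abs(x - y).sum()
                else:
                    ref = np.abs(x - y).sum() / (x + y).sum()
                assert D.d[i, j] == pytest.approx(ref, abs=1e-12)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="unknown metric"):
            gv.distance_matrix(np.ones((2, 2)), metric="cosine")

    def test_dosage_distances_pairwise_complete(self):
        dosage = np.array([[0.0, 2.0, np.nan, 1.0], [2.0, 0.0, 1.0, np.nan]])
        gm = gv.GenotypeMatrix(
            dosage=dosage,
            sample_ids=["a", "b"],
            variant_ids=list("wxyz"),
            populations=np.array(["p", "p"], dtype=object),
        )
        D = gv.dosage_distance_matrix(gm)
        # shared features: first two, squared diff 4+4=8, rescaled by 4/2
        assert D.d[0, 1] == pytest.approx(math.sqrt(8 * 4 / 2))


class TestProfileMatrix:
    def test_shape_and_fill(self, small_af_table):
        pops = ["IND-LLA", "IND-NLLA", "AFR", "AMR", "EAS", "EUR", "SAS"]
        variants = sorted(small_af_table["variant"].unique())
        prof = gv.population_profile_matrix(small_af_table, pops, variants)
        assert prof.shape == (7, len(variants))
        assert ((prof.values >= 0) & (prof.values <= 1)).all()

    def test_single_population_row(self, small_af_table):
        prof = gv.population_profile_matrix(small_af_table, ["AFR"], ["var0000"])
        assert prof.shape == (1, 1)

    def test_empty_variant_list_rejected(self, small_af_table):
        with pytest.raises(ValueError):
            gv.population_profile_matrix(small_af_table, ["AFR"], [])

    def test_tsv_round_trip(self, small_af_table, tmp_path):
        pops = ["AFR", "AMR"]
        variants = sorted(small_af_table["variant"].unique())[:10]
        prof = gv.population_profile_matrix(small_af_table, pops, variants)
        path = tmp_path / "prof.tsv"
        prof.to_csv(path, sep="\t")
        back = pd.read_csv(path, sep="\t", index_col=0)
        assert np.allclose(back.values, prof.values)


class TestClassicalMds:
    def test_right_triangle_embeds_exactly(self):
        """3-4-5 distances admit an exact planar configuration."""
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        D = DistanceMatrix(labels=["a", "b", "c"], d=d)
        emb = gv.classical_mds(D, k=2)
        embedded = squareform(pdist(emb.coordinates.values))
        assert np.allclose(embedded, d, atol=1e-9)
        assert np.allclose(emb.coordinates.values.mean(axis=0), 0, atol=1e-9)

    def test_zero_distances_zero_coordinates(self):
        D = DistanceMatrix(labels=list("abc"), d=np.zeros((3, 3)))
        with pytest.warns(UserWarning, match="truncating"):
            emb = gv.classical_mds(D, k=2)
        assert emb.coordinates.size == 0 or np.allclose(emb.coordinates.values, 0)

    def test_euclidean_configurations_have_nonnegative_spectrum(self, rng):
        X = rng.normal(size=(10, 4))
        D = gv.distance_matrix(X)
        emb = gv.classical_mds(D, k=4)
        assert (emb.eigenvalues >= -1e-9 * max(1, emb.eigenvalues.max())).all()
        # recovered pairwise distances reproduce the input
        embedded = squareform(pdist(emb.coordinates.values))
        assert np.allclose(embedded, D.d, atol=1e-8)

    def test_agrees_with_skbio_pcoa_eigenvalues(self, rng):
        skbio = pytest.importorskip("skbio")
        X = rng.normal(size=(8, 3))
        D = gv.distance_matrix(X)
        emb = gv.classical_mds(D, k=3)
        res = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D.d))
        assert np.allclose(
            sorted(emb.eigenvalues[:3])[::-1], res.eigvals.values[:3], atol=1e-8
        )


def _two_cluster_dm(rng, n1=8, n2=8, sep=20.0):
    X = rng.normal(size=(n1 + n2, 3))
    X[n1:] += sep
    return gv.distance_matrix(X), np.array(["a"] * n1 + ["b"] * n2, dtype=object)


class TestPermanova:
    def test_well_separated_clusters(self, rng):
        D, labels = _two_cluster_dm(rng)
        res = gv.permanova(D, labels, n_permutations=199, seed=5)
        assert res.r2 > 0.9
        assert res.p_raw == pytest.approx(1 / 200)

    def test_matches_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        X = rng.normal(size=(14, 4))
        X[7:, 0] += 1.5
        D = gv.distance_matrix(X)
        labels = ["a"] * 7 + ["b"] * 7
        mine = gv.permanova(D, labels, n_permutations=99, seed=1)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(D.d), labels, permutations=999
        )
        assert mine.f_stat == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_three_group_f_matches_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        X = rng.normal(size=(12, 3))
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        D = gv.distance_matrix(X)
        mine = gv.permanova(D, labels, n_permutations=49, seed=1)
        theirs = skbio.stats.distance.permanova(skbio.DistanceMatrix(D.d), labels, permutations=9)
        assert mine.f_stat == pytest.approx(theirs["test statistic"], rel=1e-9)
        assert mine.n_groups == 3

    def test_permutation_p_converges_to_exhaustive_enumeration(self, rng):
        """n=6, two groups of 3: 20 label assignments; p̂ → exhaustive p."""
        X = rng.normal(size=(6, 2))
        X[3:, 0] += 2.0
        D = gv.distance_matrix(X)
        labels = np.array(["a"] * 3 + ["b"] * 3, dtype=object)
        obs = gv.permanova(D, labels, n_permutations=9, seed=0).f_stat

        d2 = D.d**2
        n = 6
        ss_total = d2.sum() / (2 * n)
        f_values = []
        for combo in itertools.combinations(range(6), 3):
            g1 = np.array(combo)
            g2 = np.array([i for i in range(6) if i not in combo])
            ss_w = d2[np.ix_(g1, g1)].sum() / 6 + d2[np.ix_(g2, g2)].sum() / 6
            f_values.append((ss_total - ss_w) / (ss_w / 4))
        exhaustive_p = np.mean([f >= obs - 1e-12 for f in f_values])

        res = gv.permanova(D, labels, n_permutations=19_999, seed=3)
        assert res.p_raw == pytest.approx(exhaustive_p, abs=0.02)

    def test_invariance_to_relabeling_and_scaling(self, rng):
        D, labels = _two_cluster_dm(rng, sep=2.0)
        base = gv.permanova(D, labels, n_permutations=99, seed=7)
        scaled = DistanceMatrix(labels=D.labels, d=3.5 * D.d)
        res_scaled = gv.permanova(scaled, labels, n_permutations=99, seed=7)
        assert res_scaled.f_stat == pytest.approx(base.f_stat, rel=1e-12)
        assert res_scaled.r2 == pytest.approx(base.r2, rel=1e-12)
        assert res_scaled.p_raw == base.p_raw
        perm = rng.permutation(D.n)
        res_rel = gv.permanova(D.subset(perm), labels[perm], n_permutations=99, seed=7)
        assert res_rel.f_stat == pytest.approx(base.f_stat, rel=1e-12)

    def test_r2_complement_identity(self, rng):
        """R² + SS_within/SS_total = 1 to 1e−12."""
        from glucovar.divergence import _permanova_stats

        X = rng.normal(size=(10, 3))
        D = gv.distance_matrix(X)
        labels = np.array(["a"] * 5 + ["b"] * 5, dtype=object)
        d2 = D.d**2
        idx = [np.flatnonzero(labels == g) for g in ("a", "b")]
        _, r2 = _permanova_stats(d2, idx)
        ss_total = d2.sum() / (2 * 10)
        ss_within = sum(d2[np.ix_(g, g)].sum() / (2 * len(g)) for g in idx)
        assert r2 + ss_within / ss_total == pytest.approx(1.0, abs=1e-12)

    def test_fixed_seed_reproducible_and_seeds_vary(self, rng):
        D, labels = _two_cluster_dm(rng, sep=1.0)
        a = gv.permanova(D, labels, n_permutations=199, seed=2)
        b = gv.permanova(D, labels, n_permutations=199, seed=2)
        assert a.p_raw == b.p_raw
        others = {gv.permanova(D, labels, n_permutations=199, seed=s).p_raw for s in range(3, 8)}
        assert len(others) > 1  # Monte-Carlo variation across seeds

    def test_coordinate_anova_oracle(self, rng):
        """Euclidean PERMANOVA F equals the classical trace pseudo-F computed
        directly from coordinate sums of squares."""
        X = rng.normal(size=(9, 2))
        X[4:, :] += 1.0
        D = gv.distance_matrix(X)
        labels = np.array(["a"] * 4 + ["b"] * 5, dtype=object)
        res = gv.permanova(D, labels, n_permutations=9, seed=0)
        grand = X.mean(axis=0)
        ss_t = ((X - grand) ** 2).sum()
        ss_w = sum(
            ((X[labels == g] - X[labels == g].mean(axis=0)) ** 2).sum()
            for g in ("a", "b")
        )
        f_direct = ((ss_t - ss_w) / 1) / (ss_w / 7)
        assert res.f_stat == pytest.approx(f_direct, rel=1e-9)

    def test_degenerate_groupings_rejected(self, rng):
        D, _ = _two_cluster_dm(rng)
        with pytest.raises(ValueError):
            gv.permanova(D, ["a"] * D.n, n_permutations=9)


class TestPairwisePermanova:
    def test_three_populations_three_pairs(self, rng):
        X = rng.normal(size=(15, 3))
        D = gv.distance_matrix(X)
        labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        results = gv.pairwise_permanova(D, labels, n_permutations=99, seed=0)
        assert len(results) == 3
        for r in results:
            assert r.p_adjusted >= r.p_raw - 1e-12
            assert r.n_groups == 2

    def test_identical_populations_not_significant(self, rng):
        X = rng.normal(size=(30, 4))
        D = gv.distance_matrix(X)
        labels = ["a"] * 15 + ["b"] * 15
        results = gv.pairwise_permanova(D, labels, n_permutations=199, seed=1)
        assert results[0].p_adjusted > 0.05

    def test_empty_group_pair_rejected(self, rng):
        X = rng.normal(size=(6, 2))
        D = gv.distance_matrix(X)
        with pytest.raises(ValueError):
            gv.pairwise_permanova(D, ["a"] * 6, pairs=[("a", "b")], n_permutations=9)
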