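import numpy as np
import pandas as pd
import pytest
from helpers import random_ultrametric

from indelssr import (
    DistanceMatrix,
    dice_binary_distance,
    evanno_delta_k,
    individual_freq_profiles,
    kinship,
    nei_distance,
    pca_binary,
    structure_pseudo_lnp,
    upgma,
)


class TestNeiDistance:
    def test_identical_profiles_give_zero(self):
        f = {"x": {"L1": {"a": 0.5, "b": 0.5}}, "y": {"L1": {"a": 0.5, "b": 0.5}}}
        d = nei_distance(f)
        assert d.values[0, 1] == 0.0

    def test_hand_computed_single_locus(self):
        # x=(1,0), y=(0.5,0.5): D = -ln(0.5/sqrt(1*0.5)) = 0.5 ln 2
        f = {"x": {"L1": {"a": 1.0}}, "y": {"L1": {"a": 0.5, "b": 0.5}}}
        assert nei_distance(f).values[0, 1] == pytest.approx(0.5 * np.log(2))

    def test_disjoint_alleles_capped(self, caplog):
        f = {"x": {"L1": {"a": 1.0}}, "y": {"L1": {"b": 1.0}}}
        with caplog.at_level("WARNING", logger="indelssr"):
            d = nei_distance(f)
        assert d.values[0, 1] == 10.0

    def test_locus_duplication_leaves_distance_unchanged(self):
        f1 = {"x": {"L1": {"a": 1.0}}, "y": {"L1": {"a": 0.5, "b": 0.5}}}
        f2 = {
            "x": {"L1": {"a": 1.0}, "L2": {"a": 1.0}},
            "y": {"L1": {"a": 0.5, "b": 0.5}, "L2": {"a": 0.5, "b": 0.5}},
        }
        assert nei_distance(f1).values[0, 1] == pytest.approx(
            nei_distance(f2).values[0, 1]
        )

    def test_band_matrix_profiles(self, toy_band_matrix):
        profiles = individual_freq_profiles(toy_band_matrix)
        assert profiles["i0"]["m1"] == {"b1": 1.0}
        assert profiles["i4"]["m1"] == {"b1": 0.5, "b2": 0.5}


class TestUPGMA:
    def test_hand_agglomeration_three_leaves(self):
        d = DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float),
            "nei1972",
        )
        res = upgma(d)
        tt = res.tree.tip_tip_distances(["A", "B", "C"])
        assert np.allclose(tt.data, [[0, 2, 4], [2, 0, 4], [4, 4, 0]])
        assert res.tree.find("C").length == pytest.approx(2.0)
        assert res.tree.find("A").length == pytest.approx(1.0)
        assert res.merge_heights == [1.0, 2.0]
        assert ";" in res.newick()

    def test_two_leaves(self):
        d = DistanceMatrix(("A", "B"), np.array([[0, 3.0], [3.0, 0]]), "nei1972")
        tree = upgma(d).tree
        assert all(t.length == pytest.approx(1.5) for t in tree.tips())

    def test_exact_recovery_of_random_ultrametric_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            ids, mat = random_ultrametric(rng, n)
            res = upgma(DistanceMatrix(tuple(ids), mat, "nei1972"))
            cophenetic = res.tree.tip_tip_distances(ids)
            assert np.allclose(cophenetic.data, mat, atol=1e-9)

    def test_matches_scipy_average_linkage_heights(self, small_cohort):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        _, cohort = small_cohort
        d = dice_binary_distance(cohort.band_matrix)
        res = upgma(d)
        Z = average(squareform(d.values, checks=False))
        assert np.allclose(sorted(res.merge_heights), sorted(Z[:, 2] / 2), atol=1e-9)

    def test_ultrametric_output(self, small_cohort):
        _, cohort = small_cohort
        d = dice_binary_distance(cohort.band_matrix)
        res = upgma(d)
        depths = {
            t.name: t.accumulate_to_ancestor(res.tree) for t in res.tree.tips()
        }
        vals = list(depths.values())
        assert np.allclose(vals, vals[0], atol=1e-9)

    def test_nan_rejected(self):
        m = np.zeros((2, 2))
        m[0, 1] = m[1, 0] = np.nan
        with pytest.raises(ValueError):
            upgma(DistanceMatrix(("A", "B"), m, "nei1972"))


class TestPCA:
    def test_two_point_clusters_separate_on_pc1(self, toy_band_matrix):
        res = pca_binary(toy_band_matrix, n_components=2)
        coords = dict(zip(res.ids, res.coordinates[:, 0]))
        homs1 = [coords[f"i{k}"] for k in range(4)]
        homs2 = [coords[f"i{k}"] for k in (8, 9)]
        assert np.allclose(homs1, homs1[0])
        assert np.allclose(homs2, homs2[0])
        assert abs(homs1[0] - homs2[0]) > 0

    def test_full_space_distances_equal_centered_distances(self, small_cohort):
        _, cohort = small_cohort
        res = pca_binary(cohort.band_matrix)
        X = cohort.band_matrix.scores.to_numpy().T
        Xc = X - X.mean(axis=0)
        n = X.shape[0]
        for i in range(0, n, 7):
            for j in range(0, n, 11):
                d_pc = np.linalg.norm(res.coordinates[i] - res.coordinates[j])
                d_x = np.linalg.norm(Xc[i] - Xc[j])
                assert d_pc == pytest.approx(d_x, abs=1e-8)

    def test_matches_sklearn(self, small_cohort):
        from sklearn.decomposition import PCA

        _, cohort = small_cohort
        res = pca_binary(cohort.band_matrix, n_components=3)
        X = cohort.band_matrix.scores.to_numpy().T
        sk = PCA(n_components=3).fit_transform(X)
        assert np.allclose(np.abs(res.coordinates), np.abs(sk), atol=1e-8)

    def test_explained_fractions_monotone(self, small_cohort):
        _, cohort = small_cohort
        res = pca_binary(cohort.band_matrix, n_components=5)
        assert np.all(np.diff(res.explained) <= 1e-12)
        assert 0 < res.explained.sum() <= 1 + 1e-9

    def test_zero_variance_rejected(self):
        from indelssr.band_matrix import BandMatrix

        scores = pd.DataFrame(
            [[1.0, 1.0]],
            index=pd.MultiIndex.from_tuples([("m1", "b1")]),
            columns=["i1", "i2"],
        )
        with pytest.raises(ValueError):
            pca_binary(BandMatrix(scores=scores))


class TestEvannoDeltaK:
    def _table(self, means, sd=1.0, reps=10, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {k: rng.normal(mu, sd, size=reps) for k, mu in means.items()}
        )

    def test_linear_lnp_has_no_peak_structure(self):
        t = self._table({k: -1000 + 50 * k for k in range(1, 7)}, sd=0.5)
        res = evanno_delta_k(t)
        assert max(res.delta_k.values()) < 3  # second difference ~ 0

    def test_kink_at_k3_recovered(self):
        means = {1: -5000, 2: -4000, 3: -3200, 4: -3150, 5: -3120, 6: -3100}
        res = evanno_delta_k(self._table(means, sd=5.0, seed=1))
        assert res.optimal_k == 3

    def test_delta_k_invariant_to_constant_shift(self):
        t = self._table({1: -500, 2: -400, 3: -390, 4: -385}, sd=2.0, seed=2)
        a = evanno_delta_k(t)
        b = evanno_delta_k(t + 1234.5)
        for k in a.delta_k:
            assert a.delta_k[k] == pytest.approx(b.delta_k[k])

    def test_k_range_1_to_10_yields_8_interior_values(self):
        t = self._table({k: -1000 + 10 * k for k in range(1, 11)}, sd=1.0)
        assert len(evanno_delta_k(t).delta_k) == 8

    def test_zero_sd_column_excluded(self, caplog):
        t = self._table({1: -500, 2: -400, 3: -390, 4: -385}, sd=1.0, seed=3)
        t[2] = -400.0
        with caplog.at_level("WARNING", logger="indelssr"):
            res = evanno_delta_k(t)
        assert 2 not in res.delta_k

    def test_three_group_cohort_selects_k3(self, small_cohort):
        _, cohort = small_cohort
        lnp = structure_pseudo_lnp(cohort.band_matrix, range(1, 8),
                                   n_replicates=8, seed=4)
        assert evanno_delta_k(lnp).optimal_k == 3


class TestKinship:
    def test_identical_individuals_at_scale_max(self):
        from indelssr.band_matrix import BandMatrix

        rows = {
            ("m1", "b1"): [1, 1, 0], ("m1", "b2"): [0, 0, 1],
            ("m2", "b1"): [1, 1, 1], ("m2", "b2"): [1, 1, 0],
        }
        m = BandMatrix(scores=pd.DataFrame(
            np.array(list(rows.values()), dtype=float),
            index=pd.MultiIndex.from_tuples(rows), columns=["i1", "i2", "i3"],
        ))
        k = kinship(m)
        assert k.values[0, 1] == pytest.approx(1.0)  # i1 == i2
        assert k.values[0, 2] == pytest.approx(0.0)  # min off-diagonal rescaled to 0

    def test_symmetric_unit_diagonal(self, small_cohort):
        _, cohort = small_cohort
        k = kinship(cohort.band_matrix)
        assert np.allclose(k.values, k.values.T)
        assert np.allclose(np.diag(k.values), 1.0)
        assert k.values.min() >= 0

    def test_parent_offspring_exceed_cohort_mean(self):
        rng = np.random.default_rng(9)
        from indelssr.band_matrix import BandMatrix

        n_markers = 60
        rows, idx = [], []
        # two unrelated parents and their child at biallelic markers
        p1 = rng.integers(0, 2, size=(n_markers, 2))
        p2 = rng.integers(0, 2, size=(n_markers, 2))
        child = np.stack([p1[np.arange(n_markers), rng.integers(0, 2, n_markers)],
                          p2[np.arange(n_markers), rng.integers(0, 2, n_markers)]], axis=1)
        stranger = rng.integers(0, 2, size=(n_markers, 2))
        for mi in range(n_markers):
            for allele in (0, 1):
                idx.append((f"m{mi}", f"b{allele}"))
                rows.append([
                    1.0 if allele in g[mi] else 0.0
                    for g in (p1, p2, child, stranger)
                ])
        m = BandMatrix(scores=pd.DataFrame(
            np.array(rows), index=pd.MultiIndex.from_tuples(idx),
            columns=["p1", "p2", "child", "stranger"],
        ))
        k = kinship(m)
        kf = k.to_frame()
        cohort_mean = k.values[~np.eye(4, dtype=bool)].mean()
        assert kf.loc["p1", "child"] > cohort_mean
        assert kf.loc["p2", "child"] > cohort_mean

    def test_ritland_estimator_orders_relatives(self, small_cohort):
        _, cohort = small_cohort
        k = kinship(cohort.band_matrix, estimator="ritland")
        assert np.allclose(k.values, k.values.T)
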