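import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from _oracles import brute_force_medoid
from isc.stats import (
    DistanceMatrix,
    bray_curtis,
    delta_e,
    length_effect_correlation,
    mean_effectiveness,
    medoid,
    nmds,
    pairwise_matrix,
    procrustes,
)
from isc.stats import test_delta_e as delta_e_pvalue


def _dm(points):
    pts = np.asarray(points, float)
    return DistanceMatrix(squareform(pdist(pts)),
                          [f"s{i}" for i in range(len(pts))])


class TestBrayCurtis:
    def test_hand_computed_value(self):
        df = pd.DataFrame({"x": [1, 2, 0], "y": [0, 2, 1]})
        d = bray_curtis(df)
        assert d.matrix[0, 1] == pytest.approx(1 / 3)

    def test_identity_and_disjoint(self):
        df = pd.DataFrame({"x": [1, 2, 0], "y": [1, 2, 0], "z": [0, 0, 5]})
        d = bray_curtis(df)
        assert d.matrix[0, 1] == pytest.approx(0.0)
        assert d.matrix[0, 2] == pytest.approx(1.0)

    def test_all_zero_sample_rejected(self):
        df = pd.DataFrame({"x": [1, 0], "y": [0, 0]})
        with pytest.raises(ValueError, match="y"):
            bray_curtis(df)

    def test_output_is_valid_distance_matrix(self, rng):
        df = pd.DataFrame(rng.integers(0, 50, size=(30, 8)))
        d = bray_curtis(df)  # validation happens in the constructor
        assert d.matrix.shape == (8, 8)


class TestNmds:
    def test_planar_points_embed_with_negligible_stress(self, rng):
        pts = rng.normal(size=(8, 2))
        o = nmds(_dm(pts))
        assert o.stress < 0.01

    def test_deterministic(self, rng):
        pts = rng.normal(size=(10, 2))
        a = nmds(_dm(pts), seed=5)
        b = nmds(_dm(pts), seed=5)
        assert np.array_equal(a.coords, b.coords)

    def test_rank_preserving_transform_leaves_stress(self, rng):
        # squaring all distances preserves their ranks, so the non-metric
        # fit should reach (numerically) the same stress
        pts = rng.normal(size=(4, 2))
        d = _dm(pts)
        squared = DistanceMatrix(d.matrix ** 2, d.ids)
        s1 = nmds(d).stress
        s2 = nmds(squared).stress
        assert abs(s1 - s2) < 1e-3

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            nmds(_dm([[0, 0], [1, 0], [0, 1]]))


class TestProcrustes:
    def test_similarity_transform_gives_zero_m2(self, rng):
        X = rng.normal(size=(15, 2))
        theta = np.deg2rad(37)
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        Y = 3.0 * X @ R.T + np.array([5.0, -2.0])
        res = procrustes(X, Y, permutations=99, seed=0)
        assert res.m2 <= 1e-12
        assert 0 < res.p <= 1

    def test_independent_configurations_fit_poorly(self, rng):
        X = rng.normal(size=(30, 2))
        Y = rng.normal(size=(30, 2))
        res = procrustes(X, Y, permutations=199, seed=1)
        assert res.m2 > 0.5
        assert res.p > 0.05

    def test_symmetry_of_m2(self, rng):
        X = rng.normal(size=(12, 2))
        Y = rng.normal(size=(12, 2))
        a = procrustes(X, Y, permutations=1, seed=0).m2
        b = procrustes(Y, X, permutations=1, seed=0).m2
        assert a == pytest.approx(b, abs=1e-12)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            procrustes(rng.normal(size=(5, 2)), rng.normal(size=(6, 2)))


class TestMedoid:
    def test_collinear_example(self):
        # summed distances: 11, 10, 19 -> middle point wins
        assert medoid([[0, 0], [1, 0], [10, 0]]) == 1

    def test_single_point(self):
        assert medoid([[3.0, 4.0]]) == 0

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            pts = rng.normal(size=(int(rng.integers(1, 25)), 2))
            assert medoid(pts) == brute_force_medoid(pts)


class TestEffectiveness:
    def test_delta_e_examples(self):
        assert delta_e([0, 0], [0, 1], [3, 4]) == pytest.approx(1 - 5)
        assert delta_e([1, 1], [2, 2], [2, 2]) == 0.0
        a, b = [0.3, -0.2], [1.5, 0.4]
        assert delta_e([0, 0], a, b) == pytest.approx(
            -delta_e([0, 0], b, a))

    def test_mean_effectiveness(self):
        assert mean_effectiveness([-4, -2], [0, 0]) == pytest.approx(-3)
        assert mean_effectiveness([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert mean_effectiveness([1, 2], [5, 7]) == pytest.approx(
            -mean_effectiveness([5, 7], [1, 2]))

    def test_test_delta_e_degenerate_and_strong(self):
        assert delta_e_pvalue([0, 0, 0, 0]) == 1.0
        assert delta_e_pvalue([-1, -1.1, -0.9, -1.0, -1.05]) < 0.001

    def test_test_delta_e_matches_t_distribution(self, rng):
        for _ in range(20):
            x = rng.normal(0.2, 1.0, size=int(rng.integers(3, 40)))
            t = x.mean() / (x.std(ddof=1) / np.sqrt(x.size))
            p_ref = 2 * sps.t.sf(abs(t), df=x.size - 1)
            assert delta_e_pvalue(x) == pytest.approx(p_ref, rel=1e-9)


class TestEvaluatePair:
    def _tables(self, rng, n=6):
        from isc.asv import AbundanceTable

        ids = [f"s{i}" for i in range(n)]
        counts = pd.DataFrame(rng.integers(1, 80, size=(10, n)),
                              columns=ids)
        return AbundanceTable(counts), ids

    def test_identical_tables_give_zero_delta_e_in_bc_space(self, rng):
        from isc.stats import evaluate_pair

        pre, ids = self._tables(rng)
        post, _ = self._tables(rng)
        post.counts = pre.counts.copy()
        ev = evaluate_pair(pre, post, permutations=49, seed=0,
                           space="braycurtis")
        assert np.allclose(ev.delta_e.to_numpy(), 0.0)
        assert ev.t_p == 1.0  # degenerate zero-variance path

    def test_groups_fill_in_ebar_and_welch(self, rng):
        from isc.stats import evaluate_pair

        pre, ids = self._tables(rng, n=8)
        post, _ = self._tables(rng, n=8)
        post.counts.columns = pre.counts.columns
        groups = {sid: ("a" if i < 4 else "b") for i, sid in enumerate(ids)}
        ev = evaluate_pair(pre, post, groups, permutations=49, seed=0)
        assert ev.ebar is not None and ev.welch_p is not None
        assert ev.ids == ids
        assert 0 <= ev.m2 <= 1

    def test_unknown_space_rejected(self, rng):
        from isc.stats import evaluate_pair

        pre, _ = self._tables(rng)
        with pytest.raises(ValueError):
            evaluate_pair(pre, pre, space="euclid")


class TestPairwiseMatrix:
    def test_identical_groups(self, rng):
        v = rng.normal(size=20)
        df = pairwise_matrix({"a": v, "b": v.copy()})
        row = df[(df.g1 == "a") & (df.g2 == "b")].iloc[0]
        assert row.ebar == 0.0
        assert row.stars == ""

    def test_shifted_group_is_strongly_significant(self, rng):
        g1 = rng.normal(-1.0, 0.1, size=30)
        g2 = rng.normal(0.0, 0.1, size=30)
        df = pairwise_matrix({"g1": g1, "g2": g2})
        row = df[(df.g1 == "g1") & (df.g2 == "g2")].iloc[0]
        assert row.ebar == pytest.approx(-1.0, abs=0.1)
        assert row.stars == "***"

    def test_antisymmetric_in_ebar(self, rng):
        groups = {g: rng.normal(size=10) for g in "abc"}
        df = pairwise_matrix(groups).set_index(["g1", "g2"])
        for g1 in "abc":
            for g2 in "abc":
                if g1 != g2:
                    assert df.loc[(g1, g2)].ebar == pytest.approx(
                        -df.loc[(g2, g1)].ebar)

    def test_small_group_excluded(self, rng):
        with pytest.warns(UserWarning, match="tiny"):
            df = pairwise_matrix({
                "a": rng.normal(size=10),
                "b": rng.normal(size=10),
                "tiny": [1.0, 2.0],
            })
        assert set(df.g1) == {"a", "b"}


class TestLengthEffectCorrelation:
    def test_constructed_monotone_relation(self):
        lengths = {"s": 400, "n": 420, "l1": 500, "l2": 560, "l3": 620}
        ebar = {("n", "s"): -0.01, ("l1", "s"): -0.2, ("l2", "s"): -0.35,
                ("l3", "s"): -0.5}
        rho, p = length_effect_correlation(lengths, ebar)
        assert rho == pytest.approx(-1.0)

    def test_constant_ebar_is_an_error(self):
        lengths = {"a": 400, "b": 500, "c": 600}
        ebar = {("b", "a"): 0.0, ("c", "a"): 0.0, ("c", "b"): 0.0}
        with pytest.raises(ValueError):
            length_effect_correlation(lengths, ebar)

    def test_permuted_pairing_destroys_correlation(self, rng):
        lengths = {f"g{i}": 400 + 40 * i for i in range(8)}
        names = list(lengths)
        pairs = [(names[j], names[i]) for i in range(8) for j in range(i + 1, 8)]
        ebar = {p: -abs(lengths[p[0]] - lengths[p[1]]) / 100 for p in pairs}
        rho_true, _ = length_effect_correlation(lengths, ebar)
        assert rho_true < -0.9
        rhos = []
        for _ in range(30):
            vals = rng.permutation(list(ebar.values()))
            rho, _ = length_effect_correlation(
                lengths, dict(zip(ebar.keys(), vals)))
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.3
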