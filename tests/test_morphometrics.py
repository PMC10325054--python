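"""Arrangement shuffle test, aperture geometry, fold change, correlations."""

import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from anemowhisk.layout import ArrangementScheme, default_layout
from anemowhisk.morphometrics import (
    MorphometryRecord,
    aperture_angle,
    correlate,
    fold_change_vs_reference,
    mean_within_group_variance,
    select_optimal_arrangement,
    shuffle_arrangement_test,
)


def scheme(groups, name="test"):
    return ArrangementScheme(name=name, groups=groups)


def oracle_shuffle_p(values_list, group_idx_lists, observed):
    """Exhaustive assignment oracle for the shuffle test."""
    null = []
    for perm in permutations(values_list):
        perm = np.asarray(perm)
        vs = [np.var(perm[idx], ddof=1) for idx in group_idx_lists]
        null.append(np.mean(vs))
    null = np.asarray(null)
    return float((null <= observed + 1e-12).mean())


class TestMeanWithinGroupVariance:
    def test_hand_computed(self):
        sch = scheme({"a": "g1", "b": "g1", "c": "g2", "d": "g2"})
        v = mean_within_group_variance({"a": 1, "b": 3, "c": 2, "d": 4}, sch)
        assert v == pytest.approx(2.0)

    def test_constant_values_zero(self):
        sch = scheme({"a": "g1", "b": "g1", "c": "g2", "d": "g2"})
        assert mean_within_group_variance(dict.fromkeys("abcd", 7.0), sch) == 0.0

    def test_single_group_equals_overall_variance(self, rng):
        vals = {f"w{i}": float(v) for i, v in enumerate(rng.normal(size=8))}
        sch = scheme({w: "all" for w in vals} | {"extra": "other"})
        arr = np.array(list(vals.values()))
        assert mean_within_group_variance(vals, sch) == pytest.approx(
            np.var(arr, ddof=1)
        )

    def test_singletons_skipped_and_all_singletons_error(self):
        sch = scheme({"a": "g1", "b": "g1", "c": "solo", "d": "solo2"})
        v = mean_within_group_variance({"a": 0, "b": 2, "c": 100, "d": -5}, sch)
        assert v == pytest.approx(2.0)
        sch2 = scheme({"a": "g1", "b": "g2"})
        with pytest.raises(ValueError):
            mean_within_group_variance({"a": 1, "b": 2}, sch2)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.floats(-100, 100, allow_nan=False), seed=st.integers(0, 500))
    def test_invariance_constant_shift_and_relabeling(self, shift, seed):
        r = np.random.default_rng(seed)
        vals = {f"w{i}": float(v) for i, v in enumerate(r.normal(size=6))}
        g = {"w0": "x", "w1": "x", "w2": "y", "w3": "y", "w4": "y", "w5": "x"}
        base = mean_within_group_variance(vals, scheme(g))
        shifted = mean_within_group_variance(
            {k: v + shift for k, v in vals.items()}, scheme(g)
        )
        relabeled = mean_within_group_variance(
            vals, scheme({k: "G_" + v for k, v in g.items()})
        )
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-9)
        assert relabeled == pytest.approx(base)


class TestShuffleTest:
    def test_constant_values_p_one(self):
        sch = scheme({"a": "g1", "b": "g1", "c": "g2", "d": "g2"})
        res = shuffle_arrangement_test(dict.fromkeys("abcd", 3.0), sch, 200, seed=0)
        assert res.p == 1.0

    def test_exact_enumeration_matches_oracle(self, rng):
        sch = scheme({"a": "g1", "b": "g1", "c": "g2", "d": "g2"})
        for _ in range(5):
            vals = {w: float(v) for w, v in zip("abcd", rng.normal(size=4))}
            res = shuffle_arrangement_test(vals, sch, exact=True)
            arr = [vals[w] for w in vals]
            expected = oracle_shuffle_p(
                arr, [np.array([0, 1]), np.array([2, 3])], res.observed
            )
            assert res.p == pytest.approx(expected, abs=1e-12)
            assert res.n_shuffles == math.factorial(4)

    def test_exact_six_positions_three_groups(self, rng):
        g = {"a": "x", "b": "x", "c": "y", "d": "y", "e": "z", "f": "z"}
        vals = {w: float(v) for w, v in zip("abcdef", rng.normal(size=6))}
        res = shuffle_arrangement_test(vals, scheme(g), exact=True)
        idx = [np.array([0, 1]), np.array([2, 3]), np.array([4, 5])]
        expected = oracle_shuffle_p([vals[w] for w in "abcdef"], idx, res.observed)
        assert res.p == pytest.approx(expected, abs=1e-12)

    def test_monte_carlo_approximates_exact(self, rng):
        g = {"a": "x", "b": "x", "c": "y", "d": "y", "e": "x", "f": "y"}
        vals = {w: float(v) for w, v in zip("abcdef", rng.normal(size=6))}
        exact = shuffle_arrangement_test(vals, scheme(g), exact=True).p
        mc = shuffle_arrangement_test(vals, scheme(g), n_shuffles=20000, seed=5).p
        assert mc == pytest.approx(exact, abs=0.02)

    def test_null_uniformity(self):
        """Under i.i.d. values the test rejects at ~nominal rate."""
        r = np.random.default_rng(11)
        g = {f"w{i}": f"g{i % 3}" for i in range(9)}
        sch = scheme(g)
        rejections = sum(
            shuffle_arrangement_test(
                {w: float(v) for w, v in zip(g, r.normal(size=9))},
                sch,
                n_shuffles=500,
                rng=r,
            ).p
            < 0.05
            for _ in range(200)
        )
        # binomial 99% CI around 0.05, n=200
        assert 2 <= rejections <= 18

    def test_determinism_same_seed(self):
        sch = scheme({"a": "g1", "b": "g1", "c": "g2", "d": "g2", "e": "g1"})
        vals = {"a": 1.0, "b": 4.0, "c": 2.0, "d": 8.0, "e": 3.0}
        r1 = shuffle_arrangement_test(vals, sch, 300, seed=9)
        r2 = shuffle_arrangement_test(vals, sch, 300, seed=9)
        np.testing.assert_array_equal(r1.null_distribution, r2.null_distribution)
        assert r1.p == r2.p


class TestSelectOptimalArrangement:
    def test_row_structured_values_pick_rows(self, layout):
        positions = layout.positions
        vals = {w: float(r * 10) for w, (r, c) in positions.items()}
        best, results = select_optimal_arrangement(
            vals, layout.all_schemes(), n_shuffles=300, seed=1
        )
        assert best.name == "rows"
        assert results["rows"].observed == pytest.approx(0.0)

    def test_semicircle_structured_values_pick_semicircles(self, layout):
        sch = layout.scheme("semicircles_A1")
        level = {g: 7.0 * i for i, g in enumerate(sorted(set(sch.groups.values())))}
        vals = {w: level[g] for w, g in sch.groups.items()}
        best, results = select_optimal_arrangement(
            vals, layout.all_schemes(), n_shuffles=500, seed=2
        )
        assert best.name == "semicircles_A1"
        assert results["semicircles_A1"].p == min(r.p for r in results.values())

    def test_tie_resolves_to_declared_order(self, layout):
        schemes = [layout.scheme("arcs"), layout.scheme("rows")]
        vals = {w: 1.0 for w in layout.whiskers}  # all observed stats are 0
        best, _ = select_optimal_arrangement(vals, schemes, n_shuffles=50, seed=0)
        assert best.name == "arcs"


class TestFoldChange:
    def test_reference_normalizes_to_one(self):
        out = fold_change_vs_reference({"lSO": np.array([2.0, 4.0]), "A1": 6.0})
        assert out["lSO"].mean() == pytest.approx(1.0)
        np.testing.assert_allclose(out["A1"], [2.0])

    def test_scale_invariance(self):
        vals = {"lSO": np.array([2.0, 4.0]), "A1": np.array([1.0, 5.0])}
        base = fold_change_vs_reference(vals)
        scaled = fold_change_vs_reference({k: 7 * v for k, v in vals.items()})
        for k in vals:
            np.testing.assert_allclose(scaled[k], base[k])

    def test_zero_reference_mean_rejected(self):
        with pytest.raises(ValueError):
            fold_change_vs_reference({"lSO": np.array([1.0, -1.0]), "A1": 2.0})


class TestApertureAngle:
    def test_four_cardinal_points(self):
        pts = np.array([[1, 0], [0, 1], [-1, 0], [0, -1]], float)
        assert aperture_angle(pts, np.zeros(2)) == pytest.approx(90.0)

    def test_semicircular_arc(self):
        th = np.linspace(0, np.pi, 50)
        pts = np.column_stack([np.cos(th), np.sin(th)])
        assert aperture_angle(pts, np.zeros(2)) == pytest.approx(180.0, abs=1e-6)

    def test_dense_ring_aperture_vanishes(self):
        th = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        pts = np.column_stack([np.cos(th), np.sin(th)])
        assert aperture_angle(pts, np.zeros(2)) < 0.5

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        rot=st.floats(0, 2 * np.pi, allow_nan=False),
        scale=st.floats(0.01, 50, allow_nan=False),
        seed=st.integers(0, 500),
    )
    def test_rotation_and_scale_invariance(self, rot, scale, seed):
        r = np.random.default_rng(seed)
        th = r.uniform(0, 2 * np.pi, 12)
        pts = np.column_stack([np.cos(th), np.sin(th)]) * r.uniform(0.5, 2, (12, 1))
        base = aperture_angle(pts, np.zeros(2))
        m = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        moved = aperture_angle(scale * pts @ m.T, np.zeros(2))
        assert moved == pytest.approx(base, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            aperture_angle(np.array([[1.0, 0.0]]), np.zeros(2))
        with pytest.raises(ValueError):
            aperture_angle(np.zeros((3, 2)), np.zeros(2))


class TestCorrelate:
    def test_perfect_correlations(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert correlate(a, a)[0] == pytest.approx(1.0)
        assert correlate(a, -a)[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 1.0, 3.0, 5.0])
        r, _ = correlate(a, b)
        expected = np.cov(a, b, ddof=1)[0, 1] / (a.std(ddof=1) * b.std(ddof=1))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_pairwise_complete_and_errors(self):
        a = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        b = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
        r, _ = correlate(a, b)
        assert r == pytest.approx(1.0)
        with pytest.raises(ValueError):
            correlate(np.ones(5), np.arange(5.0))


class TestMorphometryRecord:
    def test_ratio_derived_and_validation(self):
        rec = MorphometryRecord("lSO", length=27.0, base_diameter=90.0)
        assert rec.ratio == pytest.approx(0.3)
        with pytest.raises(ValueError):
            MorphometryRecord("x", length=-1.0, base_diameter=10.0)
        with pytest.raises(ValueError):
            MorphometryRecord("x", length=1.0, base_diameter=10.0, ring_wulst_aperture=400.0)
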