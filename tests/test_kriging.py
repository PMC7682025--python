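import numpy as np
import pytest

from metageo.kriging import (VariogramModel, empirical_semivariogram,
                             fit_variogram, krige_probability,
                             solve_kriging_weights)

# --- independent oracle: a from-scratch dense solve of the augmented
# --- ordinary-kriging system, with its own variogram formulas

ORACLE_GAMMA = {
    "gaussian": lambda d, n, s, r: n + (s - n) * (1 - np.exp(-((d / r) ** 2))),
    "exponential": lambda d, n, s, r: n + (s - n) * (1 - np.exp(-d / r)),
    "spherical": lambda d, n, s, r: n + (s - n) * (
        1.5 * min(d / r, 1.0) - 0.5 * min(d / r, 1.0) ** 3),
}


def oracle_weights(anchors, target, family, nugget, sill, range_):
    gamma = ORACLE_GAMMA[family]
    n = len(anchors)
    A = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            if i == j:
                A[i, j] = nugget
            else:
                d = float(np.hypot(*(anchors[i] - anchors[j])))
                A[i, j] = gamma(d, nugget, sill, range_)
        A[i, n] = 1.0
        A[n, i] = 1.0
    b = np.zeros(n + 1)
    for i in range(n):
        d = float(np.hypot(*(anchors[i] - np.asarray(target))))
        b[i] = gamma(d, nugget, sill, range_) if d > 0 else nugget
    b[n] = 1.0
    sol = np.linalg.solve(A, b)
    return sol[:n], sol[n]


class TestEmpiricalSemivariogram:
    def test_single_pair(self):
        out = empirical_semivariogram(np.array([[0.0, 0.0], [1.0, 0.0]]),
                                      np.array([0.0, 2.0]), n_bins=1)
        assert len(out) == 1
        lag, gamma, count = out[0]
        assert (lag, gamma, count) == (1.0, 2.0, 1)  # 0.5 * (2-0)^2

    def test_constant_values_zero_everywhere(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(size=(8, 2))
        out = empirical_semivariogram(pts, np.full(8, 3.3))
        assert all(g == 0.0 for _, g, _ in out)

    def test_matches_brute_force_pairs(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(size=(10, 2))
        vals = rng.normal(size=10)
        out = empirical_semivariogram(pts, vals, n_bins=4)
        # brute force: enumerate pairs, bin by distance
        pairs = []
        for i in range(10):
            for j in range(i + 1, 10):
                d = float(np.hypot(*(pts[i] - pts[j])))
                pairs.append((d, 0.5 * (vals[i] - vals[j]) ** 2))
        dmax = max(d for d, _ in pairs)
        edges = np.linspace(0, dmax, 5)
        total_pairs = 0
        for lag, gamma, count in out:
            b = min(np.searchsorted(edges[1:], lag, side="left"), 3)
            members = [g for d, g in pairs
                       if (b == 0 or d > edges[b]) and d <= edges[b + 1]]
            assert count == len(members)
            assert gamma == pytest.approx(float(np.mean(members)))
            total_pairs += count
        assert total_pairs == 45

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            empirical_semivariogram(np.zeros((3, 2)), np.arange(3.0))


class TestFitVariogram:
    def test_self_consistent_gaussian_recovery(self):
        truth = VariogramModel("gaussian", nugget=0.1, sill=1.2, range_=2.0)
        lags = np.linspace(0.2, 6.0, 12)
        empirical = [(float(l), float(truth(l)), 30) for l in lags]
        fit = fit_variogram(empirical, family="gaussian")
        assert fit.nugget == pytest.approx(0.1, abs=1e-4)
        assert fit.sill == pytest.approx(1.2, abs=1e-4)
        assert fit.range_ == pytest.approx(2.0, abs=1e-4)

    def test_flat_curve_flagged_degenerate(self):
        empirical = [(0.5, 1.0, 10), (1.0, 1.0, 10), (2.0, 1.0, 10)]
        fit = fit_variogram(empirical, family="gaussian")
        assert fit.degenerate or fit.sill == pytest.approx(fit.nugget, rel=1e-3)

    def test_two_bins_fall_back_to_linear(self):
        with pytest.warns(UserWarning, match="falling back to linear"):
            fit = fit_variogram([(1.0, 0.5, 3), (2.0, 1.0, 3)],
                                family="gaussian")
        assert fit.family == "linear"

    @pytest.mark.parametrize("family", ["gaussian", "exponential", "spherical"])
    def test_monotone_in_distance(self, family):
        model = VariogramModel(family, nugget=0.05, sill=1.0, range_=1.5)
        d = np.linspace(0, 4.5, 200)  # up to 3x range
        gamma = model(d)
        assert np.all(np.diff(gamma) >= -1e-12)


class TestSolveWeights:
    def test_target_at_anchor_is_exact(self):
        model = VariogramModel("gaussian", nugget=0.0, sill=1.0, range_=1.0)
        anchors = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        w, _ = solve_kriging_weights(anchors, anchors[1], model)
        np.testing.assert_allclose(w, [0, 1, 0], atol=1e-9)

    def test_two_equidistant_anchors_split_evenly(self):
        model = VariogramModel("exponential", nugget=0.0, sill=1.0, range_=2.0)
        anchors = np.array([[-1.0, 0.0], [1.0, 0.0]])
        w, _ = solve_kriging_weights(anchors, [0.0, 0.0], model)
        np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-12)

    def test_unit_square_matches_oracle(self):
        model = VariogramModel("gaussian", nugget=0.0, sill=1.0, range_=0.7)
        anchors = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        w, mu = solve_kriging_weights(anchors, [0.5, 0.5], model)
        ow, omu = oracle_weights(anchors, [0.5, 0.5], "gaussian", 0.0, 1.0, 0.7)
        np.testing.assert_allclose(w, ow, atol=1e-10)
        assert mu == pytest.approx(omu, abs=1e-10)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = int(rng.integers(3, 13))
            anchors = rng.uniform(-5, 5, size=(n, 2))
            family = rng.choice(["gaussian", "exponential", "spherical"])
            nugget = float(rng.uniform(0, 0.3))
            sill = float(nugget + rng.uniform(0.2, 2.0))
            range_ = float(rng.uniform(0.5, 5.0))
            model = VariogramModel(family, nugget=nugget, sill=sill,
                                   range_=range_)
            target = rng.uniform(-5, 5, size=2)
            try:
                w, _ = solve_kriging_weights(anchors, target, model)
            except np.linalg.LinAlgError:
                continue  # legitimately ill-conditioned draw
            ow, _ = oracle_weights(anchors, target, family, nugget, sill, range_)
            np.testing.assert_allclose(w, ow, atol=1e-8)
            assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_duplicate_anchors_rejected(self):
        model = VariogramModel("gaussian", nugget=0.0, sill=1.0, range_=1.0)
        with pytest.raises(ValueError, match="pairwise distinct"):
            solve_kriging_weights(np.array([[0, 0], [0, 0]], float),
                                  [1.0, 1.0], model)


class TestKrigeProbability:
    def test_constant_field_reproduced(self):
        model = VariogramModel("spherical", nugget=0.0, sill=1.0, range_=2.0)
        rng = np.random.default_rng(2)
        anchors = rng.uniform(size=(6, 2))
        p, clamped = krige_probability(anchors, np.full(6, 0.37),
                                       [10.0, -3.0], model)
        assert p == pytest.approx(0.37, abs=1e-9)
        assert not clamped

    def test_target_at_anchor_returns_value(self):
        model = VariogramModel("gaussian", nugget=0.0, sill=1.0, range_=1.0)
        anchors = np.array([[0, 0], [2, 0], [0, 2]], float)
        values = np.array([0.2, 0.9, 0.4])
        p, _ = krige_probability(anchors, values, anchors[2], model)
        assert p == pytest.approx(0.4, abs=1e-9)

    def test_out_of_range_clamped_and_flagged(self):
        # gaussian weights can exceed 1 outside the hull; force clamping
        model = VariogramModel("gaussian", nugget=0.0, sill=1.0, range_=2.0)
        anchors = np.array([[0.0, 0.0], [1.0, 0.0], [0.2, 1.0]])
        values = np.array([1.0, 0.0, 1.0])
        found = False
        for x in np.linspace(-4, 4, 30):
            w, _ = solve_kriging_weights(anchors, [x, 0.3], model)
            raw = float(w @ values)
            if raw > 1 or raw < 0:
                p, clamped = krige_probability(anchors, values, [x, 0.3], model)
                assert clamped and (p in (0.0, 1.0))
                found = True
                break
        assert found, "no extrapolating target produced an out-of-range sum"
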