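"""Tropical algebra and geometry primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from tropgrad import core

finite_floats = st.floats(-50, 50, allow_nan=False, allow_infinity=False)


def vectors(min_n=2, max_n=8):
    return st.integers(min_n, max_n).flatmap(
        lambda n: arrays(np.float64, n, elements=finite_floats)
    )


class TestCanonicalize:
    @pytest.mark.parametrize(
        "v, expected",
        [
            ([1, 1, 1], [0, 0, 0]),
            ([3, 0, 0], [2, -1, -1]),
        ],
    )
    def test_examples(self, v, expected):
        np.testing.assert_allclose(core.canonicalize(v), expected)

    @given(vectors())
    def test_sum_zero_and_idempotent(self, v):
        c = core.canonicalize(v)
        assert abs(c.sum()) < 1e-9
        np.testing.assert_allclose(core.canonicalize(c), c, atol=1e-12)
        # same equivalence class: difference is a constant vector
        assert np.ptp(v - c) < 1e-9

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            core.canonicalize([1.0])
        with pytest.raises(ValueError):
            core.canonicalize([1.0, np.nan, 0.0])
        with pytest.raises(ValueError):
            core.canonicalize([1.0, np.inf, 0.0])


class TestMetrics:
    @pytest.mark.parametrize(
        "x, expected",
        [([0, 0, 0], 0.0), ([3, 1, 2], 2.0)],
    )
    def test_norm_examples(self, x, expected):
        assert core.trop_norm(x) == pytest.approx(expected)

    def test_dtr_examples(self):
        assert core.d_tr([0, 0, 0], [1, 0, 0]) == pytest.approx(1.0)
        assert core.d_tr([1, 2, 3], [1, 2, 3]) == 0.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            core.d_tr([0, 0], [0, 0, 0])
        with pytest.raises(ValueError):
            core.d_asym([0, 0], [0, 0, 0])

    def test_asym_examples(self):
        a, b = np.zeros(3), np.array([1.0, 0, 0])
        assert core.d_asym(a, a, "min") == 0.0
        assert core.d_asym(a, a, "max") == 0.0
        assert core.d_asym(a, b, "min") == pytest.approx(1.0)
        assert core.d_asym(a, b, "max") == pytest.approx(2.0)

    def test_ray_invariance_and_metric_identity(self, rng):
        """All metrics are 1-ray invariant and N d_tr = d_min + d_max."""
        for _ in range(1000):
            n = int(rng.integers(2, 9))
            x = rng.uniform(-10, 10, n)
            y = rng.uniform(-10, 10, n)
            c = rng.uniform(-10, 10)
            assert core.trop_norm(x + c) == pytest.approx(core.trop_norm(x))
            assert core.d_tr(x + c, y) == pytest.approx(core.d_tr(x, y))
            for which in ("min", "max"):
                assert core.d_asym(x + c, y, which) == pytest.approx(
                    core.d_asym(x, y, which)
                )
            identity = core.d_asym(x, y, "min") + core.d_asym(x, y, "max")
            assert identity == pytest.approx(n * core.d_tr(x, y), abs=1e-9)

    def test_triangle_inequality_and_symmetry(self, rng):
        for _ in range(1000):
            x, y, z = rng.uniform(-10, 10, (3, 5))
            assert core.d_tr(x, y) == pytest.approx(core.d_tr(y, x))
            assert core.d_tr(x, y) <= core.d_tr(x, z) + core.d_tr(z, y) + 1e-9

    @given(vectors(), st.floats(-10, 10))
    def test_vanishes_exactly_on_equal_classes(self, v, c):
        assert core.d_tr(v, v + c) < 1e-9


class TestSecondExtreme:
    @pytest.mark.parametrize(
        "v, which, expected",
        [
            ([2, 0, 0], "max", 0.0),
            ([2, 2, 0], "max", 2.0),
            ([1, 3, 2], "min", 2.0),
        ],
    )
    def test_examples(self, v, which, expected):
        assert core.second_extreme(v, which) == expected

    def test_too_short(self):
        with pytest.raises(ValueError):
            core.second_extreme([1.0], "max")


class TestHyperplaneDistance:
    @pytest.mark.parametrize(
        "offset, expected",
        [([0, 0, 0], 0.0), ([2, 0, 0], 2.0), ([2, 2, 0], 0.0)],
    )
    def test_examples(self, offset, expected):
        t = np.array([1.0, -2.0, 1.0])
        assert core.hyperplane_distance(t + offset, t) == pytest.approx(expected)

    def test_matches_sampled_min_over_hyperplane(self, rng):
        """d(x, H_t) equals the min distance to sampled hyperplane points.

        Points of H_t are built by forcing a two-way tie in x - t.
        """
        for _ in range(15):
            x = rng.uniform(-5, 5, 3)
            t = rng.uniform(-5, 5, 3)
            best = np.inf
            for i in range(3):
                for j in range(3):
                    if i == j:
                        continue
                    for top in np.linspace(-12, 12, 161):
                        h = t.copy()
                        h[i] += top
                        h[j] += top
                        # remaining coordinate stays below the tied max
                        k = 3 - i - j
                        for low in np.linspace(-12, top, 81):
                            h[k] = t[k] + low
                            best = min(best, core.d_tr(x, h))
            assert core.hyperplane_distance(x, t) == pytest.approx(
                best, abs=0.2
            )


class TestTropCombination:
    def test_single_generator(self):
        x = np.array([1.0, 2.0, -3.0])
        np.testing.assert_allclose(
            core.trop_combination([x], [0.0]), core.canonicalize(x)
        )

    def test_example(self):
        X = [[0, 0, 0], [0, 2, 4]]
        out = core.trop_combination(X, [0.0, -3.0], "max")
        np.testing.assert_allclose(out, core.canonicalize([0, 0, 1]))

    def test_reweighting_invariance(self, rng):
        X = rng.uniform(-3, 3, (3, 4))
        alphas = rng.uniform(-2, 2, 3)
        c = 1.7
        X2 = X.copy()
        X2[1] -= c
        alphas2 = alphas.copy()
        alphas2[1] += c
        np.testing.assert_allclose(
            core.trop_combination(X, alphas),
            core.trop_combination(X2, alphas2),
            atol=1e-12,
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            core.trop_combination([[0, 0, 0]], [0.0, 1.0])


class TestHullProject:
    def test_generator_projects_to_itself(self, rng):
        X = rng.uniform(-3, 3, (3, 4))
        proj = core.hull_project(X[1], X)
        assert proj.distance == pytest.approx(0.0, abs=1e-9)
        assert core.d_tr(proj.projected, X[1]) == pytest.approx(0.0, abs=1e-9)

    def test_lattice_oracle_example(self):
        """Closed-form projection matches brute-force over combinations."""
        X = np.array([[0.0, 0, 0], [0, 2, 4]])
        t_raw = np.array([0.0, 1, 1])
        t = core.canonicalize(t_raw)
        proj = core.hull_project(t, X, "max")
        # lambdas are gauge-dependent; in the raw gauge they are (0, -3)
        raw_lambdas = (t_raw[None, :] - X).min(axis=1)
        np.testing.assert_allclose(raw_lambdas, [0.0, -3.0])
        # the projection itself is gauge-invariant
        np.testing.assert_allclose(
            proj.projected,
            core.trop_combination(X, raw_lambdas, "max"),
            atol=1e-12,
        )
        np.testing.assert_allclose(
            proj.projected, core.canonicalize([0, 0, 1]), atol=1e-12
        )
        assert proj.distance == pytest.approx(1.0)
        # oracle: dense grid over the second weight (first fixed by gauge)
        best = min(
            core.d_tr(t, core.trop_combination(X, [0.0, a2], "max"))
            for a2 in np.linspace(-8, 8, 3201)
        )
        assert proj.distance == pytest.approx(best, abs=1e-2)

    @pytest.mark.parametrize("convention", ["max", "min"])
    def test_projection_optimality(self, rng, convention):
        X = rng.uniform(-3, 3, (3, 4))
        t = rng.uniform(-3, 3, 4)
        proj = core.hull_project(t, X, convention)
        for _ in range(1000):
            alphas = rng.uniform(-6, 6, 3)
            comb = core.trop_combination(X, alphas, convention)
            assert proj.distance <= core.d_tr(t, comb) + 1e-9

    def test_projected_in_hull(self, rng):
        X = rng.uniform(-3, 3, (4, 5))
        t = rng.uniform(-3, 3, 5)
        proj = core.hull_project(t, X)
        again = core.hull_project(proj.projected, X)
        assert again.distance == pytest.approx(0.0, abs=1e-9)


class TestHullDiagnostics:
    def test_zero_at_data(self, rng):
        X = rng.uniform(-3, 3, (4, 5))
        delta, _ = core.hull_diagnostics(X[2], X)
        np.testing.assert_allclose(delta, 0.0, atol=1e-9)

    def test_bounds(self, rng):
        """K delta_j <= Delta_j and hull distance <= max_j delta_j."""
        for _ in range(200):
            K, n = int(rng.integers(1, 6)), int(rng.integers(2, 7))
            X = rng.uniform(-5, 5, (K, n))
            t = rng.uniform(-5, 5, n)
            delta, Delta = core.hull_diagnostics(t, X)
            assert np.all(K * delta <= Delta + 1e-9)
            assert core.hull_project(t, X).distance <= delta.max() + 1e-9


class TestSegment:
    def test_endpoints(self):
        a = core.canonicalize([1.0, 0, 2])
        b = core.canonicalize([0.0, 3, 1])
        np.testing.assert_allclose(core.segment_point(a, b, 100, 0), a, atol=1e-9)
        np.testing.assert_allclose(core.segment_point(a, b, 0, 100), b, atol=1e-9)

    def test_example(self):
        p = core.segment_point([0, 0, 0], [0, 3, 3], 0.0, -1.0)
        np.testing.assert_allclose(p, core.canonicalize([0, 2, 2]))

    def test_points_lie_in_two_point_hull(self, rng):
        a, b = rng.uniform(-4, 4, (2, 5))
        for _ in range(50):
            alpha, beta = rng.uniform(-5, 5, 2)
            p = core.segment_point(a, b, alpha, beta)
            proj = core.hull_project(p, np.array([a, b]), "max")
            assert proj.distance == pytest.approx(0.0, abs=1e-9)


class TestIO:
    def test_roundtrip(self, tmp_path, rng):
        X = core.as_point_set(rng.uniform(-2, 2, (5, 4)))
        path = tmp_path / "pts.csv"
        core.write_point_set(X, path, columns=["a", "b", "c", "d"])
        back = core.read_point_set(path)
        np.testing.assert_allclose(back, X, atol=1e-9)

    def test_headerless(self, tmp_path):
        path = tmp_path / "pts.csv"
        path.write_text("1,2,3\n4,5,6\n")
        X = core.read_point_set(path)
        assert X.shape == (2, 3)
        np.testing.assert_allclose(X.sum(axis=1), 0.0, atol=1e-12)
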