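"""Design generation, response-surface fitting, maximum location and the
maximum-focusing range-adjustment rules."""
import numpy as np
import pytest

from lcmsopt.doe import (
    Design,
    adjust_ranges,
    build_design,
    fit_response_surface,
    locate_maximum,
    n_coefficients,
    run_doe_round,
)
from lcmsopt.model import InfeasibleRangeError, ParameterSpace, ValidationError


def space3(**kw):
    base = dict(
        optimized={"a": (-10.0, 10.0), "b": (0.0, 2.0), "c": (100.0, 200.0)},
        fixed={}, constraints=[], floors={},
    )
    base.update(kw)
    return ParameterSpace(**base)


class TestBuildDesign:
    def test_bbd_k3_structure(self):
        design = build_design(space3())
        assert design.n_rows == 13
        noncenter = [row for row in design.coded if np.any(row != 0)]
        assert len(noncenter) == 12
        for row in noncenter:
            nz = row[row != 0]
            assert len(nz) == 2 and set(np.abs(nz)) == {1.0}
        assert sum(1 for row in design.coded if np.all(row == 0)) == 1

    def test_k4_row_count(self):
        sp = ParameterSpace(optimized={n: (0.0, 1.0) for n in "abcd"})
        assert build_design(sp).n_rows == 25  # 4C2 * 4 + center

    def test_k1_three_evenly_spaced_levels(self):
        sp = ParameterSpace(optimized={"x": (10.0, 30.0)})
        design = build_design(sp)
        assert sorted(s["x"] for s in design.settings) == [10.0, 20.0, 30.0]

    def test_k2_full_factorial(self):
        sp = ParameterSpace(optimized={"x": (0.0, 1.0), "y": (0.0, 1.0)})
        assert build_design(sp).n_rows == 9

    def test_decode_encode_round_trip(self):
        sp = space3()
        design = build_design(sp)
        for row in design.coded:
            np.testing.assert_allclose(sp.encode(sp.decode(row)), row, atol=1e-12)
            decoded = sp.decode(row)
            for name, (lo, hi) in sp.optimized.items():
                assert lo - 1e-9 <= decoded[name] <= hi + 1e-9

    def test_empty_space_rejected(self):
        with pytest.raises(ValidationError):
            build_design(ParameterSpace(optimized={}))


def quad(points, beta0=2.0):
    """y = 2 + x1 - x2^2 on coded points."""
    p = np.atleast_2d(points)
    return beta0 + p[:, 0] - p[:, 1] ** 2


class TestFitResponseSurface:
    def test_recovers_known_quadratic(self):
        design = build_design(space3())
        surface = fit_response_surface(design, quad(design.coded))
        # coefficients: [intercept, a, b, c, ab, ac, bc, a2, b2, c2]
        expected = np.zeros(n_coefficients(3))
        expected[0], expected[1], expected[8] = 2.0, 1.0, -1.0
        np.testing.assert_allclose(surface.coefficients, expected, atol=1e-8)
        assert surface.r_squared == pytest.approx(1.0)

    def test_constant_scores_give_intercept_only(self):
        design = build_design(space3())
        surface = fit_response_surface(design, np.full(design.n_rows, 3.5))
        np.testing.assert_allclose(surface.coefficients[0], 3.5, atol=1e-8)
        np.testing.assert_allclose(surface.coefficients[1:], 0.0, atol=1e-8)

    def test_nan_score_names_the_row(self):
        design = build_design(space3())
        scores = quad(design.coded)
        scores[4] = np.nan
        with pytest.raises(ValidationError, match=r"\[4\]"):
            fit_response_surface(design, scores)


class TestLocateMaximum:
    def test_interior_maximum(self):
        design = build_design(space3())

        def y(p):
            p = np.atleast_2d(p)
            return 1 - (p[:, 0] - 0.2) ** 2 - p[:, 1] ** 2 - p[:, 2] ** 2

        surface = fit_response_surface(design, y(design.coded))
        best = locate_maximum(surface)
        np.testing.assert_allclose(best, [0.2, 0.0, 0.0], atol=0.02)

    def test_monotone_score_hits_bound(self):
        design = build_design(space3())
        surface = fit_response_surface(design, design.coded[:, 0])
        best = locate_maximum(surface)
        assert best[0] == pytest.approx(1.0, abs=1e-9)

    def test_constant_surface_ties_to_center(self):
        design = build_design(space3())
        surface = fit_response_surface(design, np.full(design.n_rows, 1.0))
        np.testing.assert_allclose(locate_maximum(surface), [0.0, 0.0, 0.0])


class TestAdjustRanges:
    def _space(self):
        return ParameterSpace(optimized={"x": (20.0, 50.0)})

    def test_zoom_out_at_bound(self):
        sp = self._space()
        nxt, actions = adjust_ranges(sp, {"x": 50.0}, np.array([1.0]))
        assert actions["x"] == "zoom_out"
        assert nxt.optimized["x"] == (pytest.approx(32.0), pytest.approx(68.0))

    def test_zoom_in_near_center(self):
        sp = self._space()
        nxt, actions = adjust_ranges(sp, {"x": 35.0}, np.array([0.0]))
        assert actions["x"] == "zoom_in"
        assert nxt.optimized["x"] == (pytest.approx(23.0), pytest.approx(47.0))

    def test_keep_width_elsewhere(self):
        sp = self._space()
        nxt, actions = adjust_ranges(sp, {"x": 42.5}, np.array([0.5]))
        assert actions["x"] == "keep"
        assert nxt.optimized["x"] == (pytest.approx(27.5), pytest.approx(57.5))

    def test_floor_clamps_lower_bound(self):
        sp = ParameterSpace(optimized={"x": (1.0, 9.0)}, floors={"x": 0.5})
        nxt, _ = adjust_ranges(sp, {"x": 1.0}, np.array([-1.0]))
        assert nxt.optimized["x"][0] == 0.5

    def test_ordering_violation_is_error_with_suggestion(self):
        sp = ParameterSpace(
            optimized={"lo": (10.0, 30.0), "hi": (18.0, 40.0)},
            constraints=[("lo", "hi")],
        )
        with pytest.raises(InfeasibleRangeError, match="lo"):
            adjust_ranges(sp, {"lo": 30.0, "hi": 18.0}, np.array([1.0, -1.0]))

    def test_zoom_preserves_center_and_scales_width(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            lo, w = rng.uniform(0, 50), rng.uniform(1, 20)
            sp = ParameterSpace(optimized={"x": (lo, lo + w)})
            coded = float(rng.uniform(-1, 1))
            best = sp.decode([coded])["x"]
            nxt, actions = adjust_ranges(sp, {"x": best}, np.array([coded]))
            nlo, nhi = nxt.optimized["x"]
            assert (nlo + nhi) / 2 == pytest.approx(best)
            factor = {"zoom_out": 1.2, "zoom_in": 0.8, "keep": 1.0}[actions["x"]]
            assert nhi - nlo == pytest.approx(w * factor)


class TestRunDoeRound:
    def test_exact_quadratic_round(self):
        sp = space3()

        def evaluate(settings):
            x = sp.encode(settings)
            return float(1 - (x[0] - 0.2) ** 2 - x[1] ** 2 - x[2] ** 2)

        result = run_doe_round(sp, evaluate)
        np.testing.assert_allclose(result.focus.best_coded, [0.2, 0, 0], atol=0.02)
        assert result.focus.actions["b"] == "zoom_in"

    def test_failing_row_excluded_with_warning(self):
        sp = space3()
        calls = {"n": 0}

        def evaluate(settings):
            calls["n"] += 1
            if calls["n"] == 3:
                raise RuntimeError("detector glitch")
            x = sp.encode(settings)
            return float(-np.sum(x**2))

        result = run_doe_round(sp, evaluate)
        assert len(result.errors) == 1
        assert any("failed" in w for w in result.warnings)
        assert np.isnan(result.scores[2])
        assert result.surface is not None

    def test_concurrent_matches_sequential(self):
        sp = space3()

        def evaluate(settings):
            x = sp.encode(settings)
            return float(x[0] - x[1] ** 2 + 0.3 * x[2])

        seq = run_doe_round(sp, evaluate, n_workers=1)
        par = run_doe_round(sp, evaluate, n_workers=4)
        assert seq.scores == par.scores
        np.testing.assert_allclose(seq.focus.best_coded, par.focus.best_coded)

    def test_repeated_rounds_converge_on_quadratic(self):
        """Zoom-in shrinks widths geometrically and the center approaches the
        analytic optimum of an exact quadratic with interior maximum."""
        sp = ParameterSpace(optimized={"x": (0.0, 40.0), "y": (0.0, 40.0), "z": (0.0, 40.0)})
        target = np.array([22.0, 18.0, 21.0])

        def evaluate(settings):
            v = np.array([settings["x"], settings["y"], settings["z"]])
            return float(-np.sum((v - target) ** 2))

        widths = []
        for _ in range(8):
            result = run_doe_round(sp, evaluate)
            widths.append(sp.optimized["x"][1] - sp.optimized["x"][0])
            sp = result.focus.next_space
        center = np.array([0.5 * sum(sp.optimized[n]) for n in ("x", "y", "z")])
        np.testing.assert_allclose(center, target, atol=0.5)
        assert widths[-1] < widths[0] * 0.8**3  # several zoom-in rounds happened
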