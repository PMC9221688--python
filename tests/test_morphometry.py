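"""Tortuosity, bifurcation and fractal-dimension oracles and invariances."""

import numpy as np
import pytest

from retinograph import morphometry as mm


def circle_arc(radius, sweep_rad, n=300, start=0.0):
    t = np.linspace(start, start + sweep_rad, n)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t)])


class TestCurvature:
    def test_straight_segment_zero_curvature(self):
        c = mm.resample_and_curvature(np.array([[0.0, 0.0], [100.0, 0.0]]))
        assert c.arc_length == pytest.approx(100, abs=1e-6)
        assert c.chord_length == pytest.approx(100, abs=1e-6)
        assert np.abs(c.kappa).max() < 1e-6

    def test_semicircle_curvature_matches_inverse_radius(self):
        c = mm.resample_and_curvature(circle_arc(50, np.pi))
        interior = np.abs(c.kappa[2:-2])
        assert np.allclose(interior, 1 / 50, rtol=0.02)

    def test_duplicate_points_rejected(self):
        with pytest.raises(ValueError, match="repeated"):
            mm.resample_and_curvature(np.array([[0, 0], [0, 0], [5, 5]], float))

    def test_uniform_spacing(self):
        c = mm.resample_and_curvature(circle_arc(40, 2.0), spacing=1.0)
        gaps = np.linalg.norm(np.diff(c.points, axis=0), axis=1)
        assert np.ptp(gaps) < 1e-3 * gaps.mean() + 1e-6


class TestTortuosity:
    def test_straight_segment_all_zero(self):
        c = mm.resample_and_curvature(np.array([[0.0, 0.0], [100.0, 0.0]]))
        tv = mm.tortuosity_metrics(c)
        assert tv.tau1 == pytest.approx(1.0, abs=1e-6)
        for name in ("tau2", "tau3", "tau4", "tau5", "tau6", "tau7", "tau8",
                     "tau9", "tau11", "tau12", "tau13", "tau14"):
            assert abs(tv.values[name]) < 1e-6, name

    def test_semicircle_closed_forms(self):
        r = 50.0
        tv = mm.tortuosity_metrics(mm.resample_and_curvature(circle_arc(r, np.pi)))
        assert tv.tau1 == pytest.approx(np.pi / 2, rel=0.01)
        assert tv.tau3 == pytest.approx(np.pi, rel=0.01)      # total curvature
        assert tv.tau5 == pytest.approx(1 / r, rel=0.01)
        assert tv.tau9 == pytest.approx(np.pi, rel=0.01)      # turn-angle sum
        assert tv.tau2 == pytest.approx(tv.tau1 - 1, abs=1e-9)

    @pytest.mark.parametrize("sweep_deg", [10, 45, 90, 180, 270, 350])
    def test_total_curvature_equals_subtended_angle(self, sweep_deg):
        tv = mm.tortuosity_metrics(
            mm.resample_and_curvature(circle_arc(80, np.radians(sweep_deg)))
        )
        assert tv.tau3 == pytest.approx(np.radians(sweep_deg), rel=0.01)

    def test_single_sine_period_has_one_inflection(self):
        # brute-force oracle: signed curvature of a sin(2πx/L) changes sign
        # once in the interior, so the tortuosity coefficients double tau2
        x = np.linspace(0, 200, 400)
        y = 5.0 * np.sin(2 * np.pi * x / 200)
        tv = mm.tortuosity_metrics(mm.resample_and_curvature(np.column_stack([x, y])))
        assert tv.tau12 == pytest.approx(2 * tv.tau2, rel=1e-9)
        assert tv.tau13 == pytest.approx(2 * tv.tau7, rel=1e-9)

    def test_rigid_motion_invariance(self):
        poly = circle_arc(60, 2.2)
        tv0 = mm.tortuosity_metrics(mm.resample_and_curvature(poly)).as_array()
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = poly @ rot.T + np.array([123.4, -56.7])
        tv1 = mm.tortuosity_metrics(mm.resample_and_curvature(moved)).as_array()
        assert np.allclose(tv0, tv1, atol=1e-6, rtol=1e-6)

    def test_scaling_behavior(self):
        """Dimensionless metrics are scale-invariant; total curvature is
        too; the per-length densities scale as 1/length."""
        x = np.linspace(0, 200, 400)
        poly = np.column_stack([x, 8.0 * np.sin(2 * np.pi * x / 200)])
        s = 3.0
        a = mm.tortuosity_metrics(mm.resample_and_curvature(poly)).values
        b = mm.tortuosity_metrics(mm.resample_and_curvature(poly * s)).values
        for name in ("tau1", "tau2", "tau10", "tau12"):
            assert b[name] == pytest.approx(a[name], rel=1e-3), name
        # the turn-angle sum is a polygonal approximation whose refinement
        # changes with the sample count, so its invariance is coarser
        assert b["tau9"] == pytest.approx(a["tau9"], rel=1e-2)
        assert b["tau3"] == pytest.approx(a["tau3"], rel=1e-3)
        # total curvature is scale-free, total squared curvature carries one
        # inverse length, so the per-length densities fall off as 1/s or 1/s²
        for name in ("tau4", "tau5", "tau7", "tau13", "tau14"):
            assert b[name] == pytest.approx(a[name] / s, rel=1e-2), name
        for name in ("tau6", "tau8", "tau11"):
            assert b[name] == pytest.approx(a[name] / s**2, rel=1e-2), name


class TestBifurcation:
    def test_symmetric_junction_arithmetic(self):
        d = np.array([np.cos(np.radians(35)), np.sin(np.radians(35))])
        d2 = np.array([np.cos(np.radians(-35)), np.sin(np.radians(-35))])
        bm = mm.bifurcation_metrics(10, 8, 8, np.array([1.0, 0.0]), d, d2)
        assert bm.alpha == pytest.approx(1.0, abs=1e-9)
        assert bm.lam == pytest.approx(1.0, abs=1e-9)
        assert bm.beta == pytest.approx(1.28, abs=1e-9)       # (64+64)/100
        assert bm.theta == pytest.approx(70.0, abs=1e-9)

    def test_murray_law_symmetric_area_ratio(self):
        d0 = 10.0
        d1 = d0 * 2 ** (-1 / 3)
        bm = mm.bifurcation_metrics(
            d0, d1, d1, np.array([1.0, 0.0]),
            np.array([1.0, 0.5]), np.array([1.0, -0.5]),
        )
        assert bm.beta == pytest.approx(2 ** (1 / 3), abs=1e-9)

    def test_daughter_relabelling(self):
        bm = mm.bifurcation_metrics(10, 4, 9, np.array([1.0, 0.0]),
                                    np.array([1.0, 1.0]), np.array([1.0, -1.0]))
        assert bm.d1 == 9 and bm.d2 == 4
        assert 0 < bm.alpha <= 1 and 0 < bm.lam <= 1
        assert bm.lam1 >= bm.lam2

    def test_theta_decomposition_on_random_junctions(self, rng):
        for _ in range(1000):
            widths = rng.uniform(1, 20, size=3)
            dirs = rng.normal(size=(3, 2))
            bm = mm.bifurcation_metrics(widths[0], widths[1], widths[2], *dirs)
            assert bm.theta == pytest.approx(bm.theta1 + bm.theta2, abs=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            mm.bifurcation_metrics(0, 1, 1, np.ones(2), np.ones(2), np.ones(2))
        with pytest.raises(ValueError):
            mm.bifurcation_metrics(1, 1, 1, np.zeros(2), np.ones(2), np.ones(2))


class TestFractal:
    def test_line_has_dimension_one(self, rng):
        pts = np.column_stack([rng.uniform(0, 1000, 10000), np.full(10000, 200.0)])
        fd = mm.fractal_dimensions(pts, (1024, 1024))
        assert fd.D_B == pytest.approx(1.0, abs=0.05)
        assert fd.D_I == pytest.approx(1.0, abs=0.05)
        assert fd.D_C == pytest.approx(1.0, abs=0.05)

    def test_sierpinski_dimension(self, rng):
        # chaos game; similarity dimension log3/log2 ≈ 1.585
        v = np.array([[0, 0], [600, 0], [300, 519.6]])
        p = np.zeros(2)
        pts = []
        for i in range(20200):
            p = (p + v[rng.integers(0, 3)]) / 2
            if i >= 200:
                pts.append(p.copy())
        fd = mm.fractal_dimensions(np.array(pts), (640, 640))
        assert fd.D_B == pytest.approx(np.log(3) / np.log(2), abs=0.1)

    def test_repeated_point_has_dimension_zero(self):
        pts = np.tile([5.0, 5.0], (200, 1))
        fd = mm.fractal_dimensions(pts, (512, 512))
        assert abs(fd.D_B) < 0.05
        assert abs(fd.D_I) < 0.05
        assert abs(fd.D_C) < 0.05

    def test_rigid_motion_stability(self, rng):
        pts = np.column_stack([rng.uniform(100, 500, 5000), rng.uniform(100, 500, 5000)])
        th = 0.4
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        a = mm.fractal_dimensions(pts, (1024, 1024))
        b = mm.fractal_dimensions(pts @ rot.T + 30.0, (1024, 1024))
        assert abs(a.D_B - b.D_B) < 0.05

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            mm.fractal_dimensions(np.zeros((50, 2)), (512, 512))
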