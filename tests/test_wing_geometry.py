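"""Outline processing: EFD, normalization, power, PCA, regions, unions."""

import numpy as np
import pytest
import shapely
from shapely.geometry import LineString, Point, Polygon

from palaeoflight import wing_geometry as wg
from palaeoflight.synthetic import WingShapeParams, generate_wing_outline

from conftest import smooth_blob


def ellipse(a=1.0, b=1.0, n=300, phase=0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([a * np.cos(t + phase), b * np.sin(t + phase)])


def rot(deg):
    r = np.deg2rad(deg)
    return np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])


class TestEfdForward:
    def test_circle_first_harmonic_carries_all_power(self):
        h = wg.efd_forward(wg.WingOutline(ellipse()), n_harmonics=7)
        assert np.abs(h.coeffs[1:]).max() < 1e-3
        assert wg.harmonic_power(h)[0] == pytest.approx(1.0, abs=1e-6)

    def test_rotation_invariance_of_normalized_coefficients(self):
        ell = ellipse(2.0, 1.0)
        h1 = wg.efd_forward(wg.WingOutline(ell), 7)
        h2 = wg.efd_forward(wg.WingOutline(ell @ rot(37).T), 7)
        assert np.abs(h1.coeffs - h2.coeffs).max() < 1e-6

    def test_square_matches_quadrature_oracle(self):
        """Exact segment formulas vs dense numerical quadrature of the EFD
        integrals on the same resampled polygon."""
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        pts = wg.resample_outline(sq, 300)
        coeffs, _ = wg._efd_coefficients(pts, 10)
        closed = np.vstack([pts, pts[:1]])
        seg = np.diff(closed, axis=0)
        t = np.concatenate([[0], np.cumsum(np.hypot(*seg.T))])
        T = t[-1]
        tt = np.linspace(0, T, 400_001)
        x = np.interp(tt, t, closed[:, 0])
        y = np.interp(tt, t, closed[:, 1])
        for n in range(1, 11):
            cosn = np.cos(2 * np.pi * n * tt / T)
            sinn = np.sin(2 * np.pi * n * tt / T)
            oracle = [2 / T * np.trapezoid(f * g, tt)
                      for f in (x, y) for g in (cosn, sinn)]
            an, bn, cn, dn = oracle[0], oracle[1], oracle[2], oracle[3]
            assert np.allclose(coeffs[n - 1], [an, bn, cn, dn], atol=1e-8)

    def test_invariance_rotation_scale_startpoint(self):
        """Normalized coefficients identical under rigid rotation, uniform
        scaling and starting-point shifts of the input points."""
        rng = np.random.default_rng(7)
        worst = 0.0
        for seed in range(20):
            pts = smooth_blob(seed)
            h0 = wg.efd_forward(wg.WingOutline(pts), 7)
            k = int(rng.integers(1, len(pts)))
            scale = float(rng.uniform(0.2, 5.0))
            moved = (np.roll(pts, k, axis=0) @ rot(rng.uniform(0, 360)).T
                     * scale + rng.uniform(-10, 10, 2))
            h1 = wg.efd_forward(wg.WingOutline(moved), 7)
            worst = max(worst, float(np.abs(h0.coeffs - h1.coeffs).max()))
        assert worst < 1e-6

    def test_aliasing_and_geometry_errors(self):
        with pytest.raises(wg.ParameterError):
            wg.efd_forward(wg.WingOutline(ellipse()), n_harmonics=80,
                           n_points=100)
        bowtie = wg.WingOutline(
            np.array([[0, 0], [1, 1], [1, 0], [0, 1]], float))
        with pytest.raises(wg.GeometryError):
            wg.efd_forward(bowtie, 5)


class TestEfdInverse:
    def test_round_trip_deviation_below_half_percent_of_diameter(self):
        pts = generate_wing_outline(
            WingShapeParams(length=30, aspect=2.2, triangularity=0.5,
                            noise_amp=0.0)).points
        h = wg.efd_forward(wg.WingOutline(pts), 20, normalize=False)
        rec = wg.efd_inverse(h, 400).points
        ref = np.vstack([pts, pts[:1]])
        ls = LineString(ref)
        dev = np.mean([ls.distance(Point(p)) for p in rec])
        diam = pts[:, 0].max() - pts[:, 0].min()
        assert dev / diam < 0.005

    def test_single_harmonic_reconstructs_ellipse(self):
        h = wg.efd_forward(wg.WingOutline(ellipse(2, 1)), 1, normalize=False)
        rec = wg.efd_inverse(h, 200).points
        c = rec.mean(axis=0)
        # an ellipse satisfies a fixed quadratic form; fit residual ~ 0
        x, y = (rec - c).T
        A = np.column_stack([x ** 2, x * y, y ** 2])
        coef, res, *_ = np.linalg.lstsq(A, np.ones_like(x), rcond=None)
        resid = float(res[0]) if res.size else 0.0
        assert resid < 1e-6

    def test_zeroing_higher_harmonics_equals_first_ellipse(self):
        pts = smooth_blob(5)
        h = wg.efd_forward(wg.WingOutline(pts), 10, normalize=False)
        h_trunc = wg.HarmonicSeries(
            np.vstack([h.coeffs[:1], np.zeros((9, 4))]), h.offset)
        h_first = wg.HarmonicSeries(h.coeffs[:1], h.offset)
        a = wg.efd_inverse(h_trunc, 100).points
        b = wg.efd_inverse(h_first, 100).points
        assert np.allclose(a, b, atol=1e-12)


class TestHarmonicPower:
    def test_pure_ellipse_all_power_in_first_harmonic(self):
        # a circle is its own first harmonic under arc-length parameterization
        h = wg.efd_forward(wg.WingOutline(ellipse()), 7, normalize=False)
        assert wg.harmonic_power(h)[0] == pytest.approx(1.0, abs=1e-6)
        # a series that IS a single elliptic harmonic
        pure = wg.HarmonicSeries(np.array([[2.0, 0.0, 0.0, 1.0],
                                           [0.0, 0.0, 0.0, 0.0]]))
        assert wg.harmonic_power(pure)[0] == pytest.approx(1.0, abs=1e-12)

    def test_cumulative_nondecreasing_ends_at_one(self):
        h = wg.efd_forward(wg.WingOutline(smooth_blob(3)), 12)
        cum = wg.harmonic_power(h)
        assert np.all(np.diff(cum) >= -1e-15)
        assert cum[-1] == pytest.approx(1.0, abs=1e-12)

    def test_seven_harmonics_capture_99_percent_on_wings(self):
        rng = np.random.default_rng(0)
        fracs = []
        for i in range(50):
            out = generate_wing_outline(
                WingShapeParams(length=30, aspect=2.0,
                                triangularity=rng.uniform(0, 1)), rng=rng)
            h = wg.efd_forward(out, 21, normalize=False)
            fracs.append(wg.harmonic_power(h)[6])
        assert np.mean(fracs) >= 0.99

    def test_power_conservation_parseval(self):
        """Coefficient power converges to the exact mean squared deviation
        of the (piecewise-linear) signal from its locus."""
        for seed in (1, 4):
            pts = wg.resample_outline(smooth_blob(seed), 200)
            coeffs, (A0, C0) = wg._efd_coefficients(pts, 1000)
            total = 0.5 * np.sum(coeffs ** 2)
            # exact integral of (x-A0)^2+(y-C0)^2 over the closed polyline
            closed = np.vstack([pts, pts[:1]]) - [A0, C0]
            seg = np.diff(closed, axis=0)
            dt = np.hypot(*seg.T)
            p0, p1 = closed[:-1], closed[1:]
            quad = (np.sum(p0 * p0 + p0 * p1 + p1 * p1, axis=1) / 3.0) * dt
            signal_power = quad.sum() / dt.sum()
            assert total == pytest.approx(signal_power, abs=1e-9)

    def test_zero_series_rejected(self):
        with pytest.raises(wg.ParameterError):
            wg.harmonic_power(wg.HarmonicSeries(np.zeros((3, 4))))


class TestShapePca:
    def test_identical_outlines_give_zero_variance(self):
        h = wg.efd_forward(wg.WingOutline(smooth_blob(1)), 7)
        space = wg.shape_pca([h] * 10)
        assert np.allclose(space.variance_ratio, 0.0)
        assert np.allclose(space.scores, 0.0)

    def test_two_triangularity_clusters_separate_without_overlap(self):
        rng = np.random.default_rng(2)
        series = []
        for tri in (0.1, 0.9):
            for _ in range(20):
                out = generate_wing_outline(
                    WingShapeParams(length=30, aspect=2.0, triangularity=tri),
                    rng=rng)
                series.append(wg.efd_forward(out, 7))
        space = wg.shape_pca(series)
        separated = False
        for axis in (0, 1):
            a, b = space.scores[:20, axis], space.scores[20:, axis]
            if a.max() < b.min() or b.max() < a.min():
                separated = True
        assert separated

    def test_scores_times_loadings_reproduce_centered_data(self):
        series = [wg.efd_forward(wg.WingOutline(smooth_blob(s)), 7)
                  for s in range(8)]
        X = np.array([s.coeffs.ravel() for s in series])[:, 3:]
        space = wg.shape_pca(series)
        assert np.allclose(space.scores @ space.loadings.T,
                           X - X.mean(axis=0), atol=1e-8)
        assert space.variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)


class TestRegionProportions:
    def test_whole_and_half_regions(self):
        sq = np.array([[0, 0], [2, 0], [2, 2], [0, 2]], float)
        out = wg.WingOutline(sq)
        out.regions = {"costal": sq.copy()}
        assert wg.region_area_proportions(out)["S_costal"] == pytest.approx(1.0)
        out.regions = {"clavus": np.array([[0, 0], [2, 0], [2, 1], [0, 1]],
                                          float)}
        props = wg.region_area_proportions(out)
        assert props["S_clavus"] == pytest.approx(0.5, abs=1e-9)
        assert "S_costal" not in props     # absent, not zero

    def test_generated_regions_match_construction_targets(self):
        rng = np.random.default_rng(4)
        p = WingShapeParams(length=25, aspect=2.1, triangularity=0.4,
                            costal_fraction=0.08, clavus_fraction=0.09,
                            peco_fraction=0.13)
        out = generate_wing_outline(p, rng=rng)
        props = wg.region_area_proportions(out)
        assert props["S_costal"] == pytest.approx(0.08, abs=1e-6)
        assert props["S_clavus"] == pytest.approx(0.09, abs=1e-6)
        assert props["Peco"] == pytest.approx(0.13, abs=1e-6)
        # sub-polygons contained in the forewing
        fw = Polygon(out.points).buffer(1e-9)
        for reg in out.regions.values():
            assert fw.contains(Polygon(reg))


def raster_union_area(p1, p2, n=900):
    """Rasterization oracle for union area (cell-center membership)."""
    g1, g2 = Polygon(p1), Polygon(p2)
    minx = min(g1.bounds[0], g2.bounds[0])
    miny = min(g1.bounds[1], g2.bounds[1])
    maxx = max(g1.bounds[2], g2.bounds[2])
    maxy = max(g1.bounds[3], g2.bounds[3])
    xs = np.linspace(minx, maxx, n)
    ys = np.linspace(miny, maxy, n)
    X, Y = np.meshgrid(xs, ys)
    inside = (shapely.contains_xy(g1, X.ravel(), Y.ravel())
              | shapely.contains_xy(g2, X.ravel(), Y.ravel()))
    cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
    return inside.sum() * cell


class TestCombineWings:
    sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)

    def test_identical_overlap_and_shared_edge(self):
        a = wg.WingOutline(self.sq)
        u = wg.combine_wings(a, wg.WingOutline(self.sq))
        assert abs(u.area) == pytest.approx(1.0, abs=1e-9)
        u2 = wg.combine_wings(a, wg.WingOutline(self.sq), translation=(1, 0))
        assert abs(u2.area) == pytest.approx(2.0, abs=1e-9)

    def test_offset_squares_match_rasterization(self):
        a = wg.WingOutline(self.sq)
        u = wg.combine_wings(a, wg.WingOutline(self.sq), translation=(0.5, 0))
        assert abs(u.area) == pytest.approx(1.5, abs=1e-9)
        oracle = raster_union_area(self.sq, self.sq + [0.5, 0])
        assert abs(u.area) == pytest.approx(oracle, abs=0.005)

    def test_random_convex_pairs_against_raster_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            h1 = rng.uniform(-1, 1, (12, 2))
            h2 = rng.uniform(-1, 1, (12, 2)) + rng.uniform(-0.8, 0.8, 2)
            p1 = np.array(Polygon(h1).convex_hull.exterior.coords)[:-1]
            p2 = np.array(Polygon(h2).convex_hull.exterior.coords)[:-1]
            u = wg.combine_wings(wg.WingOutline(p1), wg.WingOutline(p2))
            total = abs(u.area) + sum(abs(wg.signed_area(p))
                                      for p in u.parts)
            oracle = raster_union_area(p1, p2)
            assert abs(total - oracle) / oracle < 0.005
            a1, a2 = Polygon(p1).area, Polygon(p2).area
            assert max(a1, a2) - 1e-9 <= total <= a1 + a2 + 1e-9

    def test_disjoint_parts_flagged(self):
        a = wg.WingOutline(self.sq)
        u = wg.combine_wings(a, wg.WingOutline(self.sq), translation=(5, 5))
        assert u.multi_part and len(u.parts) == 1


class TestOutlineIO:
    def test_tps_round_trip(self, tmp_path):
        outs = {"tax_a": wg.WingOutline(smooth_blob(1)),
                "tax_b": wg.WingOutline(smooth_blob(2))}
        path = tmp_path / "wings.tps"
        wg.write_tps(path, outs)
        back = wg.read_tps(path)
        assert set(back) == {"tax_a", "tax_b"}
        assert np.allclose(back["tax_a"].points, outs["tax_a"].points,
                           atol=1e-6)

    def test_clockwise_input_is_reversed(self):
        ccw = ellipse(2, 1)
        cw = ccw[::-1]
        out = wg.WingOutline(cw)
        assert wg.signed_area(out.points) > 0

    def test_xy_csv_reader(self, tmp_path):
        import pandas as pd

        pts = smooth_blob(3)
        pd.DataFrame(pts, columns=["x_mm", "y_mm"]).to_csv(
            tmp_path / "o.csv", index=False)
        assert np.allclose(wg.read_xy_csv(tmp_path / "o.csv"), pts)
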