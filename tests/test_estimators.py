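"""MCP peeling, reference/LSCV bandwidths, kernel UDs, isopleths."""

import itertools

import numpy as np
import pytest
from scipy.integrate import simpson

from herpranges.estimators import (
    DegenerateGeometryError,
    ParameterError,
    href_bandwidth,
    kde_ud,
    lscv_bandwidth,
    lscv_score,
    mcp_region,
)
from herpranges.grids import GridError, GridSpec, UDGrid, isopleth_region


def centred_grid(half_extent: float, cell: float) -> GridSpec:
    n = int(np.ceil(2 * half_extent / cell))
    return GridSpec(-half_extent, -half_extent, cell, n, n)


class TestMCP:
    def test_unit_square_full_level(self):
        pts = [(0, 0), (1, 0), (1, 1), (0, 1)]
        r = mcp_region(pts, level=1.0)
        assert r.area == pytest.approx(1.0)

    def test_ceiling_keeps_all_four(self):
        pts = [(0, 0), (1, 0), (1, 1), (0, 1)]
        assert mcp_region(pts, level=0.95).area == pytest.approx(1.0)

    def test_peel_excludes_outliers_brute_force(self):
        """95% peel drops the 5 planted outliers; area matches the hull of the
        nearest-to-centroid subset chosen by exhaustive sorting."""
        rng = np.random.default_rng(3)
        cluster = rng.normal(0.0, 5.0, size=(100, 2))
        outliers = np.array([[500, 0], [-400, 300], [0, 800], [600, 600], [-700, -100]])
        pts = np.vstack([cluster, outliers])
        r = mcp_region(pts, level=0.95)
        keep = int(np.ceil(0.95 * len(pts)))  # 100 points
        d = np.hypot(*(pts - pts.mean(axis=0)).T)
        kept = pts[np.argsort(d, kind="stable")[:keep]]
        assert np.max(np.hypot(*kept.T)) < 100  # outliers gone
        from shapely import MultiPoint

        assert r.area == pytest.approx(MultiPoint(kept).convex_hull.area)

    def test_containment_across_levels(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(50, 2))
        inner = mcp_region(pts, level=0.95).polygon
        outer = mcp_region(pts, level=1.0).polygon
        assert outer.contains(inner) or outer.equals(inner)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateGeometryError):
            mcp_region([(0, 0), (1, 1)])
        with pytest.raises(DegenerateGeometryError):
            mcp_region([(0, 0), (1, 1), (2, 2), (3, 3)])


class TestHref:
    def test_closed_form_unit_variance(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(64, 2))
        pts = (pts - pts.mean(axis=0)) / pts.std(axis=0, ddof=1)  # var exactly 1
        assert href_bandwidth(pts).h == pytest.approx(64 ** (-1.0 / 6.0))
        assert href_bandwidth(pts).h == pytest.approx(0.5)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(30, 2))
        h1 = href_bandwidth(pts).h
        assert href_bandwidth(pts * 7.5).h == pytest.approx(7.5 * h1)
        assert h1 > 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ParameterError):
            href_bandwidth(np.ones((10, 2)))


def lscv_quadrature_oracle(pts: np.ndarray, h: float) -> float:
    """CV(h) by 2-D Simpson quadrature of fhat^2 minus exact leave-one-out sums."""
    n = len(pts)
    span = 8.0 * h
    xs = np.arange(pts[:, 0].min() - span, pts[:, 0].max() + span, h / 30.0)
    ys = np.arange(pts[:, 1].min() - span, pts[:, 1].max() + span, h / 30.0)
    xx, yy = np.meshgrid(xs, ys)
    f = np.zeros_like(xx)
    for px, py in pts:
        f += np.exp(-((xx - px) ** 2 + (yy - py) ** 2) / (2 * h * h))
    f /= 2 * np.pi * h * h * n
    integral = simpson(simpson(f**2, x=xs, axis=1), x=ys)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    k = np.exp(-d2 / (2 * h * h)) / (2 * np.pi * h * h)
    loo = (k.sum(axis=1) - np.diag(k)) / (n - 1)
    return integral - 2.0 * loo.mean()


class TestLSCV:
    @pytest.mark.parametrize("h", [0.4, 0.8, 1.5])
    def test_closed_form_matches_quadrature_oracle(self, h):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 2))
        ours = lscv_score(pts, h)
        oracle = lscv_quadrature_oracle(pts, h)
        assert ours == pytest.approx(oracle, rel=1e-6)

    def test_duplicate_heavy_data_fails_at_boundary(self):
        """180 exact duplicates of 5 sites drive the score minimum to the
        smallest candidate bandwidth -> declared non-converged."""
        rng = np.random.default_rng(6)
        sites = rng.normal(0, 100.0, size=(5, 2))
        pts = np.vstack([np.repeat(sites, 36, axis=0), rng.normal(0, 100.0, size=(20, 2))])
        bw = lscv_bandwidth(pts)
        assert not bw.converged
        assert bw.h == pytest.approx(bw.candidates[0])
        # score monotone decreasing toward the boundary on this input
        assert np.all(np.diff(bw.scores[:10]) > 0) or bw.scores[0] == bw.scores.min()

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(40, 2))
        a = lscv_bandwidth(pts)
        b = lscv_bandwidth(pts + 1000.0)
        assert a.h == pytest.approx(b.h)
        assert a.converged == b.converged

    def test_well_separated_gaussian_converges(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(60, 2))
        assert lscv_bandwidth(pts).converged

    def test_too_few_points(self):
        with pytest.raises(ParameterError):
            lscv_bandwidth(np.random.default_rng(0).normal(size=(5, 2)))


class TestKdeUD:
    def test_single_point_symmetry_and_mode(self):
        grid = centred_grid(50.5, 1.0)  # 101 cells per axis, centres -50..50
        ud = kde_ud(np.array([[0.0, 0.0]]), 3.0, grid)
        assert ud.masses.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(ud.masses, np.rot90(ud.masses), atol=1e-12)
        r, c = np.unravel_index(np.argmax(ud.masses), ud.masses.shape)
        assert (r, c) == (50, 50)

    def test_two_point_mixture_mass_split(self):
        h = 2.0
        grid = centred_grid(60.0, 0.5)
        pts = np.array([[-10.0, 0.0], [10.0, 0.0]])  # 10h apart
        ud = kde_ud(pts, h, grid)
        xc, yc = grid.x_centers(), grid.y_centers()
        xx, yy = np.meshgrid(xc, yc)
        for px in (-10.0, 10.0):
            near = np.hypot(xx - px, yy) <= 3.0 * h
            assert ud.masses[near].sum() == pytest.approx(0.5, abs=0.01)

    def test_grid_too_small_rejected(self):
        grid = centred_grid(5.0, 1.0)
        with pytest.raises(GridError):
            kde_ud(np.array([[0.0, 0.0]]), 10.0, grid)

    def test_area_strictly_increasing_in_h(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(0, 5.0, size=(40, 2))
        areas = []
        for h in (2.0, 4.0, 8.0):
            grid = centred_grid(60.0, 0.5)
            ud = kde_ud(pts, h, grid)
            areas.append(isopleth_region(ud, 0.95, "KDE").area)
        assert areas[0] < areas[1] < areas[2]


class TestIsopleth:
    def grid_for(self, masses):
        masses = np.asarray(masses, dtype=float)
        g = GridSpec(0, 0, 1.0, *masses.shape)
        return UDGrid(g, masses / masses.sum())

    def test_uniform_ud(self):
        ud = self.grid_for(np.full((10, 10), 1.0))
        assert isopleth_region(ud, 0.95).mask.sum() == 95

    def test_point_mass(self):
        m = np.zeros((5, 5))
        m[2, 2] = 1.0
        assert isopleth_region(self.grid_for(m), 0.95).mask.sum() == 1

    def test_cumulative_cut(self):
        ud = self.grid_for(np.array([[0.5, 0.3], [0.15, 0.05]]))
        assert isopleth_region(ud, 0.95).mask.sum() == 3

    def test_minimality_by_exhaustive_subsets(self):
        """On a 12-cell UD the selected region is the smallest subset whose
        mass reaches the level (checked against full enumeration)."""
        rng = np.random.default_rng(10)
        masses = rng.random(12)
        ud = self.grid_for(masses.reshape(3, 4))
        region = isopleth_region(ud, 0.95)
        flat = ud.masses.ravel()
        best = min(
            sum(sel)
            for sel in itertools.product([0, 1], repeat=12)
            if np.dot(sel, flat) >= 0.95 - 1e-12
        )
        assert region.mask.sum() == best

    def test_area_nondecreasing_in_level(self):
        rng = np.random.default_rng(11)
        ud = self.grid_for(rng.random((8, 8)))
        areas = [isopleth_region(ud, lev).area for lev in (0.5, 0.8, 0.95, 1.0)]
        assert all(a <= b for a, b in zip(areas, areas[1:]))

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            isopleth_region(self.grid_for(np.ones((2, 2))), 1.5)
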