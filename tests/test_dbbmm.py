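"""Brownian bridge variance estimation and occurrence distributions."""

import numpy as np
import pytest

import herpranges as hr
from herpranges.dbbmm import (
    SIGMA2_HI,
    SIGMA2_LO,
    EstimationError,
    MotionVarianceSeries,
    ParameterError,
    _loglik,
    _triples,
    breakpoint_fraction,
    bridge_variance,
    dbbmm_ud,
    dynamic_variance_series,
    estimate_sigma2m,
    max_bridge_sd,
)
from herpranges.grids import GridSpec
from herpranges.movement import Trajectory


def brownian_track(n, sigma2, dt=60.0, seed=0, start=(0.0, 0.0)):
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(sigma2 * dt), size=(n - 1, 2))
    xy = np.vstack([start, np.cumsum(steps, axis=0) + start])
    return Trajectory("bm", 1, t=np.arange(n) * dt, x=xy[:, 0], y=xy[:, 1])


class TestBridgeVariance:
    def test_endpoints_return_location_error(self):
        assert bridge_variance(0.0, 100.0, 4.0, 3.0, 7.0) == pytest.approx(9.0)
        assert bridge_variance(1.0, 100.0, 4.0, 3.0, 7.0) == pytest.approx(49.0)

    def test_midpoint_closed_form(self):
        assert bridge_variance(0.5, 100.0, 4.0, 0.0, 0.0) == pytest.approx(100.0)

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            bridge_variance(1.5, 100.0, 4.0, 0.0, 0.0)
        with pytest.raises(ParameterError):
            bridge_variance(0.5, -1.0, 4.0, 0.0, 0.0)


class TestSigma2Estimation:
    def test_straight_line_constant_speed_is_zero_variance(self):
        t = np.arange(31) * 1800.0
        sig = estimate_sigma2m(t, t * 0.01, t * 0.02, delta=5.0)
        assert sig < 1e-8

    def test_mle_matches_dense_grid_search(self):
        """Optimiser agrees with a 10^4-candidate log-grid argmax."""
        tr = brownian_track(21, sigma2=0.5, seed=1)
        sig = estimate_sigma2m(tr.t, tr.x, tr.y, delta=5.0)
        _, c1, c2, r2 = _triples(tr.t, tr.x, tr.y, 5.0)
        grid = np.geomspace(SIGMA2_LO, SIGMA2_HI, 10_000)
        lls = np.array([_loglik(s, c1, c2, r2) for s in grid])
        best = grid[np.argmax(lls)]
        step = np.log(grid[1] / grid[0])
        assert abs(np.log(sig) - np.log(best)) <= step

    def test_parameter_recovery_on_brownian_path(self):
        tr = brownian_track(200, sigma2=2.0, seed=2)
        sig = estimate_sigma2m(tr.t, tr.x, tr.y, delta=0.0)
        assert abs(sig - 2.0) / 2.0 < 0.25

    def test_too_short_window(self):
        with pytest.raises(EstimationError):
            estimate_sigma2m([0.0, 60.0], [0.0, 1.0], [0.0, 1.0])


class TestDynamicSeries:
    def test_homogeneous_track_rarely_selects_breakpoints(self):
        tr = brownian_track(400, sigma2=1.0, seed=3)
        frac = breakpoint_fraction(tr)
        assert frac < 0.5
        mvs = dynamic_variance_series(tr)
        cv = mvs.sigma2m.std() / mvs.sigma2m.mean()
        assert cv < 0.5

    def test_changepoint_track_splits_variance(self):
        lo = brownian_track(200, sigma2=0.05, seed=4)
        rng = np.random.default_rng(5)
        steps = rng.normal(0, np.sqrt(5.0 * 60.0), size=(200, 2))
        hi_xy = np.cumsum(steps, axis=0) + np.array([lo.x[-1], lo.y[-1]])
        x = np.concatenate([lo.x, hi_xy[:, 0]])
        y = np.concatenate([lo.y, hi_xy[:, 1]])
        tr = Trajectory("cp", 1, t=np.arange(400) * 60.0, x=x, y=y)
        mvs = dynamic_variance_series(tr, delta=0.5)
        first, second = mvs.sigma2m[:199], mvs.sigma2m[200:]
        assert second.mean() > 10.0 * first.mean()

    def test_short_track_falls_back_to_global(self):
        tr = brownian_track(12, sigma2=1.0, seed=6)
        mvs = dynamic_variance_series(tr, window_size=31)
        assert mvs.fallback_global
        assert len(mvs.sigma2m) == 11
        assert np.all(mvs.sigma2m == mvs.sigma2m[0])

    def test_single_window_constant_model(self):
        t = np.arange(31) * 60.0
        tr = Trajectory("line", 1, t=t, x=t * 0.05, y=np.zeros(31))
        mvs = dynamic_variance_series(tr, window_size=31)
        assert len(mvs.sigma2m) == 30
        assert np.allclose(mvs.sigma2m, mvs.sigma2m[0])

    def test_invalid_window_margin(self):
        with pytest.raises(ParameterError):
            MotionVarianceSeries(np.ones(5), window_size=10, margin=11)


def small_grid(half, cell):
    n = int(round(2 * half / cell))
    return GridSpec(-half, -half, cell, n, n)


class TestOccurrenceUD:
    def test_normalization_and_reflection_symmetry(self):
        tr = Trajectory("seg", 1, t=[0.0, 600.0], x=[-40.0, 40.0], y=[0.0, 0.0])
        mvs = MotionVarianceSeries(np.array([1.0]), loc_error=5.0)
        ud = dbbmm_ud(tr, mvs, GridSpec(-201.0, -201.0, 2.0, 201, 201))
        assert ud.masses.sum() == pytest.approx(1.0, abs=1e-9)
        # symmetric under reflection across the segment's perpendicular bisector
        np.testing.assert_allclose(ud.masses, ud.masses[:, ::-1], atol=1e-9)
        np.testing.assert_allclose(ud.masses, ud.masses[::-1, :], atol=1e-9)

    def test_disc_mass_matches_gaussian_mixture_closed_form(self):
        """Zero-length segment: every time slice is a Gaussian centred on the
        point, so the disc mass has an exact closed form."""
        T, sig2, delta = 600.0, 2.0, 5.0
        tr = Trajectory("pt", 1, t=[0.0, T], x=[0.0, 0.0], y=[0.0, 0.0])
        mvs = MotionVarianceSeries(np.array([sig2]), loc_error=delta)
        ud = dbbmm_ud(tr, mvs, small_grid(150.0, 1.0), time_substeps=10)
        alphas = (np.arange(10) + 0.5) / 10
        v = T * alphas * (1 - alphas) * sig2 + delta**2 * (alphas**2 + (1 - alphas) ** 2)
        radius = 2.0 * np.sqrt(v[4])  # 2 SD at alpha ~ 0.5
        expected = np.mean(1.0 - np.exp(-(radius**2) / (2.0 * v)))
        g = ud.grid
        xx, yy = np.meshgrid(g.x_centers(), g.y_centers())
        got = ud.masses[np.hypot(xx, yy) <= radius].sum()
        assert got == pytest.approx(expected, rel=0.01)

    def test_chord_moment_for_pure_bridge(self):
        """With no location error the mean squared distance of UD mass from
        the chord approaches T*sigma2m/6 (Brownian bridge moment)."""
        T, sig2 = 3600.0, 1.0
        tr = Trajectory("seg", 1, t=[0.0, T], x=[-40.0, 40.0], y=[0.0, 0.0])
        mvs = MotionVarianceSeries(np.array([sig2]), loc_error=0.0)
        ud = dbbmm_ud(tr, mvs, small_grid(250.0, 1.0), time_substeps=50)
        g = ud.grid
        yy = np.meshgrid(g.x_centers(), g.y_centers())[1]
        msd = float((ud.masses * yy**2).sum())
        assert msd == pytest.approx(T * sig2 / 6.0, rel=0.05)

    def test_substep_convergence(self, short_track):
        tr = hr.apply_regime(short_track, hr.regime_schedule(4))
        mvs = dynamic_variance_series(tr)
        pad = max(5 * max_bridge_sd(tr, mvs), 100.0)
        from herpranges.grids import make_grid

        grid = make_grid(tr.x, tr.y, 5.0, padding=pad)
        a10 = hr.isopleth_region(dbbmm_ud(tr, mvs, grid, time_substeps=10), 0.95).area
        a20 = hr.isopleth_region(dbbmm_ud(tr, mvs, grid, time_substeps=20), 0.95).area
        assert abs(a20 - a10) / a10 < 0.01

    def test_fix_frequency_robustness(self, year_tracks):
        """Halving the fix rate (daily vs twice-daily sampling) moves the
        dBBMM 95% area by less than 50%."""
        from herpranges.grids import make_grid

        tr = year_tracks[2]
        th3 = hr.apply_regime(tr, hr.regime_schedule(3))
        th4 = hr.apply_regime(tr, hr.regime_schedule(4))
        mvs = {r: dynamic_variance_series(t) for r, t in [(3, th3), (4, th4)]}
        pads = [5 * max_bridge_sd(t, mvs[r]) for r, t in [(3, th3), (4, th4)]]
        grid = make_grid(tr.x, tr.y, 5.0, padding=max(pads))
        d3 = hr.isopleth_region(dbbmm_ud(th3, mvs[3], grid), 0.95).area
        d4 = hr.isopleth_region(dbbmm_ud(th4, mvs[4], grid), 0.95).area
        assert abs(d4 - d3) / d3 < 0.5
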