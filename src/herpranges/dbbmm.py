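"""Dynamic Brownian Bridge Movement Model.

Between consecutive fixes the animal is modelled as a Brownian bridge
whose diffusion, the Brownian motion variance ``sigma2m`` (m^2/s), is
estimated by leave-one-out: odd-indexed fixes are treated as observations
of the bridge spanning their even-indexed neighbours, each contributing a
bivariate normal likelihood with the interpolation variance

    var(alpha) = T * alpha * (1 - alpha) * sigma2m
                 + (1 - alpha)^2 * delta1^2 + alpha^2 * delta2^2

where ``alpha`` is the fractional time along the bridge, ``T`` the bridge
duration and ``delta`` the telemetry location error (5 m throughout).

The *dynamic* part slides a window (default 31 fixes) along the track and
compares, by BIC, a constant-variance model against all two-piece models
with a single breakpoint outside the window margins (default 11 fixes),
so behaviourally distinct phases (sheltering vs. travelling) get their
own variance.  Each window assigns its selected variances to the
margin-interior segments; overlapping assignments are averaged.  Tracks
shorter than the window fall back to a single global variance (flagged).

The occurrence distribution integrates the bridge density over time by
midpoint quadrature (default 10 substeps per segment), weighting each
slice by its duration, and normalises total cell mass to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import ndtr

from .grids import GridError, GridSpec, UDGrid
from .movement import Trajectory

__all__ = [
    "MotionVarianceSeries",
    "bridge_variance",
    "estimate_sigma2m",
    "dynamic_variance_series",
    "dbbmm_ud",
]

SIGMA2_LO = 1e-10
SIGMA2_HI = 1e6
_GRID_SIZE = 400  # profile-likelihood sigma2 grid used by the sliding window


class ParameterError(ValueError):
    pass


class EstimationError(ValueError):
    pass


@dataclass
class MotionVarianceSeries:
    """Per-segment Brownian motion variance (m^2/s) for one trajectory."""

    sigma2m: np.ndarray  # one value per inter-fix segment
    window_size: int = 31
    margin: int = 11
    loc_error: float = 5.0
    fallback_global: bool = False

    def __post_init__(self) -> None:
        self.sigma2m = np.asarray(self.sigma2m, dtype=float)
        if np.any(self.sigma2m < 0):
            raise ParameterError("sigma2m must be nonnegative")
        if self.margin < 3:
            raise ParameterError("margin must be >= 3")
        if self.window_size < 2 * self.margin + 1 or self.window_size % 2 == 0:
            raise ParameterError("window_size must be odd and >= 2*margin + 1")


def bridge_variance(alpha, T, sigma2m, delta1, delta2):
    """Interpolation variance of a Brownian bridge at fractional time alpha."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise ParameterError("alpha must lie in [0, 1]")
    if np.any(np.asarray(T) <= 0) or sigma2m < 0 or delta1 < 0 or delta2 < 0:
        raise ParameterError("T must be positive; sigma2m and deltas nonnegative")
    out = T * alpha * (1.0 - alpha) * sigma2m + (1.0 - alpha) ** 2 * delta1**2 + alpha**2 * delta2**2
    return float(out) if out.ndim == 0 else out


def _triples(t: np.ndarray, x: np.ndarray, y: np.ndarray, delta: float):
    """Leave-one-out constants for odd-indexed interior fixes.

    Returns (centers, c1, c2, r2) where for each odd index i with
    neighbours a = i-1, b = i+1:  var = c1 * sigma2m + c2 and r2 is the
    squared deviation of fix i from the time-interpolated position.
    """
    n = len(t)
    centers = np.arange(1, n - 1, 2)
    if len(centers) == 0:
        raise EstimationError("need at least one leave-out triple (>= 3 fixes)")
    a = centers - 1
    b = centers + 1
    T = t[b] - t[a]
    alpha = (t[centers] - t[a]) / T
    c1 = T * alpha * (1.0 - alpha)
    c2 = (1.0 - alpha) ** 2 * delta**2 + alpha**2 * delta**2
    mx = (1.0 - alpha) * x[a] + alpha * x[b]
    my = (1.0 - alpha) * y[a] + alpha * y[b]
    r2 = (x[centers] - mx) ** 2 + (y[centers] - my) ** 2
    return centers, c1, c2, r2


def _loglik(sigma2: float, c1: np.ndarray, c2: np.ndarray, r2: np.ndarray) -> float:
    v = c1 * sigma2 + c2
    return float(np.sum(-np.log(2.0 * np.pi * v) - r2 / (2.0 * v)))


def estimate_sigma2m(t, x, y, delta: float = 5.0) -> float:
    """Maximum-likelihood sigma2m for one window of fixes."""
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 3:
        raise EstimationError("window needs at least 3 fixes")
    _, c1, c2, r2 = _triples(t, x, y, delta)
    res = minimize_scalar(
        lambda u: -_loglik(np.exp(u), c1, c2, r2),
        bounds=(np.log(SIGMA2_LO), np.log(SIGMA2_HI)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(np.exp(res.x))


def dynamic_variance_series(
    traj: Trajectory,
    window_size: int = 31,
    margin: int = 11,
    delta: float = 5.0,
) -> MotionVarianceSeries:
    """Sliding-window sigma2m with single-breakpoint model selection.

    The profile likelihood is evaluated on a fixed geometric sigma2 grid
    (400 candidates spanning [1e-10, 1e6] m^2/s); cumulative per-triple
    log-likelihoods make every window and breakpoint a difference of two
    cumulative sums, so the whole sweep is vectorised.
    """
    n = traj.n_fixes
    if n < window_size:
        sigma2 = estimate_sigma2m(traj.t, traj.x, traj.y, delta)
        return MotionVarianceSeries(
            sigma2m=np.full(n - 1, sigma2),
            window_size=window_size,
            margin=margin,
            loc_error=delta,
            fallback_global=True,
        )
    centers, c1, c2, r2 = _triples(traj.t, traj.x, traj.y, delta)
    m = len(centers)
    sig_grid = np.geomspace(SIGMA2_LO, SIGMA2_HI, _GRID_SIZE)
    # per-triple log-likelihood at every candidate, cumulated along triples
    v = c1[None, :] * sig_grid[:, None] + c2[None, :]
    L = -np.log(2.0 * np.pi * v) - r2[None, :] / (2.0 * v)
    C = np.zeros((_GRID_SIZE, m + 1))
    np.cumsum(L, axis=1, out=C[:, 1:])

    def best(jlo: np.ndarray, jhi: np.ndarray):
        """Max profile log-likelihood and argmax sigma2 for triple ranges."""
        diff = C[:, jhi] - C[:, jlo]
        g = np.argmax(diff, axis=0)
        return diff[g, np.arange(len(jlo))], sig_grid[g]

    starts = np.arange(0, n - window_size + 1)
    # triples fully inside window [s, s+w-1]
    jlo = np.searchsorted(centers, starts + 1)
    jhi = np.searchsorted(centers, starts + window_size - 2, side="right")
    nobs = np.maximum(jhi - jlo, 1)

    ll_const, sig_const = best(jlo, jhi)
    bic_const = 1.0 * np.log(nobs) - 2.0 * ll_const

    # two-piece models: split after the k-th triple of the window, with the
    # breakpoint fix (the split triple's centre) outside the margins
    best_bic_bp = np.full(len(starts), np.inf)
    best_split = np.zeros(len(starts), dtype=int)
    best_sig_l = np.zeros(len(starts))
    best_sig_r = np.zeros(len(starts))
    max_triples = int(np.max(jhi - jlo))
    for k in range(1, max_triples):
        jm = jlo + k
        valid = (jm < jhi) & (centers[np.minimum(jm, m - 1)] >= starts + margin) & (
            centers[np.minimum(jm, m - 1)] <= starts + window_size - 1 - margin
        )
        if not np.any(valid):
            continue
        ll_l, sg_l = best(jlo, jm)
        ll_r, sg_r = best(jm, jhi)
        bic = 3.0 * np.log(nobs) - 2.0 * (ll_l + ll_r)
        bic = np.where(valid, bic, np.inf)
        better = bic < best_bic_bp
        best_bic_bp = np.where(better, bic, best_bic_bp)
        best_split = np.where(better, jm, best_split)
        best_sig_l = np.where(better, sg_l, best_sig_l)
        best_sig_r = np.where(better, sg_r, best_sig_r)

    use_bp = best_bic_bp < bic_const

    # assign each window's selected variances to its margin-interior segments
    sums = np.zeros(n - 1)
    counts = np.zeros(n - 1)
    for s_idx, s in enumerate(starts):
        lo_seg = s + margin
        hi_seg = s + window_size - 1 - margin  # exclusive upper segment index
        if use_bp[s_idx]:
            b_fix = centers[best_split[s_idx]]
            for seg in range(lo_seg, hi_seg):
                val = best_sig_l[s_idx] if seg < b_fix else best_sig_r[s_idx]
                sums[seg] += val
                counts[seg] += 1.0
        else:
            sums[lo_seg:hi_seg] += sig_const[s_idx]
            counts[lo_seg:hi_seg] += 1.0

    sigma2 = np.full(n - 1, np.nan)
    has = counts > 0
    sigma2[has] = sums[has] / counts[has]
    # head/tail segments inherit the nearest estimated value
    if not np.any(has):
        sigma2[:] = sig_const[0]
    else:
        idx = np.flatnonzero(has)
        first, last = idx[0], idx[-1]
        sigma2[:first] = sigma2[first]
        sigma2[last + 1 :] = sigma2[last]
        # interior gaps (none expected, but be safe)
        nans = np.flatnonzero(~np.isfinite(sigma2))
        for j in nans:
            sigma2[j] = sigma2[idx[np.argmin(np.abs(idx - j))]]

    return MotionVarianceSeries(
        sigma2m=sigma2,
        window_size=window_size,
        margin=margin,
        loc_error=delta,
        fallback_global=False,
    )


def breakpoint_fraction(
    traj: Trajectory, window_size: int = 31, margin: int = 11, delta: float = 5.0
) -> float:
    """Fraction of sliding windows in which BIC prefers the breakpoint model."""
    n = traj.n_fixes
    if n < window_size:
        return 0.0
    centers, c1, c2, r2 = _triples(traj.t, traj.x, traj.y, delta)
    m = len(centers)
    sig_grid = np.geomspace(SIGMA2_LO, SIGMA2_HI, _GRID_SIZE)
    v = c1[None, :] * sig_grid[:, None] + c2[None, :]
    L = -np.log(2.0 * np.pi * v) - r2[None, :] / (2.0 * v)
    C = np.zeros((_GRID_SIZE, m + 1))
    np.cumsum(L, axis=1, out=C[:, 1:])
    starts = np.arange(0, n - window_size + 1)
    jlo = np.searchsorted(centers, starts + 1)
    jhi = np.searchsorted(centers, starts + window_size - 2, side="right")
    nobs = np.maximum(jhi - jlo, 1)
    diff = C[:, jhi] - C[:, jlo]
    ll_const = diff.max(axis=0)
    bic_const = np.log(nobs) - 2.0 * ll_const
    best_bic_bp = np.full(len(starts), np.inf)
    for k in range(1, int(np.max(jhi - jlo))):
        jm = jlo + k
        valid = (jm < jhi) & (centers[np.minimum(jm, m - 1)] >= starts + margin) & (
            centers[np.minimum(jm, m - 1)] <= starts + window_size - 1 - margin
        )
        if not np.any(valid):
            continue
        ll = (C[:, jm] - C[:, jlo]).max(axis=0) + (C[:, jhi] - C[:, jm]).max(axis=0)
        bic = np.where(valid, 3.0 * np.log(nobs) - 2.0 * ll, np.inf)
        best_bic_bp = np.minimum(best_bic_bp, bic)
    return float(np.mean(best_bic_bp < bic_const))


def max_bridge_sd(traj: Trajectory, mvs: MotionVarianceSeries) -> float:
    """Largest bridge standard deviation along the track (for grid padding)."""
    T = np.diff(traj.t)
    peak = 0.25 * T * mvs.sigma2m + mvs.loc_error**2
    return float(np.sqrt(np.max(peak)))


def dbbmm_ud(
    traj: Trajectory,
    mvs: MotionVarianceSeries,
    grid: GridSpec,
    time_substeps: int = 10,
    max_chunk: float = 2e7,
) -> UDGrid:
    """Occurrence distribution: time-integrated bridge density on a grid.

    Each segment contributes ``time_substeps`` bivariate normal slices at
    the midpoints of equal time slices, weighted by slice duration.
    Kernels are truncated at 5 SD; if more than 0.1% of the total mass
    falls off the grid a GridError is raised.
    """
    n = traj.n_fixes
    if n < 2:
        raise ParameterError("need at least one segment")
    if len(mvs.sigma2m) != n - 1:
        raise ParameterError("variance series length must equal segment count")
    T = np.diff(traj.t)
    delta = mvs.loc_error
    alphas = (np.arange(time_substeps) + 0.5) / time_substeps

    # flatten segments x substeps into one blob list
    a = alphas[None, :]
    mx = (1.0 - a) * traj.x[:-1, None] + a * traj.x[1:, None]
    my = (1.0 - a) * traj.y[:-1, None] + a * traj.y[1:, None]
    var = (
        T[:, None] * a * (1.0 - a) * mvs.sigma2m[:, None]
        + (1.0 - a) ** 2 * delta**2
        + a**2 * delta**2
    )
    w = np.repeat(T / time_substeps, time_substeps)
    mx, my, var = mx.ravel(), my.ravel(), var.ravel()

    cs = grid.cell_size
    n_rows, n_cols = grid.n_rows, grid.n_cols
    sd = np.sqrt(var)
    hw = np.ceil(5.0 * sd / cs).astype(int)
    hw = np.minimum(hw, max(n_rows, n_cols))
    col0 = np.floor((mx - grid.origin_x) / cs).astype(int)
    row0 = np.floor((my - grid.origin_y) / cs).astype(int)

    density = np.zeros(n_rows * n_cols)
    for width in np.unique(hw):
        sel = np.flatnonzero(hw == width)
        K = 2 * int(width) + 1
        step = max(int(max_chunk // (K * K)), 1)
        ar = np.arange(K) - int(width)
        for beg in range(0, len(sel), step):
            idx = sel[beg : beg + step]
            rows = row0[idx][:, None] + ar[None, :]
            cols = col0[idx][:, None] + ar[None, :]
            np.clip(rows, 0, n_rows - 1, out=rows)
            np.clip(cols, 0, n_cols - 1, out=cols)
            # exact per-cell Gaussian mass via erf differences on each axis,
            # so bridges narrower than a cell are not under-counted
            ylo = grid.origin_y + rows * cs
            xlo = grid.origin_x + cols * cs
            s = sd[idx][:, None]
            wy = ndtr((ylo + cs - my[idx][:, None]) / s) - ndtr((ylo - my[idx][:, None]) / s)
            wx = ndtr((xlo + cs - mx[idx][:, None]) / s) - ndtr((xlo - mx[idx][:, None]) / s)
            contrib = w[idx][:, None, None] * wy[:, :, None] * wx[:, None, :]
            flat = rows[:, :, None] * n_cols + cols[:, None, :]
            np.add.at(density, flat.ravel(), contrib.ravel())

    mass = density  # contributions are already cell masses
    total_expected = w.sum()
    clipped = 1.0 - mass.sum() / total_expected
    if clipped > 1e-3:
        raise GridError(f"grid clips {clipped:.2%} of bridge mass; enlarge padding")
    total = mass.sum()
    return UDGrid(grid=grid, masses=(mass / total).reshape(n_rows, n_cols))
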