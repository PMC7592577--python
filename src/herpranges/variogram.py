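"""Positional semivariograms and time-to-independence of tracking data.

The empirical semivariogram of a planar track uses the per-coordinate
convention

    gamma(tau) = (1 / (4 N_tau)) * sum ||r(t + tau) - r(t)||^2

over all fix pairs whose lag falls in the bin around tau (the division
by 4 = 2 pairs-per-difference x 2 coordinates makes the white-noise
plateau equal the per-coordinate position variance).

"Time to independence" operationalises when autocorrelation becomes
insignificant: the plateau is the mean semivariance over the last third
of lag bins, and independence is declared at the smallest lag from which
gamma stays within +/- 2 SE of the plateau for every later bin.  If no
lag qualifies the result is censored at the track duration and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .movement import SECONDS_PER_DAY, Trajectory

__all__ = ["VariogramResult", "empirical_variogram", "time_to_independence"]


class ParameterError(ValueError):
    pass


@dataclass
class VariogramResult:
    lag_s: np.ndarray  # bin centres, seconds
    gamma: np.ndarray  # semivariance, m^2
    gamma_se: np.ndarray
    n_pairs: np.ndarray
    duration_s: float
    independence_days: float | None = None
    censored: bool = False


def empirical_variogram(traj: Trajectory, n_lag_bins: int = 30) -> VariogramResult:
    """Binned empirical semivariogram up to half the track duration."""
    n = traj.n_fixes
    if n < 2:
        raise ParameterError("need at least 2 fixes")
    duration = float(traj.t[-1] - traj.t[0])
    max_lag = duration / 2.0
    edges = np.linspace(0.0, max_lag, n_lag_bins + 1)
    sums = np.zeros(n_lag_bins)
    sumsq = np.zeros(n_lag_bins)
    counts = np.zeros(n_lag_bins, dtype=np.int64)

    dt = np.diff(traj.t)
    regular = np.allclose(dt, dt[0])
    if regular:
        step = dt[0]
        kmax = int(np.floor(max_lag / step))
        for k in range(1, kmax + 1):
            lag = k * step
            b = min(int(np.searchsorted(edges, lag, side="right")) - 1, n_lag_bins - 1)
            d2 = (traj.x[k:] - traj.x[:-k]) ** 2 + (traj.y[k:] - traj.y[:-k]) ** 2
            sums[b] += d2.sum()
            sumsq[b] += (d2**2).sum()
            counts[b] += len(d2)
    else:
        # exhaustive pairs; fine for thinned (low-frequency) tracks
        ti = traj.t
        for i in range(n - 1):
            lag = ti[i + 1 :] - ti[i]
            sel = lag <= max_lag
            if not np.any(sel):
                continue
            d2 = (traj.x[i + 1 :][sel] - traj.x[i]) ** 2 + (traj.y[i + 1 :][sel] - traj.y[i]) ** 2
            b = np.minimum(np.searchsorted(edges, lag[sel], side="right") - 1, n_lag_bins - 1)
            np.add.at(sums, b, d2)
            np.add.at(sumsq, b, d2**2)
            np.add.at(counts, b, 1)

    keep = counts > 0
    mean_d2 = sums[keep] / counts[keep]
    var_d2 = np.maximum(sumsq[keep] / counts[keep] - mean_d2**2, 0.0)
    gamma = mean_d2 / 4.0
    # overlapping pairs are positively dependent, so the effective sample
    # size per bin is capped at the number of fixes, not the pair count
    eff = np.minimum(counts[keep], n)
    gamma_se = np.sqrt(var_d2 / eff) / 4.0
    centers = 0.5 * (edges[:-1] + edges[1:])[keep]
    return VariogramResult(
        lag_s=centers,
        gamma=gamma,
        gamma_se=gamma_se,
        n_pairs=counts[keep],
        duration_s=duration,
    )


def time_to_independence(vg: VariogramResult) -> VariogramResult:
    """Smallest lag from which gamma stays at the plateau (see module doc).

    Returns the input with ``independence_days`` (and ``censored``) set.
    """
    nb = len(vg.lag_s)
    if nb < 10:
        raise ParameterError("need at least 10 lag bins")
    tail = vg.gamma[-(nb // 3) :]
    plateau = float(np.mean(tail))
    within = np.abs(vg.gamma - plateau) <= 2.0 * vg.gamma_se
    # smallest lag index from which every later bin stays inside the band
    ok_from = np.flatnonzero(np.cumsum((~within)[::-1])[::-1] == 0)
    if len(ok_from) == 0:
        vg.independence_days = vg.duration_s / SECONDS_PER_DAY
        vg.censored = True
    else:
        vg.independence_days = float(vg.lag_s[ok_from[0]] / SECONDS_PER_DAY)
        vg.censored = False
    return vg
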