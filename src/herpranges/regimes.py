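"""VHF field sampling regimes: thinning full trajectories to tracking schedules.

Regime 1 keeps the full 30-min data.  Regimes 2-7 retain scheduled clock
times inside the species' daylight activity window: four per day, two per
day, one per day, two per week, one per week, one per month.  Regime 8
starts from the regime-2 schedule and keeps only relocations (fixes at
least a threshold distance from the previously retained fix).

Weeks are 52 disjoint 7-day blocks from day 1; months are eleven 30-day
blocks plus a final 35-day block, so a 365-day track yields exactly
1460 / 730 / 365 / 104 / 52 / 12 fixes for regimes 2-7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .movement import SECONDS_PER_DAY, Trajectory

__all__ = ["RegimeSpec", "regime_schedule", "apply_regime", "relocations_only", "REGIME_IDS"]

REGIME_IDS = tuple(range(1, 9))


class ParameterError(ValueError):
    pass


class AlignmentError(ValueError):
    """A scheduled clock time is absent from the trajectory."""


@dataclass
class RegimeSpec:
    regime_id: int
    times_of_day: tuple[float, ...]  # clock hours
    day_filter: str  # "all" | "weekly" | "monthly" | "none"
    days: tuple[int, ...] = ()  # 1-based day-of-year list for weekly/monthly filters
    relocations_only: bool = False
    stationary_threshold: float = 5.0

    def scheduled_times(self, duration_s: float) -> np.ndarray:
        """Scheduled fix times (seconds since study start) within the track."""
        if self.day_filter == "none":
            raise ParameterError("regime 1 has no schedule (identity)")
        if self.day_filter == "all":
            n_days = int(np.floor(duration_s / SECONDS_PER_DAY)) + 1
            days = np.arange(1, n_days + 1)
        else:
            days = np.asarray(self.days)
        times = []
        for d in days:
            for h in self.times_of_day:
                t = (d - 1) * SECONDS_PER_DAY + h * 3600.0
                if t <= duration_s:
                    times.append(t)
        return np.array(sorted(times))


def regime_schedule(regime_id: int) -> RegimeSpec:
    """The eight tracking-regime schedules."""
    if regime_id == 1:
        return RegimeSpec(1, (), "none")
    if regime_id == 2:
        return RegimeSpec(2, (6.0, 10.0, 14.0, 18.0), "all")
    if regime_id == 3:
        return RegimeSpec(3, (8.0, 16.0), "all")
    if regime_id == 4:
        return RegimeSpec(4, (12.0,), "all")
    if regime_id == 5:
        days = tuple(7 * w + d for w in range(52) for d in (1, 4))
        return RegimeSpec(5, (12.0,), "weekly", days)
    if regime_id == 6:
        days = tuple(7 * w + 1 for w in range(52))
        return RegimeSpec(6, (12.0,), "weekly", days)
    if regime_id == 7:
        days = tuple(30 * m + 15 for m in range(12))
        return RegimeSpec(7, (12.0,), "monthly", days)
    if regime_id == 8:
        base = regime_schedule(2)
        return RegimeSpec(8, base.times_of_day, "all", relocations_only=True)
    raise ParameterError(f"unknown regime id {regime_id}")


def apply_regime(traj: Trajectory, spec: RegimeSpec) -> Trajectory:
    """Thin a trajectory to a regime's schedule; drops true-state labels.

    The input must be sampled on a regular grid aligned to midnight so
    every scheduled time exists exactly.
    """
    if spec.regime_id == 1:
        return traj.subset(np.arange(traj.n_fixes), drop_state=True)
    sched = spec.scheduled_times(traj.t[-1])
    idx = np.searchsorted(traj.t, sched)
    ok = (idx < traj.n_fixes) & np.isclose(traj.t[np.minimum(idx, traj.n_fixes - 1)], sched)
    if not np.all(ok):
        missing = sched[~ok][:3]
        raise AlignmentError(f"scheduled times not present in trajectory (e.g. {missing})")
    thinned = traj.subset(idx, drop_state=True)
    if spec.relocations_only:
        thinned = relocations_only(thinned, spec.stationary_threshold)
    return thinned


def relocations_only(traj: Trajectory, threshold: float = 5.0) -> Trajectory:
    """Drop fixes within ``threshold`` metres of the last retained fix.

    The first fix is always retained; each later fix is kept iff its
    distance to the most recently kept fix is >= threshold.
    """
    if threshold < 0:
        raise ParameterError("threshold must be nonnegative")
    keep = [0]
    last = 0
    for i in range(1, traj.n_fixes):
        d = np.hypot(traj.x[i] - traj.x[last], traj.y[i] - traj.y[last])
        if d >= threshold:
            keep.append(i)
            last = i
    return traj.subset(np.array(keep), drop_state=True)
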