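"""True-pathway buffer and overlap error metrics.

The reference against which every estimator is scored is the union of
discs centred on every fix of the full-resolution (30-min) trajectory,
with species-specific radius (40 / 20 / 10 m for archetypes 1/2/3).
All overlap arithmetic is rasterized on one shared grid per individual,
so polygon estimates (MCP) are rasterized before comparison.

Commission (Type I) and omission (Type II) errors are expressed as
percentages of the true-pathway area, so omission is bounded at 100%
while commission is unbounded above.  Precision, recall and the
F-measure follow their standard confusion-area definitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GridError, GridSpec, RegionMask
from .movement import Trajectory

__all__ = [
    "ErrorMetrics",
    "true_pathway_buffer",
    "confusion_areas",
    "error_percentages",
    "f_measure",
    "score_region",
]


class ParameterError(ValueError):
    pass


@dataclass
class ErrorMetrics:
    tp_area: float
    fp_area: float
    fn_area: float
    commission_pct: float
    omission_pct: float
    precision: float
    recall: float
    f_measure: float


def true_pathway_buffer(full_traj: Trajectory, width: float, grid: GridSpec) -> RegionMask:
    """Union of discs of radius ``width`` around every fix, on ``grid``.

    A cell belongs to the buffer iff its centre lies within ``width`` of
    at least one fix (distances use the exact fix coordinates, not
    cell-snapped positions).
    """
    if full_traj.n_fixes == 0:
        raise ParameterError("empty trajectory")
    if width <= 0:
        raise ParameterError("width must be positive")
    cs = grid.cell_size
    n_rows, n_cols = grid.n_rows, grid.n_cols
    hw = int(np.ceil(width / cs)) + 1
    ar = np.arange(2 * hw + 1) - hw
    col0 = np.floor((full_traj.x - grid.origin_x) / cs).astype(int)
    row0 = np.floor((full_traj.y - grid.origin_y) / cs).astype(int)
    hits = np.zeros(n_rows * n_cols, dtype=np.int32)
    chunk = max(int(2e7 // ((2 * hw + 1) ** 2)), 1)
    for beg in range(0, full_traj.n_fixes, chunk):
        sl = slice(beg, beg + chunk)
        rows = row0[sl][:, None] + ar[None, :]
        cols = col0[sl][:, None] + ar[None, :]
        np.clip(rows, 0, n_rows - 1, out=rows)
        np.clip(cols, 0, n_cols - 1, out=cols)
        ycv = grid.origin_y + (rows + 0.5) * cs
        xcv = grid.origin_x + (cols + 0.5) * cs
        d2 = (ycv[:, :, None] - full_traj.y[sl][:, None, None]) ** 2 + (
            xcv[:, None, :] - full_traj.x[sl][:, None, None]
        ) ** 2
        inside = d2 <= width * width
        flat = rows[:, :, None] * n_cols + cols[:, None, :]
        np.add.at(hits, flat[inside], 1)
    mask = (hits > 0).reshape(n_rows, n_cols)
    area = float(mask.sum()) * grid.cell_area
    if area <= 0:
        raise ParameterError("true pathway buffer has zero area on this grid")
    return RegionMask(method="truth", level=1.0, grid=grid, mask=mask, area=area)


def confusion_areas(estimate: RegionMask, truth: RegionMask) -> tuple[float, float, float]:
    """(tp, fp, fn) areas by cell counting on the shared grid."""
    if estimate.mask is None or truth.mask is None:
        raise GridError("both regions must be rasterized")
    if estimate.grid != truth.grid:
        raise GridError("regions live on different grids")
    ca = truth.grid.cell_area
    est, tru = estimate.mask, truth.mask
    tp = float(np.sum(est & tru)) * ca
    fp = float(np.sum(est & ~tru)) * ca
    fn = float(np.sum(~est & tru)) * ca
    return tp, fp, fn


def error_percentages(tp: float, fp: float, fn: float) -> tuple[float, float]:
    """Commission and omission errors as % of the true-pathway area."""
    if min(tp, fp, fn) < 0:
        raise ParameterError("areas must be nonnegative")
    truth_area = tp + fn
    if truth_area <= 0:
        raise ParameterError("zero truth area")
    # fn <= tp + fn, so omission is <= 100 up to one rounding ulp; clamp it
    return 100.0 * fp / truth_area, min(100.0 * fn / truth_area, 100.0)


def f_measure(tp: float, fp: float, fn: float) -> float:
    """Harmonic mean of precision and recall; 0 when tp = 0 (defined limit)."""
    if min(tp, fp, fn) < 0:
        raise ParameterError("areas must be nonnegative")
    denom = 2.0 * tp + fp + fn
    if denom == 0 or tp == 0:
        return 0.0
    return 2.0 * tp / denom


def score_region(estimate: RegionMask, truth: RegionMask) -> ErrorMetrics:
    """Full error metrics of one estimate against the true-pathway buffer."""
    est = estimate.rasterize(truth.grid)
    tp, fp, fn = confusion_areas(est, truth)
    commission, omission = error_percentages(tp, fp, fn)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    return ErrorMetrics(
        tp_area=tp,
        fp_area=fp,
        fn_area=fn,
        commission_pct=commission,
        omission_pct=omission,
        precision=precision,
        recall=recall,
        f_measure=f_measure(tp, fp, fn),
    )
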