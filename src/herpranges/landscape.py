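"""Fractional-Brownian-motion neutral landscapes.

The movement simulator needs a single spatially autocorrelated habitat
covariate.  We synthesise it as two-dimensional fractional Brownian motion
via spectral synthesis: white Gaussian noise is filtered in the frequency
domain with amplitude ``f**-(H+1)`` (power spectrum ``f**-(2H+2)``), which
yields a surface whose semivariance grows as ``lag**(2H)`` at small lags.
The field is synthesised on a domain twice the requested size and cropped,
so the periodicity of the discrete Fourier transform does not contaminate
the small-lag scaling, then standardised to zero mean and unit variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LandscapeRaster",
    "generate_fbm_landscape",
    "sample_covariate",
    "sample_covariate_clamped",
    "write_ascii_grid",
    "read_ascii_grid",
]


class ParameterError(ValueError):
    """Invalid parameter passed to a landscape routine."""


@dataclass
class LandscapeRaster:
    """Gridded habitat covariate, standardised to mean 0 / SD 1.

    Row 0 is the southmost row; the centre of cell ``(r, c)`` sits at
    ``(origin_x + (c + 0.5) * cell_size, origin_y + (r + 0.5) * cell_size)``.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int
    values: np.ndarray = field(repr=False)
    hurst: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_rows < 2 or self.n_cols < 2:
            raise ParameterError("raster needs at least 2x2 cells")
        if self.cell_size <= 0:
            raise ParameterError("cell_size must be positive")
        if self.values.shape != (self.n_rows, self.n_cols):
            raise ParameterError("values shape does not match n_rows/n_cols")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("raster values must be finite")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    @property
    def center(self) -> tuple[float, float]:
        xmin, ymin, xmax, ymax = self.extent
        return (0.5 * (xmin + xmax), 0.5 * (ymin + ymax))


def _spectral_fbm(n_rows: int, n_cols: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """fBm field of shape (n_rows, n_cols) via spectrally filtered white noise.

    Synthesised on a torus 2x the requested extent (cropped afterwards, so
    DFT periodicity does not wrap correlation back in) and at 2x spatial
    oversampling (decimated afterwards, so the Nyquist cut-off of the
    power law does not flatten the semivariance at one- and two-cell lags).
    """
    over = 2
    pr, pc = over * 2 * n_rows, over * 2 * n_cols
    noise = rng.standard_normal((pr, pc))
    spec = np.fft.fft2(noise)
    fy = np.fft.fftfreq(pr)[:, None]
    fx = np.fft.fftfreq(pc)[None, :]
    f = np.hypot(fy, fx)
    with np.errstate(divide="ignore"):
        amp = f ** -(hurst + 1.0)
    amp[0, 0] = 0.0  # kill the DC component; mean is re-set anyway
    field_ = np.real(np.fft.ifft2(spec * amp))
    return field_[: over * n_rows : over, : over * n_cols : over]


def generate_fbm_landscape(
    n_rows: int,
    n_cols: int,
    cell_size: float,
    hurst: float = 0.5,
    seed: int = 0,
    origin_x: float = 0.0,
    origin_y: float = 0.0,
) -> LandscapeRaster:
    """Generate a standardised fBm habitat raster.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape (>= 2 each).
    cell_size
        Cell edge length in metres.
    hurst
        Fractal exponent H in (0, 1); semivariance scales as lag**(2H).
    seed
        RNG seed; output is bit-identical for a fixed seed.
    """
    if not (0.0 < hurst < 1.0):
        raise ParameterError(f"hurst must lie in (0, 1), got {hurst}")
    if n_rows < 2 or n_cols < 2:
        raise ParameterError("n_rows and n_cols must be >= 2")
    if cell_size <= 0:
        raise ParameterError("cell_size must be positive")
    rng = np.random.default_rng(seed)
    vals = _spectral_fbm(int(n_rows), int(n_cols), float(hurst), rng)
    vals = (vals - vals.mean()) / vals.std()
    return LandscapeRaster(
        origin_x=origin_x,
        origin_y=origin_y,
        cell_size=float(cell_size),
        n_rows=int(n_rows),
        n_cols=int(n_cols),
        values=vals,
        hurst=float(hurst),
        seed=int(seed),
    )


class OutOfBoundsError(ValueError):
    """Query point outside the raster extent."""


def _cell_index(raster: LandscapeRaster, x: float, y: float) -> tuple[int, int]:
    col = int(np.floor((x - raster.origin_x) / raster.cell_size))
    row = int(np.floor((y - raster.origin_y) / raster.cell_size))
    return row, col


def sample_covariate(raster: LandscapeRaster, x: float, y: float) -> float:
    """Nearest-cell covariate lookup; raises OutOfBoundsError outside the extent."""
    xmin, ymin, xmax, ymax = raster.extent
    if not (xmin <= x < xmax and ymin <= y < ymax):
        raise OutOfBoundsError(f"point ({x}, {y}) outside raster extent {raster.extent}")
    row, col = _cell_index(raster, x, y)
    return float(raster.values[row, col])


def sample_covariate_clamped(raster: LandscapeRaster, x: float, y: float) -> float:
    """Covariate lookup with out-of-extent points clamped to the nearest edge cell."""
    row, col = _cell_index(raster, x, y)
    row = min(max(row, 0), raster.n_rows - 1)
    col = min(max(col, 0), raster.n_cols - 1)
    return float(raster.values[row, col])


def write_ascii_grid(raster: LandscapeRaster, path, nodata: float = -9999.0) -> None:
    """Write an ESRI ASCII grid (.asc); northmost row first in the file."""
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {raster.origin_x:.6f}\n")
        fh.write(f"yllcorner {raster.origin_y:.6f}\n")
        fh.write(f"cellsize {raster.cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, raster.values[::-1], fmt="%.10g")


def read_ascii_grid(path, hurst: float = 0.5) -> LandscapeRaster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)[::-1].copy()
    return LandscapeRaster(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        values=vals,
        hurst=hurst,
    )
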