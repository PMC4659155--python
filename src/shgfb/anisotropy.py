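"""Ensemble fiber-orientation anisotropy from the Fourier spectrum.

A field of fibers sharing one orientation concentrates spectral energy along
the line through the origin perpendicular to the fiber axis; an isotropic
field spreads it over a disk.  The statistic here is the R² of an ordinary
least-squares line fitted to the coordinates of the bright spectrum pixels:
near 1 for a strongly aligned ensemble (off-axis orientations), near 0 for
an isotropic one.

Conventions (the threshold of 20 presumes an 8-bit display scale, which the
source material leaves unspecified; all three choices below are this
package's reconstruction):

* the spectrum is the centred magnitude of the 2-D DFT, displayed on an
  8-bit scale — by default mapped LINEARLY onto [0, 255] (the standard
  Matlab magnitude display); a log(1+magnitude) mapping and the raw
  magnitude are available as alternatives;
* the DC (zero-frequency) pixel carries no orientation information, would
  dominate any scale, and is excluded from both the display normalisation
  and the binarization;
* the regression is unweighted OLS of row on column.  Because R² of a
  simple regression equals the squared correlation, it is blind to point
  sets elongated along an image axis (a vertical or horizontal band has
  correlation ~0): fibers parallel to an image axis score low no matter
  which variable is regressed on which.  `symmetrize=True` therefore also
  evaluates R² on the point set rotated 45° about the spectrum centre and
  reports the larger value, which removes that blind spot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fb import ProjectedImage

DEFAULT_SPECTRUM_THRESHOLD = 20.0

SCALING_MODES = ("linear8bit", "log8bit", "raw_magnitude")


class DegenerateSpectrumError(ValueError):
    """Too few / collapsed spectrum points: anisotropy undefined."""


@dataclass
class SpectrumPointSet:
    """Coordinates (row, col) of above-threshold spectrum pixels."""

    coordinates: np.ndarray  # (n, 2) int array
    threshold_used: float
    scaling_mode: str
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=int).reshape(-1, 2)
        if len(self.coordinates):
            r, c = self.coordinates[:, 0], self.coordinates[:, 1]
            if (r < 0).any() or (c < 0).any() or (r >= self.shape[0]).any() or (c >= self.shape[1]).any():
                raise ValueError("spectrum point outside image bounds")

    @property
    def n_points(self) -> int:
        return len(self.coordinates)


@dataclass
class AnisotropyResult:
    r_squared: float
    n_points: int
    regression_slope: float
    regression_intercept: float
    symmetrized: bool = False

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("R^2 outside [0, 1]")
        self.r_squared = float(min(max(self.r_squared, 0.0), 1.0))


def _dc_index(shape: tuple[int, int]) -> tuple[int, int]:
    # centre pixel after fftshift
    return (shape[0] // 2, shape[1] // 2)


def fft_spectrum(image: ProjectedImage | np.ndarray, scaling_mode: str = "linear8bit") -> np.ndarray:
    """Centred magnitude spectrum of a forward-channel image, on the chosen
    display scale.  The DC pixel is zeroed so it never enters the
    normalisation or the downstream binarization."""
    pixels = image.pixels if isinstance(image, ProjectedImage) else np.asarray(image, dtype=float)
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValueError("image must be a nonempty 2-D array")
    if scaling_mode not in SCALING_MODES:
        raise ValueError(f"scaling_mode must be one of {SCALING_MODES}")
    mag = np.abs(np.fft.fftshift(np.fft.fft2(pixels)))
    mag[_dc_index(mag.shape)] = 0.0
    if scaling_mode == "raw_magnitude":
        return mag
    if scaling_mode == "log8bit":
        mag = np.log1p(mag)
    peak = mag.max()
    if peak > 0:
        mag = mag * (255.0 / peak)
    return mag


def binarize_spectrum(
    spectrum: np.ndarray,
    threshold: float = DEFAULT_SPECTRUM_THRESHOLD,
    scaling_mode: str = "linear8bit",
) -> SpectrumPointSet:
    """Coordinates of spectrum pixels strictly greater than the threshold,
    DC excluded.  An empty set is valid (flat image)."""
    spectrum = np.asarray(spectrum, dtype=float)
    above = spectrum > threshold
    above[_dc_index(spectrum.shape)] = False
    coords = np.argwhere(above)
    return SpectrumPointSet(coordinates=coords, threshold_used=threshold,
                            scaling_mode=scaling_mode, shape=spectrum.shape)


def _ols_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(x, y)
    return res.rvalue ** 2, res.slope, res.intercept


def anisotropy_r2(points: SpectrumPointSet, symmetrize: bool = False) -> AnisotropyResult:
    """OLS of row-coordinate on column-coordinate over the bright spectrum
    points; R² is the anisotropy statistic.

    With ``symmetrize=True`` the regression is also run on the point set
    rotated 45° about the spectrum centre and the larger R² is reported
    (see module docstring: the plain statistic cannot see bands parallel to
    an image axis).  Fewer than 3 points, or zero variance in the
    regressor, make the statistic undefined and raise
    DegenerateSpectrumError (such a sample is flagged, not scored).
    """
    if points.n_points < 3:
        raise DegenerateSpectrumError(
            f"anisotropy undefined: only {points.n_points} spectrum points"
        )
    rows = points.coordinates[:, 0].astype(float)
    cols = points.coordinates[:, 1].astype(float)
    if not symmetrize:
        if cols.var() == 0:
            raise DegenerateSpectrumError("anisotropy undefined: zero variance in column coordinate")
        r2, slope, intercept = _ols_r2(cols, rows)
        return AnisotropyResult(r2, points.n_points, slope, intercept, symmetrized=False)
    cy, cx = _dc_index(points.shape)
    u, v = rows - cy, cols - cx
    # unnormalised 45-degree rotation; R^2 is scale-invariant
    frames = [(cols, rows), (v - u, v + u)]
    candidates = [_ols_r2(x, y) for x, y in frames if x.var() > 0]
    if not candidates:
        raise DegenerateSpectrumError("anisotropy undefined: point set collapsed to one pixel")
    best = max(candidates, key=lambda t: t[0])
    return AnisotropyResult(best[0], points.n_points, best[1], best[2], symmetrized=True)


def image_anisotropy(
    image: ProjectedImage | np.ndarray,
    threshold: float = DEFAULT_SPECTRUM_THRESHOLD,
    scaling_mode: str = "linear8bit",
    symmetrize: bool = False,
) -> AnisotropyResult:
    """Full chain: spectrum → binarize → regression R²."""
    spec = fft_spectrum(image, scaling_mode)
    points = binarize_spectrum(spec, threshold, scaling_mode)
    return anisotropy_r2(points, symmetrize=symmetrize)
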