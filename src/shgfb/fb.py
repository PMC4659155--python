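"""Average F/B ratio quantification from paired forward/backward SHG stacks.

The measurement chain per imaged location:

1. maximum-intensity projection of the 11-frame forward and backward stacks
   ("auto-focus": tissue sections are a single collagen layer thick);
2. subtraction of the closed-shutter background (projected noise stack,
   per-pixel by default; a scalar mean level is the alternative reading),
   negative results clamped to zero;
3. a common intensity threshold (default 40 of the 4095-count range) applied
   to BOTH channels, strictly greater-than; the two binary masks are
   multiplied into one forward×backward mask;
4. the pixel-wise F/B ratio image, restricted to the combined mask;
5. detector-gain normalisation from the session's daily FITC calibration,
   applied multiplicatively to the ratio (equivalent to calibrating F and B
   separately; masking sees raw counts because the threshold is stated in
   raw counts);
6. the arithmetic mean of the masked ratios is the location's F/B; a
   sample's F/B is the mean over its imaged locations (one for TMA cores,
   three for large sections) and ln F/B its natural log.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .image_io import ScanStack, read_stack

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 40  # counts, out of 4095


class NoFibersError(ValueError):
    """No pixel passed both channel thresholds: nothing to ratio."""


@dataclass
class ProjectedImage:
    """Maximum-intensity projection of one channel at one location."""

    pixels: np.ndarray  # 2-D float64, non-negative
    channel: str
    background_corrected: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("projected image must be 2-D")
        if self.pixels.min(initial=0.0) < 0:
            raise ValueError("projected image has negative pixels")


@dataclass
class BackgroundModel:
    """Closed-shutter background: per-pixel projected noise image, or its
    scalar mean."""

    value: np.ndarray | float
    mode: str  # "per_pixel" | "scalar"
    channel: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("per_pixel", "scalar"):
            raise ValueError(f"unknown background mode {self.mode!r}")
        if self.mode == "scalar":
            self.value = float(self.value)
            if self.value < 0:
                raise ValueError("background must be >= 0")
        else:
            self.value = np.asarray(self.value, dtype=np.float64)
            if self.value.ndim != 2 or (self.value < 0).any():
                raise ValueError("per-pixel background must be a non-negative 2-D array")


@dataclass
class FBMask:
    pixels: np.ndarray  # 2-D uint8 in {0,1}
    threshold_used: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if not np.isin(self.pixels, (0, 1)).all():
            raise ValueError("mask must be strictly binary")
        self.pixels = self.pixels.astype(np.uint8)

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())


@dataclass
class CalibrationFactors:
    """Per-detector multiplicative normalisation from the daily FITC standard:
    factor = reference_signal / measured mean signal."""

    factor_forward: float
    factor_backward: float
    session_id: str = ""

    def __post_init__(self) -> None:
        if not (self.factor_forward > 0 and self.factor_backward > 0):
            raise ValueError("calibration factors must be strictly positive")


UNIT_CALIBRATION = CalibrationFactors(1.0, 1.0, session_id="unit")


@dataclass
class FBResult:
    """A sample's average F/B with provenance."""

    sample_id: str
    mean_fb: float
    ln_fb: float
    n_pixels_retained: int
    n_locations: int
    per_location_fb: list[float]
    session_id: str = ""

    def __post_init__(self) -> None:
        if not self.mean_fb > 0:
            raise ValueError("mean F/B must be positive")
        if not math.isclose(self.ln_fb, math.log(self.mean_fb), rel_tol=1e-12, abs_tol=1e-12):
            raise ValueError("ln_fb must be the natural log of mean_fb")


# ---------------------------------------------------------------------------
# operations

def max_project(stack: ScanStack) -> ProjectedImage:
    """Maximum-intensity projection over frames."""
    if stack.n_frames < 1:
        raise ValueError("empty stack")
    return ProjectedImage(
        pixels=stack.frames.max(axis=0).astype(np.float64),
        channel=stack.channel,
        background_corrected=False,
    )


def estimate_background(noise_stack: ScanStack, mode: str = "per_pixel") -> BackgroundModel:
    """Background from a closed-shutter stack.

    per_pixel: the maximum-intensity projection of the noise stack.
    scalar: the mean of that projection.
    """
    proj = max_project(noise_stack).pixels
    if mode == "per_pixel":
        return BackgroundModel(value=proj, mode=mode, channel=noise_stack.channel)
    if mode == "scalar":
        return BackgroundModel(value=float(proj.mean()), mode=mode, channel=noise_stack.channel)
    raise ValueError(f"unknown background mode {mode!r}")


def subtract_background(image: ProjectedImage, background: BackgroundModel) -> ProjectedImage:
    """Pixel-wise background subtraction, clamped at zero."""
    if background.mode == "per_pixel":
        bg = np.asarray(background.value)
        if bg.shape != image.pixels.shape:
            raise ValueError(
                f"background shape {bg.shape} does not match image shape {image.pixels.shape}"
            )
    else:
        bg = background.value
    corrected = np.maximum(image.pixels - bg, 0.0)
    return ProjectedImage(pixels=corrected, channel=image.channel, background_corrected=True)


def make_mask(image: ProjectedImage, threshold: float = DEFAULT_THRESHOLD) -> FBMask:
    """Binary fiber mask: pixel = 1 iff value > threshold (strict)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if not image.background_corrected:
        raise ValueError("mask must be computed on a background-corrected image")
    return FBMask(pixels=(image.pixels > threshold).astype(np.uint8), threshold_used=threshold)


def combine_masks(mask_f: FBMask, mask_b: FBMask) -> FBMask:
    """The forward×backward mask: 1 only where both channel masks are 1."""
    if mask_f.pixels.shape != mask_b.pixels.shape:
        raise ValueError("mask dimensions differ")
    if mask_f.threshold_used != mask_b.threshold_used:
        raise ValueError("masks were computed at different thresholds")
    return FBMask(pixels=mask_f.pixels * mask_b.pixels, threshold_used=mask_f.threshold_used)


def compute_calibration(
    cal_forward: ScanStack,
    cal_backward: ScanStack,
    reference: dict[str, float],
    session_id: str = "",
) -> CalibrationFactors:
    """Normalisation factors from the daily FITC standard image pair.

    factor_channel = reference[channel] / mean(projected calibration image).
    Applying the factors to the calibration measurement itself reproduces the
    reference signal.
    """
    means = {}
    for stack in (cal_forward, cal_backward):
        m = float(max_project(stack).pixels.mean())
        if m <= 0:
            raise ValueError(f"calibration image for {stack.channel} channel has zero mean signal")
        means[stack.channel] = m
    if set(means) != {"forward", "backward"}:
        raise ValueError("calibration pair must contain one forward and one backward stack")
    return CalibrationFactors(
        factor_forward=reference["forward"] / means["forward"],
        factor_backward=reference["backward"] / means["backward"],
        session_id=session_id,
    )


def fb_from_pair(
    f_img: ProjectedImage,
    b_img: ProjectedImage,
    threshold: float = DEFAULT_THRESHOLD,
    calibration: CalibrationFactors = UNIT_CALIBRATION,
    sample_id: str = "",
) -> tuple[float, int]:
    """Average F/B of one location from its background-corrected image pair.

    Masks are taken on the raw-count (uncalibrated) images; the calibration
    enters as a single multiplicative factor on the ratio.  Returns
    (mean ratio over combined-mask pixels, number of retained pixels).
    """
    if not (f_img.background_corrected and b_img.background_corrected):
        raise ValueError("images must be background-corrected before ratioing")
    if f_img.pixels.shape != b_img.pixels.shape:
        raise ValueError("forward and backward images differ in shape")
    mask = combine_masks(make_mask(f_img, threshold), make_mask(b_img, threshold))
    n = mask.n_pixels
    if n == 0:
        raise NoFibersError(
            f"no fibers detected{f' in sample {sample_id}' if sample_id else ''}: "
            f"no pixel exceeds threshold {threshold} in both channels"
        )
    sel = mask.pixels.astype(bool)
    ratio = f_img.pixels[sel] / b_img.pixels[sel]  # b > threshold >= 0 inside mask
    cal = calibration.factor_forward / calibration.factor_backward
    return float(ratio.mean() * cal), n


def sample_fb(
    sample_id: str,
    locations: Sequence[tuple[ScanStack, ScanStack]],
    noise: dict[str, ScanStack],
    calibration: CalibrationFactors = UNIT_CALIBRATION,
    threshold: float = DEFAULT_THRESHOLD,
    background_mode: str = "per_pixel",
) -> FBResult:
    """A sample's average F/B over its imaged locations.

    Each location runs the full chain (project, subtract background, mask,
    ratio, calibrate, mean); the per-location F/B values are then averaged
    arithmetically.  Locations in which no pixel passes both thresholds are
    dropped with a warning; a sample with no usable location is an error
    (never scored F/B = 0, which is not a valid ratio).
    """
    if len(locations) == 0:
        raise ValueError(f"sample {sample_id}: no locations")
    backgrounds = {ch: estimate_background(stk, background_mode) for ch, stk in noise.items()}
    per_loc: list[float] = []
    n_pixels_total = 0
    for i, (f_stack, b_stack) in enumerate(locations):
        if f_stack.shape != b_stack.shape:
            raise ValueError(f"sample {sample_id} location {i}: channel dimensions differ")
        f_img = subtract_background(max_project(f_stack), backgrounds["forward"])
        b_img = subtract_background(max_project(b_stack), backgrounds["backward"])
        try:
            fb, n_pix = fb_from_pair(f_img, b_img, threshold, calibration, sample_id=sample_id)
        except NoFibersError:
            logger.warning("sample %s: location %d dropped (no pixels above threshold)",
                           sample_id, i)
            continue
        per_loc.append(fb)
        n_pixels_total += n_pix
    if not per_loc:
        raise NoFibersError(f"sample {sample_id}: all {len(locations)} locations had empty masks")
    mean_fb = float(np.mean(per_loc))
    return FBResult(
        sample_id=sample_id,
        mean_fb=mean_fb,
        ln_fb=math.log(mean_fb),
        n_pixels_retained=n_pixels_total,
        n_locations=len(per_loc),
        per_location_fb=per_loc,
        session_id=calibration.session_id,
    )


def process_session(
    manifest_path,
    threshold: float = DEFAULT_THRESHOLD,
    background_mode: str = "per_pixel",
):
    """Compute F/B for every sample listed in a session manifest.

    Returns a pandas DataFrame with one row per sample: sample_id,
    per-location fb values, mean_fb, ln_fb, n_pixels.
    """
    import pandas as pd

    from .image_io import read_manifest

    meta, locations = read_manifest(manifest_path)
    noise = {ch: read_stack(p, ch, session_id=meta.session_id)
             for ch, p in meta.noise_stack_paths.items()}
    cal = compute_calibration(
        read_stack(meta.calibration_pair_paths["forward"], "forward"),
        read_stack(meta.calibration_pair_paths["backward"], "backward"),
        meta.reference_calibration_signal,
        session_id=meta.session_id,
    )
    by_sample: dict[str, list[tuple[ScanStack, ScanStack]]] = {}
    for loc in locations:
        pair = (
            read_stack(loc["forward"], "forward", session_id=meta.session_id,
                       location_id=loc["location_id"]),
            read_stack(loc["backward"], "backward", session_id=meta.session_id,
                       location_id=loc["location_id"]),
        )
        by_sample.setdefault(loc["sample_id"], []).append(pair)
    rows = []
    for sample_id, pairs in by_sample.items():
        res = sample_fb(sample_id, pairs, noise, cal, threshold, background_mode)
        rows.append({
            "sample_id": sample_id,
            "per_location_fb": ";".join(f"{v:.6g}" for v in res.per_location_fb),
            "mean_fb": res.mean_fb,
            "ln_fb": res.ln_fb,
            "n_pixels": res.n_pixels_retained,
            "n_locations": res.n_locations,
        })
    return pd.DataFrame(rows)
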