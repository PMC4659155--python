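"""Synthetic inputs for every pipeline stage.

No public dataset of paired forward/backward SHG stacks with clinical
follow-up exists, so this module fabricates each input with known ground
truth:

* fiber fields — straight anti-aliased thick segments with von Mises
  orientations, rendered into 11-frame focal stacks whose out-of-focus
  frames are attenuated (so maximum projection recovers the in-focus
  plane); the backward channel carries the fiber intensity and the forward
  channel carries intensity x true_fb, so the per-pixel ratio is known
  exactly;
* closed-shutter noise stacks and constant FITC-like calibration images
  with controllable per-detector gain;
* patient cohorts whose hazard depends log-linearly on ln F/B, with
  clinical covariates drawn at realistic prevalences.

All generators are pure functions of (spec, seed): identical inputs give
bit-identical outputs.

Numerical conventions that keep ground truth exact under 12-bit
quantization: fiber coverage is computed on a 4x4 subpixel grid, so it is
an exact multiple of 1/16; the default fiber intensity (1600 counts) is a
multiple of 16, making coverage x intensity an exact integer; detector
gains drawn with :func:`random_gain` live on a discrete grid chosen so
gain x count is still an exact integer.  Under these conventions a noise-free field is recovered by the
measurement chain with zero error, and gain sweeps test the calibration
algebra rather than rounding noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .image_io import MAX_COUNT, PatientRecord, ScanStack

_SUPERSAMPLE = 4  # subpixel grid per axis; coverage is a multiple of 1/16


@dataclass
class FiberFieldSpec:
    """One imaged location of a fibrous specimen."""

    shape: tuple[int, int] = (256, 256)
    n_fibers: int = 30
    mean_angle_deg: float = 45.0
    kappa: float = 50.0          # von Mises concentration; 0 = isotropic
    fiber_length: float = 180.0  # px
    fiber_width: float = 4.0     # px
    intensity: int = 1600        # backward-channel fiber counts
    true_fb: float = 2.0         # forward = intensity * true_fb
    offset: int = 0              # background counts added to both channels
    noise: str = "none"          # "none" | "poisson" | "gaussian"
    gaussian_sigma: float = 5.0
    gain_forward: float = 1.0    # detector gains (see random_gain)
    gain_backward: float = 1.0
    n_frames: int = 11
    focus_frame: int = 5
    defocus_attenuation: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.true_fb > 0:
            raise ValueError("true_fb must be positive")
        if self.noise not in ("none", "poisson", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        peak_b = self.intensity * self.gain_backward + self.offset
        peak_f = self.intensity * self.true_fb * self.gain_forward + self.offset
        if max(peak_b, peak_f) > MAX_COUNT:
            raise ValueError(
                f"spec exceeds the {MAX_COUNT}-count ceiling "
                f"(forward peak {peak_f:.0f}, backward peak {peak_b:.0f}); "
                "lower intensity, gain or true_fb"
            )
        if not 0 <= self.focus_frame < self.n_frames:
            raise ValueError("focus_frame outside stack")


@dataclass
class CohortSpec:
    """A simulated patient cohort with hazard log-linear in ln F/B.

    Defaults place ln F/B at the observed population location and spread
    (median 2.228, IQR 0.416, hence SD 0.416/1.349 under normality) and use
    per-endpoint log hazard ratios matching the reported continuous-marker
    effects in ER+ disease (MFS HR~0.23, OS HR~0.34, PFS HR~3.4 per unit
    ln F/B); ER- patients get beta_er_neg (default 0, the reported null).
    Times are months.
    """

    n_patients: int = 221
    ln_fb_mean: float = 2.228
    ln_fb_sd: float = 0.416 / 1.349
    baseline_rate: float = 0.004          # events/month at ln F/B = mean
    beta_mfs: float = -1.5
    beta_os: float = -1.1
    beta_pfs: float = 1.2
    beta_er_neg: float = 0.0
    other_cause_rate: float = 0.002       # deaths without disease, /month
    horizon: float = 120.0                # administrative censoring, months
    dropout_max: Optional[float] = None   # uniform(0, dropout_max) dropout
    er_pos_frac: float = 0.566
    os_rule: str = "censor_disease_free_deaths"  # or "all_cause"
    missing_grade_frac: float = 6 / 221
    covariate_prevalences: dict = field(default_factory=lambda: {
        "age_band": {"<=40": 0.149, "41-55": 0.425, "56-70": 0.317, ">70": 0.109},
        "menopausal": {"pre": 0.511, "post": 0.489},
        "size_band": {"pT1": 0.493, "pT2": 0.475, "pT3/4": 0.032},
        "grade": {"I": 0.172, "II": 0.358, "III": 0.470},
        "pgr": {"pos": 0.471, "neg": 0.529},
        "her2": {"pos": 0.118, "neg": 0.882},
    })
    seed: int = 0

    def __post_init__(self) -> None:
        if self.os_rule not in ("censor_disease_free_deaths", "all_cause"):
            raise ValueError(f"unknown os_rule {self.os_rule!r}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


# ---------------------------------------------------------------------------
# fiber fields

def _fiber_coverage(spec: FiberFieldSpec, rng: np.random.Generator) -> np.ndarray:
    """Subpixel area coverage of the fiber union, an exact multiple of 1/16."""
    h, w = spec.shape
    centers = rng.uniform(low=(0, 0), high=(h, w), size=(spec.n_fibers, 2))
    if spec.kappa > 0:
        angles = rng.vonmises(math.radians(spec.mean_angle_deg), spec.kappa,
                              size=spec.n_fibers)
    else:
        angles = rng.uniform(-math.pi, math.pi, size=spec.n_fibers)
    half_len = spec.fiber_length / 2.0
    half_w = spec.fiber_width / 2.0
    offs = (np.arange(_SUPERSAMPLE) + 0.5) / _SUPERSAMPLE - 0.5
    count = np.zeros(spec.shape, dtype=np.int32)
    pad = half_w + 1.0
    for oy in offs:
        for ox in offs:
            inside = np.zeros(spec.shape, dtype=bool)
            for (cy, cx), ang in zip(centers, angles):
                uy, ux = math.sin(ang), math.cos(ang)
                y0 = max(0, int(math.floor(cy - abs(uy) * half_len - pad)))
                y1 = min(h, int(math.ceil(cy + abs(uy) * half_len + pad)) + 1)
                x0 = max(0, int(math.floor(cx - abs(ux) * half_len - pad)))
                x1 = min(w, int(math.ceil(cx + abs(ux) * half_len + pad)) + 1)
                if y0 >= y1 or x0 >= x1:
                    continue
                Y = np.arange(y0, y1, dtype=float)[:, None] + oy - cy
                X = np.arange(x0, x1, dtype=float)[None, :] + ox - cx
                t = np.clip(Y * uy + X * ux, -half_len, half_len)
                d2 = (Y - t * uy) ** 2 + (X - t * ux) ** 2
                inside[y0:y1, x0:x1] |= d2 <= half_w**2
            count += inside
    return count / float(_SUPERSAMPLE**2)


def _render_stack(base: np.ndarray, spec: FiberFieldSpec, channel: str,
                  rng: np.random.Generator) -> ScanStack:
    """Focal stack from an in-focus expectation image (fiber signal only)."""
    frames = np.empty((spec.n_frames, *spec.shape), dtype=np.uint16)
    for i in range(spec.n_frames):
        atten = spec.defocus_attenuation ** abs(i - spec.focus_frame)
        expected = base * atten + spec.offset
        if spec.noise == "poisson":
            vals = rng.poisson(expected).astype(float)
        elif spec.noise == "gaussian":
            vals = expected + rng.normal(0.0, spec.gaussian_sigma, size=expected.shape)
        else:
            vals = expected
        frames[i] = np.clip(np.rint(vals), 0, MAX_COUNT).astype(np.uint16)
    return ScanStack(frames=frames, channel=channel,
                     session_id=f"sim-{spec.seed}", location_id="loc0")


def generate_fiber_pair(spec: FiberFieldSpec) -> tuple[ScanStack, ScanStack, np.ndarray]:
    """Paired forward/backward stacks plus the per-pixel truth ratio map
    (true_fb on fiber pixels, NaN elsewhere)."""
    rng = np.random.default_rng(spec.seed)
    coverage = _fiber_coverage(spec, rng)
    base_b = coverage * (spec.intensity * spec.gain_backward)
    base_f = coverage * (spec.intensity * spec.true_fb * spec.gain_forward)
    # independent noise streams, but shared geometry
    b_stack = _render_stack(base_b, spec, "backward", rng)
    f_stack = _render_stack(base_f, spec, "forward", rng)
    truth = np.where(coverage > 0, spec.true_fb, np.nan)
    return f_stack, b_stack, truth


def generate_isotropic_noise_image(
    shape: tuple[int, int] = (256, 256),
    smooth_sigma: float = 3.0,
    level: int = 800,
    seed: int = 0,
) -> np.ndarray:
    """Smoothed random field with no preferred orientation (a stand-in for
    an unstructured specimen), scaled to [0, level] counts."""
    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.normal(size=shape), smooth_sigma)
    img -= img.min()
    if img.max() > 0:
        img *= level / img.max()
    return np.rint(img).astype(float)


# ---------------------------------------------------------------------------
# noise and calibration fixtures

def generate_noise_stack(
    level: float = 3.0,
    sigma: float = 1.0,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    n_frames: int = 11,
    channel: str = "forward",
) -> ScanStack:
    """Closed-shutter stack: clipped Gaussian counts around the dark level."""
    if level < 0:
        raise ValueError("level must be >= 0")
    rng = np.random.default_rng(seed)
    vals = rng.normal(level, sigma, size=(n_frames, *shape)) if sigma > 0 \
        else np.full((n_frames, *shape), float(level))
    frames = np.clip(np.rint(vals), 0, MAX_COUNT).astype(np.uint16)
    return ScanStack(frames=frames, channel=channel, session_id=f"noise-{seed}")


def generate_calibration_pair(
    gain_forward: float = 1.0,
    gain_backward: float = 1.0,
    base_signal: int = 1000,
    shape: tuple[int, int] = (64, 64),
    n_frames: int = 11,
    seed: int = 0,
) -> tuple[ScanStack, ScanStack]:
    """Daily-standard image pair: each detector sees gain x base_signal.

    Gains are snapped to the 0.01 grid so the recorded counts are exact.
    """
    vals = {}
    for ch, g in (("forward", gain_forward), ("backward", gain_backward)):
        v = round(round(g * 100) / 100 * base_signal)
        if not 0 < v <= MAX_COUNT:
            raise ValueError(f"calibration signal {v} for {ch} outside (0, {MAX_COUNT}]")
        vals[ch] = v
    mk = lambda ch: ScanStack(
        frames=np.full((n_frames, *shape), vals[ch], dtype=np.uint16),
        channel=ch, session_id=f"cal-{seed}")
    return mk("forward"), mk("backward")


def random_gain(rng: np.random.Generator, low: float = 0.5, high: float = 2.0,
                step: float = 0.02) -> float:
    """A detector gain drawn uniformly on a discrete grid in [low, high].

    The default 0.02 step keeps gain x count integral for fiber intensities
    that are multiples of 800, so gain sweeps probe the calibration algebra
    rather than count rounding.
    """
    k = int(round(1.0 / step))
    return int(rng.integers(round(low * k), round(high * k) + 1)) / k


# ---------------------------------------------------------------------------
# cohorts

def _draw_categorical(rng, levels_probs: dict, n: int) -> np.ndarray:
    levels = list(levels_probs)
    p = np.array([levels_probs[l] for l in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(levels, size=n, p=p)


def _censored_times(rng, rates: np.ndarray, horizon: float,
                    dropout_max: Optional[float]) -> tuple[np.ndarray, np.ndarray]:
    t = rng.exponential(1.0 / rates)
    c = np.full_like(t, horizon)
    if dropout_max is not None:
        c = np.minimum(c, rng.uniform(0, dropout_max, size=len(t)))
    return np.minimum(t, c), (t <= c).astype(int)


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Simulate a cohort whose event hazards are exponential with rate
    baseline_rate * exp(beta * (ln F/B - population mean)).

    MFS, OS and PFS use their own betas (see CohortSpec).  OS additionally
    mixes in an independent other-cause death process; under the default
    rule a death without disease censors the patient at that time, under
    "all_cause" it counts as an event.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    ln_fb = rng.normal(spec.ln_fb_mean, spec.ln_fb_sd, size=n)
    er = rng.choice(["pos", "neg"], size=n,
                    p=[spec.er_pos_frac, 1 - spec.er_pos_frac])
    covs = {k: _draw_categorical(rng, v, n) for k, v in spec.covariate_prevalences.items()}
    grade_missing = rng.random(n) < spec.missing_grade_frac
    centered = ln_fb - spec.ln_fb_mean

    def rates(beta_pos: float) -> np.ndarray:
        beta = np.where(er == "pos", beta_pos, spec.beta_er_neg)
        return spec.baseline_rate * np.exp(beta * centered)

    mfs_time, mfs_event = _censored_times(rng, rates(spec.beta_mfs),
                                          spec.horizon, spec.dropout_max)
    pfs_time, pfs_event = _censored_times(rng, rates(spec.beta_pfs),
                                          spec.horizon, spec.dropout_max)

    # overall survival: disease deaths (marker-dependent) vs other-cause deaths
    t_disease = rng.exponential(1.0 / rates(spec.beta_os))
    t_other = rng.exponential(1.0 / spec.other_cause_rate, size=n)
    c = np.full(n, spec.horizon)
    if spec.dropout_max is not None:
        c = np.minimum(c, rng.uniform(0, spec.dropout_max, size=n))
    if spec.os_rule == "all_cause":
        death = np.minimum(t_disease, t_other)
        os_time = np.minimum(death, c)
        os_event = (death <= c).astype(int)
    else:  # deaths without evidence of disease censor at that time
        cens = np.minimum(c, t_other)
        os_time = np.minimum(t_disease, cens)
        os_event = (t_disease <= cens).astype(int)

    records = []
    for i in range(n):
        records.append(PatientRecord(
            patient_id=f"P{i:04d}",
            ln_fb=float(ln_fb[i]),
            mfs_time=float(mfs_time[i]), mfs_event=int(mfs_event[i]),
            os_time=float(os_time[i]), os_event=int(os_event[i]),
            pfs_time=float(pfs_time[i]), pfs_event=int(pfs_event[i]),
            age_band=str(covs["age_band"][i]),
            menopausal=str(covs["menopausal"][i]),
            size_band=str(covs["size_band"][i]),
            grade=None if grade_missing[i] else str(covs["grade"][i]),
            er=str(er[i]), pgr=str(covs["pgr"][i]), her2=str(covs["her2"][i]),
        ))
    return records


# ---------------------------------------------------------------------------
# whole-session fixture on disk

def simulate_session(
    out_dir: str | Path,
    n_samples: int = 4,
    locations_per_sample: int = 1,
    gain_forward: float = 1.0,
    gain_backward: float = 1.0,
    intensity: int = 160,
    noise: str = "poisson",
    offset: int = 3,
    shape: tuple[int, int] = (256, 256),
    reference_signal: float = 1000.0,
    seed: int = 0,
) -> Path:
    """Write a complete session directory: per-sample stacks drawn with
    sample-level true F/B ~ lognormal at the population location/spread,
    a closed-shutter noise stack and a calibration pair per channel, a JSON
    manifest, and truth.csv with each sample's stipulated ratio.

    Returns the manifest path.  The default intensity (160 counts in the
    backward channel) leaves headroom for forward = intensity x F/B under
    the 12-bit ceiling at realistic F/B values.
    """
    import pandas as pd

    from .image_io import SessionMeta, write_manifest, write_stack

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    session_id = f"session-{seed}"

    noise_paths, cal_paths = {}, {}
    for ch, chan_seed in (("forward", 11), ("backward", 12)):
        stk = generate_noise_stack(level=offset, sigma=1.0, seed=seed * 1000 + chan_seed,
                                   shape=shape, channel=ch)
        noise_paths[ch] = f"noise_{ch}.tif"
        write_stack(stk, out / noise_paths[ch])
    cal_f, cal_b = generate_calibration_pair(gain_forward, gain_backward, seed=seed)
    for ch, stk in (("forward", cal_f), ("backward", cal_b)):
        cal_paths[ch] = f"calibration_{ch}.tif"
        write_stack(stk, out / cal_paths[ch])

    locations, truth_rows = [], []
    ceiling = (MAX_COUNT - offset) / (intensity * max(gain_forward, gain_backward, 1.0))
    for s in range(n_samples):
        true_fb = float(np.clip(rng.lognormal(2.228, 0.416 / 1.349), 0.2, ceiling * 0.95))
        truth_rows.append({"sample_id": f"S{s:03d}", "true_fb": true_fb,
                           "true_ln_fb": math.log(true_fb)})
        for loc in range(locations_per_sample):
            spec = FiberFieldSpec(
                shape=shape, intensity=intensity, true_fb=true_fb, offset=offset,
                noise=noise, gain_forward=gain_forward, gain_backward=gain_backward,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            f_stack, b_stack, _ = generate_fiber_pair(spec)
            f_name = f"S{s:03d}_loc{loc}_forward.tif"
            b_name = f"S{s:03d}_loc{loc}_backward.tif"
            write_stack(f_stack, out / f_name)
            write_stack(b_stack, out / b_name)
            locations.append({"sample_id": f"S{s:03d}", "location_id": f"loc{loc}",
                              "forward": f_name, "backward": b_name})

    meta = SessionMeta(
        session_id=session_id,
        noise_stack_paths=noise_paths,
        calibration_pair_paths=cal_paths,
        reference_calibration_signal={"forward": reference_signal,
                                      "backward": reference_signal},
    )
    manifest = out / "manifest.json"
    write_manifest(manifest, meta, locations)
    pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False)
    return manifest
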