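"""Reading and writing the pipeline's on-disk inputs.

Image stacks are multi-page 16-bit grayscale TIFFs carrying 12-bit photon
counts (0–4095); a value above 4095 indicates an acquisition fault and is an
error, never a clip.  A *session* (one microscope day) is a directory with a
JSON manifest listing, per detector channel, the closed-shutter noise stack,
the FITC calibration stack, the calibration reference signal, and the
per-location forward/backward sample stacks.

Cohort tables are UTF-8 CSV with one row per patient; clinical covariates use
the fixed categorical vocabularies below and unknown labels are rejected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

MAX_COUNT = 4095  # 12-bit detector ceiling, in a 16-bit container

CHANNELS = ("forward", "backward")

#: categorical vocabulary of the clinical covariates
AGE_BANDS = ("<=40", "41-55", "56-70", ">70")
MENOPAUSAL = ("pre", "post")
SIZE_BANDS = ("pT1", "pT2", "pT3/4")
GRADES = ("I", "II", "III")
POS_NEG = ("pos", "neg")

_CATEGORY_VOCAB = {
    "age_band": AGE_BANDS,
    "menopausal": MENOPAUSAL,
    "size_band": SIZE_BANDS,
    "grade": GRADES,
    "er": POS_NEG,
    "pgr": POS_NEG,
    "her2": POS_NEG,
}

# columns that may legitimately be missing for a patient
_OPTIONAL_COLUMNS = ("ln_fb", "ln_r", "grade", "pfs_time", "pfs_event")

COHORT_COLUMNS = (
    "patient_id", "ln_fb", "ln_r",
    "mfs_time", "mfs_event", "os_time", "os_event", "pfs_time", "pfs_event",
    "age_band", "menopausal", "size_band", "grade", "er", "pgr", "her2",
)


class StackFormatError(ValueError):
    """Raised when a stack file violates the 12-bit multi-page contract."""


class CohortFormatError(ValueError):
    """Raised when a cohort table contains labels outside the vocabulary."""


@dataclass
class ScanStack:
    """One channel's raw image stack at one imaged location.

    frames has shape (n_frames, height, width) with integer counts in
    [0, 4095]; frame order is acquisition (axial) order.
    """

    frames: np.ndarray
    channel: str
    session_id: str = ""
    location_id: str = ""
    frame_spacing_um: float = 3.0
    field_of_view_um: float = 660.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise StackFormatError(
                f"stack must be 3-D (n_frames, h, w) with >=1 frame, got shape {self.frames.shape}"
            )
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if not np.issubdtype(self.frames.dtype, np.integer):
            raise StackFormatError("stack frames must be integer counts")
        if self.frames.min() < 0:
            raise StackFormatError("negative pixel count in stack")
        too_big = self.frames.max(axis=(1, 2)) > MAX_COUNT
        if too_big.any():
            bad = int(np.nonzero(too_big)[0][0])
            raise StackFormatError(
                f"frame {bad} contains a pixel count above {MAX_COUNT}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class SessionMeta:
    """Per-session plumbing: where the noise/calibration stacks live and the
    reference signal each detector pathway is normalised to."""

    session_id: str
    noise_stack_paths: dict[str, str]
    calibration_pair_paths: dict[str, str]
    reference_calibration_signal: dict[str, float]

    def __post_init__(self) -> None:
        for d in (self.noise_stack_paths, self.calibration_pair_paths,
                  self.reference_calibration_signal):
            missing = set(CHANNELS) - set(d)
            if missing:
                raise ValueError(f"session {self.session_id}: missing channel entries {missing}")
        for ch, ref in self.reference_calibration_signal.items():
            if not ref > 0:
                raise ValueError(f"reference signal for {ch} must be positive")


@dataclass
class PatientRecord:
    """One patient: imaging markers, endpoint times/events, covariates.

    Times are months; event flags are 0/1.  mfs = metastasis-free survival
    (event: confirmed distant metastasis), os = overall survival (event:
    death; deaths without evidence of disease censored at last follow-up),
    pfs = progression-free survival under tamoxifen (event: second-line
    treatment needed, or death).  Missing values stay missing (None);
    nothing is imputed.
    """

    patient_id: str
    ln_fb: Optional[float]
    mfs_time: float
    mfs_event: int
    os_time: float
    os_event: int
    age_band: str
    menopausal: str
    size_band: str
    grade: Optional[str]
    er: str
    pgr: str
    her2: str
    ln_r: Optional[float] = None
    pfs_time: Optional[float] = None
    pfs_event: Optional[int] = None

    def __post_init__(self) -> None:
        for name, value in (("mfs_time", self.mfs_time), ("os_time", self.os_time)):
            if not value > 0:
                raise ValueError(f"{self.patient_id}: {name} must be > 0")
        if self.pfs_time is not None and not self.pfs_time > 0:
            raise ValueError(f"{self.patient_id}: pfs_time must be > 0")
        for name, value in (("mfs_event", self.mfs_event), ("os_event", self.os_event),
                            ("pfs_event", self.pfs_event)):
            if value is not None and value not in (0, 1):
                raise ValueError(f"{self.patient_id}: {name} must be 0/1")
        for name, vocab in _CATEGORY_VOCAB.items():
            value = getattr(self, name)
            if value is None:
                if name in _OPTIONAL_COLUMNS:
                    continue
                raise CohortFormatError(f"{self.patient_id}: {name} is required")
            if value not in vocab:
                raise CohortFormatError(
                    f"{self.patient_id}: unknown {name} label {value!r} (expected one of {vocab})"
                )


# ---------------------------------------------------------------------------
# stacks

def read_stack(path: str | Path, channel: str, **meta) -> ScanStack:
    """Read a multi-page TIFF into a ScanStack, preserving page order.

    Raises StackFormatError naming the offending frame when a page's
    dimensions differ from frame 0 or a pixel exceeds 4095.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tif:
        pages = [p.asarray() for p in tif.pages]
    if not pages:
        raise StackFormatError(f"{path}: no image pages")
    shape0 = pages[0].shape
    for i, page in enumerate(pages):
        if page.ndim != 2:
            raise StackFormatError(f"{path}: frame {i} is not 2-D grayscale")
        if page.shape != shape0:
            raise StackFormatError(
                f"{path}: frame {i} has shape {page.shape}, expected {shape0}"
            )
        if page.max(initial=0) > MAX_COUNT:
            raise StackFormatError(f"{path}: frame {i} contains a pixel count above {MAX_COUNT}")
    frames = np.stack(pages).astype(np.uint16)
    return ScanStack(frames=frames, channel=channel, **meta)


def write_stack(stack: ScanStack, path: str | Path) -> None:
    """Write a ScanStack as a multi-page 16-bit grayscale TIFF."""
    tifffile.imwrite(str(path), stack.frames.astype(np.uint16), photometric="minisblack")


# ---------------------------------------------------------------------------
# session manifests

def read_manifest(path: str | Path) -> tuple[SessionMeta, list[dict]]:
    """Read a session manifest.

    Returns the SessionMeta and the list of location entries, each a dict
    with keys sample_id, location_id, forward, backward (paths relative to
    the manifest's directory are resolved).
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    base = path.parent

    def _resolve(p: str) -> str:
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    meta = SessionMeta(
        session_id=doc["session_id"],
        noise_stack_paths={ch: _resolve(p) for ch, p in doc["noise"].items()},
        calibration_pair_paths={ch: _resolve(p) for ch, p in doc["calibration"].items()},
        reference_calibration_signal={ch: float(v) for ch, v in doc["reference_signal"].items()},
    )
    for ch in CHANNELS:
        for p in (meta.noise_stack_paths[ch], meta.calibration_pair_paths[ch]):
            if not Path(p).exists():
                raise FileNotFoundError(f"session {meta.session_id}: {p} does not exist")
    locations = []
    for loc in doc["locations"]:
        locations.append({
            "sample_id": loc["sample_id"],
            "location_id": loc.get("location_id", ""),
            "forward": _resolve(loc["forward"]),
            "backward": _resolve(loc["backward"]),
        })
    return meta, locations


def write_manifest(path: str | Path, meta: SessionMeta, locations: list[dict]) -> None:
    doc = {
        "session_id": meta.session_id,
        "noise": meta.noise_stack_paths,
        "calibration": meta.calibration_pair_paths,
        "reference_signal": meta.reference_calibration_signal,
        "locations": locations,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


# ---------------------------------------------------------------------------
# cohort tables

def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip() == "":
        return True
    return False


def read_cohort_table(path: str | Path) -> list[PatientRecord]:
    """Parse a cohort CSV into PatientRecords.

    Unknown category labels and duplicate patient ids raise
    CohortFormatError with the offending row number (1-based, excluding the
    header).  Missing optional values are preserved as None.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing_cols = set(COHORT_COLUMNS) - set(df.columns) - {"ln_r", "pfs_time", "pfs_event"}
    if missing_cols:
        raise CohortFormatError(f"cohort table missing columns: {sorted(missing_cols)}")
    records: list[PatientRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.to_dict("records"), start=1):
        pid = row["patient_id"]
        if pid in seen:
            raise CohortFormatError(f"row {i}: duplicate patient id {pid!r}")
        seen.add(pid)

        def _opt_float(key):
            v = row.get(key)
            return None if _is_missing(v) else float(v)

        def _opt_int(key):
            v = row.get(key)
            return None if _is_missing(v) else int(v)

        def _cat(key):
            v = row.get(key)
            if _is_missing(v):
                return None
            v = str(v).strip()
            if v not in _CATEGORY_VOCAB[key]:
                raise CohortFormatError(
                    f"row {i}: unknown {key} label {v!r} "
                    f"(expected one of {_CATEGORY_VOCAB[key]})"
                )
            return v

        try:
            rec = PatientRecord(
                patient_id=pid,
                ln_fb=_opt_float("ln_fb"),
                ln_r=_opt_float("ln_r"),
                mfs_time=float(row["mfs_time"]), mfs_event=int(row["mfs_event"]),
                os_time=float(row["os_time"]), os_event=int(row["os_event"]),
                pfs_time=_opt_float("pfs_time"), pfs_event=_opt_int("pfs_event"),
                age_band=_cat("age_band"), menopausal=_cat("menopausal"),
                size_band=_cat("size_band"), grade=_cat("grade"),
                er=_cat("er"), pgr=_cat("pgr"), her2=_cat("her2"),
            )
        except CohortFormatError as exc:
            raise CohortFormatError(f"row {i}: {exc}") if "row " not in str(exc) else exc
        records.append(rec)
    return records


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Tabular view of a cohort; missing values become NaN."""
    rows = []
    for r in records:
        rows.append({c: getattr(r, c) for c in COHORT_COLUMNS})
    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    return df


def write_cohort_table(records: list[PatientRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)
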