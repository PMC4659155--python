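"""End-to-end run from a session directory on disk.

Writes a complete synthetic imaging session (sample stacks, closed-shutter
noise, FITC calibration pair, JSON manifest) with a deliberate gain
mismatch between the two detectors, then recomputes every sample's F/B from
the files alone and compares with the stipulated truth — demonstrating that
the daily-standard calibration cancels the gain drift.
"""

import tempfile
from pathlib import Path

import pandas as pd

from shgfb import process_session, simulate_session

with tempfile.TemporaryDirectory() as tmp:
    manifest = simulate_session(Path(tmp) / "session", n_samples=4,
                                gain_forward=1.3, gain_backward=0.7, seed=11)
    fb = process_session(manifest)
    truth = pd.read_csv(Path(tmp) / "session" / "truth.csv")
    merged = fb.merge(truth, on="sample_id")

    print(merged[["sample_id", "mean_fb", "true_fb", "ln_fb", "n_pixels"]]
          .round(4).to_string(index=False))
    rel = ((merged["mean_fb"] - merged["true_fb"]).abs() / merged["true_fb"])
    print(f"max relative error vs truth: {rel.max():.4f}")
# Despite the 1.3x / 0.7x detector gains, the calibrated mean F/B matches
# each sample's stipulated ratio to within the shot-noise level (~1%).
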