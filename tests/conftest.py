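import numpy as np
import pytest

from shgfb import ProjectedImage, ScanStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_stack(values, channel="forward", **kw):
    """ScanStack from nested lists / arrays (adds frame axis if 2-D)."""
    arr = np.asarray(values)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    return ScanStack(frames=arr.astype(np.uint16), channel=channel, **kw)


def corrected(values, channel="forward"):
    """Background-corrected ProjectedImage from an array-like."""
    return ProjectedImage(pixels=np.asarray(values, dtype=float),
                         channel=channel, background_corrected=True)


def zero_noise(shape=(256, 256), n_frames=11):
    """Noiseless closed-shutter stacks for both channels."""
    z = np.zeros((n_frames, *shape), dtype=np.uint16)
    return {
        "forward": ScanStack(frames=z, channel="forward"),
        "backward": ScanStack(frames=z.copy(), channel="backward"),
    }
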