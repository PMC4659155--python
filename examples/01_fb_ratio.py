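"""Measure a sample's average F/B ratio from a synthetic fiber field.

Generates a paired forward/backward focal stack with a stipulated
ground-truth ratio of 2.0 plus Poisson shot noise, then runs the full
measurement chain: maximum projection, closed-shutter background
subtraction, dual-channel masking at 40 counts, and the masked mean of the
F/B ratio image.
"""

import math

from shgfb import (
    FiberFieldSpec, generate_fiber_pair, generate_noise_stack, sample_fb,
)

spec = FiberFieldSpec(true_fb=2.0, noise="poisson", offset=3, seed=42)
f_stack, b_stack, truth = generate_fiber_pair(spec)
noise = {
    "forward": generate_noise_stack(level=3, sigma=1, seed=1, channel="forward"),
    "backward": generate_noise_stack(level=3, sigma=1, seed=2, channel="backward"),
}

result = sample_fb("demo", [(f_stack, b_stack)], noise)

print(f"ground-truth F/B : {spec.true_fb}")
print(f"measured mean F/B: {result.mean_fb:.4f}")
print(f"ln F/B           : {result.ln_fb:.4f}  (truth {math.log(spec.true_fb):.4f})")
print(f"pixels retained  : {result.n_pixels_retained}")
# The measured ratio should sit within a fraction of a percent of the
# stipulated truth; the retained-pixel count is the size of the
# forward x backward mask, i.e. how much fiber area passed both thresholds.
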