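"""Shared fixtures: desk-scale phantom arrays and a small on-disk dataset."""

from dataclasses import replace

import numpy as np
from hypothesis import settings

from ctrseg import phantom, preprocess

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_phantom_arrays(n: int, organ: str, *, size: int = 64,
                        noise_sd: float = 0.0, gradient_amp: float = 0.0,
                        seed: int = 0, ctr_range=(0.35, 0.75)):
    """Standardized images plus binary masks for one organ."""
    rng = np.random.default_rng(seed)
    base = phantom.PhantomSpec(image_size=size, noise_sd=noise_sd,
                               gradient_amp=gradient_amp)
    imgs, msks, ctrs = [], [], []
    for _ in range(n):
        spec = replace(
            phantom._jittered(base, rng),
            target_ctr=float(rng.uniform(*ctr_range)),
            seed=int(rng.integers(2**31 - 1)),
        )
        img, heart, lungs, true_ctr = phantom.generate_phantom(spec)
        raw = np.round(img * 255).astype(np.uint8)
        imgs.append(preprocess.standardize(raw, size))
        msks.append(heart if organ == "heart" else lungs)
        ctrs.append(true_ctr)
    return (np.stack(imgs).astype(np.float32), np.stack(msks),
            np.array(ctrs))
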