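import numpy as np
from scipy import ndimage as ndi


def smooth_field(seed: int, shape=(96, 96), blur: float = 2.0) -> np.ndarray:
    """Normalized Gaussian-smoothed noise raster, the generic textured fixture."""
    f = ndi.gaussian_filter(np.random.default_rng(seed).uniform(0, 1, shape), blur)
    return (f - f.min()) / (f.max() - f.min())
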