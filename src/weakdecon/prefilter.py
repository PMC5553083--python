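"""Flux-preserving Gaussian blur prefilter.

Prefiltering the optical sections with a small Gaussian blur (sigma 0.75 to
1.0 px) before maximum-likelihood deconvolution spreads isolated single-photon
events over several pixels.  This keeps very weak structures from being
discarded by the deconvolver while leaving the integrated intensity of each
structure unchanged (away from image borders, the normalized kernel conserves
flux exactly).

The kernel is a sampled Gaussian truncated at ``kernel_cutoff`` sigmas and
renormalized to sum 1, with reflecting boundaries; 2D mode filters each
z-slice independently, 3D mode filters the whole volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .stacks import EncodedStack

MODE_2D = "2d"
MODE_3D = "3d"


@dataclass(frozen=True)
class BlurConfig:
    """sigma in pixels (the blur tool's "radius" parameter), 2d or 3d mode."""

    sigma: float = 0.75
    mode: str = MODE_2D
    kernel_cutoff: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.mode not in (MODE_2D, MODE_3D):
            raise ValueError(f"mode must be '{MODE_2D}' or '{MODE_3D}'")
        if self.kernel_cutoff < 3:
            raise ValueError("kernel_cutoff must be at least 3 sigma")


def _blur_array(values: np.ndarray, config: BlurConfig) -> np.ndarray:
    if config.sigma == 0:
        return values.astype(np.float64, copy=True)
    # minimum half-width of 1 px so sub-pixel sigmas still blur
    radius = max(1, math.ceil(config.kernel_cutoff * config.sigma))
    if config.mode == MODE_2D:
        sigma = (0.0, config.sigma, config.sigma)
        radii = (0, radius, radius)
    else:
        sigma = (config.sigma,) * 3
        radii = (radius,) * 3
    return ndimage.gaussian_filter(values.astype(np.float64), sigma=sigma,
                                   mode="reflect", radius=radii)


def gaussian_blur(stack: EncodedStack | np.ndarray, config: BlurConfig):
    """Blur a stack; integer-encoded input is re-quantized to its encoding.

    Real (float) input returns the float result of the convolution; an
    :class:`EncodedStack` is computed in real arithmetic and rounded back to
    its own bit depth so that 8-bit and 16-bit processing paths can both be
    reproduced.
    """
    if isinstance(stack, EncodedStack):
        blurred = _blur_array(stack.values, config)
        limit = 255 if stack.bit_depth == 8 else 65535
        codes = np.clip(np.floor(blurred + 0.5), 0, limit)
        values = codes.astype(stack.values.dtype)
        prov = dict(stack.provenance)
        prov["blur_sigma_px"] = config.sigma
        prov["blur_mode"] = config.mode
        return EncodedStack(values, stack.photons_per_code, prov)
    return _blur_array(np.asarray(stack, dtype=np.float64), config)
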