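"""Zero-padded linear FFT convolution with explicit kernel-origin alignment.

All convolutions in this package are linear (zero-padded), never circular:
stacks are short along z and wrap-around would leak PSF tails from the top
of the volume into the bottom.  The kernel origin (the voxel treated as the
center of the PSF) is passed explicitly so that alignment is unambiguous for
even-sized grids.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as _spfft


def _padded_shape(shape_a: tuple[int, ...], shape_b: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(_spfft.next_fast_len(na + nb - 1) for na, nb in zip(shape_a, shape_b))


class LinearConvolver:
    """Caches the kernel spectrum for repeated convolution with one PSF.

    Parameters
    ----------
    kernel
        Real 3-D array (z, y, x).
    origin
        Index (oz, oy, ox) of the kernel voxel treated as the origin
        (typically the PSF center).
    shape
        Shape of the data arrays that will be convolved.
    """

    def __init__(self, kernel: np.ndarray, origin: tuple[int, ...], shape: tuple[int, ...]):
        kernel = np.asarray(kernel, dtype=np.float64)
        if kernel.ndim != len(shape) or kernel.ndim != len(origin):
            raise ValueError("kernel, origin and shape must have matching dimensionality")
        for o, k in zip(origin, kernel.shape):
            if not 0 <= o < k:
                raise ValueError(f"kernel origin {origin} outside kernel shape {kernel.shape}")
        self.shape = tuple(shape)
        self.origin = tuple(origin)
        self._padded = _padded_shape(shape, kernel.shape)
        self._kf = _spfft.rfftn(kernel, self._padded)
        rev = kernel[tuple(slice(None, None, -1) for _ in kernel.shape)]
        self._kf_rev = _spfft.rfftn(rev, self._padded)
        self._origin_rev = tuple(k - 1 - o for o, k in zip(origin, kernel.shape))

    def _run(self, data: np.ndarray, kf: np.ndarray, origin: tuple[int, ...]) -> np.ndarray:
        data = np.asarray(data, dtype=np.float64)
        if data.shape != self.shape:
            raise ValueError(f"expected shape {self.shape}, got {data.shape}")
        full = _spfft.irfftn(_spfft.rfftn(data, self._padded) * kf, self._padded)
        crop = tuple(slice(o, o + n) for o, n in zip(origin, self.shape))
        return full[crop]

    def convolve(self, data: np.ndarray) -> np.ndarray:
        """Linear convolution, cropped so the kernel origin maps onto itself."""
        return self._run(data, self._kf, self.origin)

    def correlate(self, data: np.ndarray) -> np.ndarray:
        """Adjoint of :meth:`convolve` (convolution with the reversed kernel)."""
        return self._run(data, self._kf_rev, self._origin_rev)


def linear_convolve(data: np.ndarray, kernel: np.ndarray, origin: tuple[int, ...]) -> np.ndarray:
    """One-shot zero-padded linear convolution cropped to ``data.shape``."""
    return LinearConvolver(np.asarray(kernel), origin, np.asarray(data).shape).convolve(data)
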