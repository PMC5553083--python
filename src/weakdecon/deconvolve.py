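"""Richardson-Lucy maximum-likelihood deconvolution for photon-counting data.

The observed stack ``d`` is modelled as d ~ Poisson(H x + b): ``H`` is linear
(zero-padded) convolution with a sum-normalized PSF, ``x`` the non-negative
object estimate and ``b`` a uniform additive background in photons/voxel.
The classic multiplicative EM update

    x_{k+1} = x_k * H~( d / (H x_k + b) )

(H~ = convolution with the spatially reversed PSF) maximizes the Poisson
likelihood; keeping the background inside the forward model, rather than
subtracting it from the data, keeps the likelihood valid at the very low
counts this package targets.  Iterations run to a fixed count (default 40)
with no early stopping.  Every iterate is non-negative by construction and
the per-iteration Poisson log-likelihood trace is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._fft import LinearConvolver
from .optics import PSFVolume, SUM_ONE
from .stacks import EncodedStack

AUTO = "auto"

_TINY = 1e-30


@dataclass(frozen=True)
class DeconvConfig:
    """Iteration count, background handling and bookkeeping options.

    ``background`` is either a number (photons/voxel) or ``"auto"``, in which
    case the histogram mode of the observed stack is used.  ``snr_hint`` has
    no mathematical effect on the update; it is recorded in provenance only,
    mirroring how an SNR knob of a proprietary deconvolver would be logged.
    """

    iterations: int = 40
    background: float | str = AUTO
    snr_hint: float | None = None
    flux_correct: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.iterations <= 1000:
            raise ValueError("iterations must be in [1, 1000]")
        if self.background != AUTO:
            if not isinstance(self.background, (int, float)):
                raise ValueError("background must be 'auto' or a number")
            if self.background < 0:
                raise ValueError("background must be non-negative")


@dataclass
class DeconvResult:
    estimate: np.ndarray
    iterations_run: int
    log_likelihood_trace: list[float]
    background_used: float
    flux_scale: float = 1.0
    flags: list[str] = field(default_factory=list)


def estimate_background(stack: EncodedStack | np.ndarray,
                        photons_per_code: float | None = None) -> float:
    """Histogram-mode background estimate, in photons/voxel.

    The mode of the voxel-value histogram is taken as the background level;
    ties break toward the smaller value.  For photon-counting data dominated
    by empty voxels this is 0.
    """
    if isinstance(stack, EncodedStack):
        values = stack.values
        scale = stack.photons_per_code
    else:
        values = np.asarray(stack)
        scale = photons_per_code if photons_per_code is not None else 1.0
    if values.size == 0:
        raise ValueError("empty stack")
    if np.issubdtype(values.dtype, np.integer):
        counts = np.bincount(values.ravel())
        mode = int(np.argmax(counts))  # argmax returns the first (smallest) tie
        return float(mode) * scale
    uniq, counts = np.unique(values.ravel(), return_counts=True)
    return float(uniq[np.argmax(counts)]) * scale


def resolve_background(config: DeconvConfig, observed) -> float:
    if config.background == AUTO:
        return estimate_background(observed)
    return float(config.background)


def richardson_lucy(observed: np.ndarray, psf: PSFVolume, config: DeconvConfig,
                    background: float | None = None,
                    convolver: LinearConvolver | None = None) -> DeconvResult:
    """Run the multiplicative EM iteration on a stack in photon units.

    ``psf`` must be sum-normalized; ``background`` overrides the config
    (useful after :func:`estimate_background` ran on the encoded stack).
    """
    if psf.normalization != SUM_ONE:
        raise ValueError("richardson_lucy requires a sum_one PSF")
    d = np.asarray(observed, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("observed stack must be non-negative")
    b = resolve_background(config, d) if background is None else float(background)
    if b < 0:
        raise ValueError("background must be non-negative")
    flags: list[str] = []
    if d.size and b > d.max():
        flags.append(f"background {b} exceeds observed maximum {d.max()}")

    if not d.any():
        return DeconvResult(np.zeros_like(d), 0, [], b, 1.0, flags)

    conv = convolver if convolver is not None else LinearConvolver(
        psf.values, psf.origin_zyx, d.shape)

    x = np.full_like(d, max(np.mean(np.maximum(d - b, 0.0)), _TINY))
    positive = d > 0
    trace: list[float] = []
    for _ in range(config.iterations):
        m = conv.convolve(x) + b
        np.maximum(m, _TINY, out=m)
        ratio = np.where(positive, d / m, 0.0)
        x = x * conv.correlate(ratio)
        np.clip(x, 0.0, None, out=x)
        trace.append(_poisson_loglik(d, conv.convolve(x) + b))
    return DeconvResult(x, config.iterations, trace, b, 1.0, flags)


def _poisson_loglik(d: np.ndarray, m: np.ndarray) -> float:
    """sum(d log m - m) up to the data-only lgamma constant."""
    m = np.maximum(m, _TINY)
    pos = d > 0
    return float(np.sum(d[pos] * np.log(m[pos])) - m.sum())


def flux_correction(result: DeconvResult, observed: np.ndarray, b: float) -> DeconvResult:
    """Rescale the estimate so its total matches the background-subtracted data.

    Deconvolvers routinely return arbitrarily scaled intensities; matching
    total(estimate) to total(max(observed - b, 0)) makes per-object integrated
    densities comparable across processed and unprocessed stacks.
    """
    target = float(np.sum(np.maximum(np.asarray(observed, dtype=np.float64) - b, 0.0)))
    total = float(result.estimate.sum())
    if total <= 0:
        if target > 0:
            result.flags.append("zero estimate total; flux correction skipped")
        return result
    scale = target / total
    result.estimate = result.estimate * scale
    result.flux_scale = scale
    return result
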