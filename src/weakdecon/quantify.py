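"""Average projection, ROI integrated density, and preserved-object counting.

The readout for a processed stack is the average projection (per-pixel mean
over z), per-object integrated densities in 20x20-px ROIs centered on the
known emitter positions, and the number of objects counted as preserved.

Preservation is decided on a small *detection window* matched to the core of
a processed point image (5x5 px by default, capped at half the lattice
spacing so windows at the lattice midpoints never touch an emitter): an
object is preserved when the density in its detection window exceeds the mean
of the midpoint-window densities by more than five of their standard
deviations.  Object and background windows have identical size, so the
comparison is like-for-like and insensitive to any global intensity scaling;
a window much larger than the spot core would drown the ~18 photons of a
weak object in the Poisson noise of the background it integrates.  The
full-ROI integrated density remains the reported per-object measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import ObjectLayout


@dataclass
class ObjectMeasure:
    center_xy: tuple[int, int]
    integrated_density: float
    detection_density: float
    preserved: bool


@dataclass
class QuantReport:
    per_object: list[ObjectMeasure]
    n_preserved: int
    background_mean: float
    background_sd: float
    threshold: float
    k_sigma: float
    roi_size: int
    detection_size: int
    correction_factor: float = 1.0

    def densities(self) -> np.ndarray:
        return np.array([m.integrated_density for m in self.per_object])

    def to_rows(self) -> list[dict]:
        return [
            {"object": i, "x": m.center_xy[0], "y": m.center_xy[1],
             "integrated_density": m.integrated_density, "preserved": int(m.preserved)}
            for i, m in enumerate(self.per_object)
        ]


def average_project(stack: np.ndarray) -> np.ndarray:
    """Per-pixel mean over z of a (z, y, x) stack."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("expected a non-empty (z, y, x) stack")
    return stack.mean(axis=0, dtype=np.float64)


def _roi_slices(center_xy: tuple[int, int], size: int, shape: tuple[int, int]):
    # an even-sized window cannot be symmetric about one pixel: span [c-s//2, c-s//2+s)
    x, y = center_xy
    y0, x0 = y - size // 2, x - size // 2
    if y0 < 0 or x0 < 0 or y0 + size > shape[0] or x0 + size > shape[1]:
        raise ValueError(f"ROI of size {size} at {center_xy} out of bounds for image {shape}")
    return slice(y0, y0 + size), slice(x0, x0 + size)


def integrated_density(projection: np.ndarray, center_xy: tuple[int, int],
                       roi_size: int = 20) -> float:
    """Sum of pixel values over the ROI window centered on ``center_xy``."""
    projection = np.asarray(projection)
    ys, xs = _roi_slices(center_xy, roi_size, projection.shape)
    return float(projection[ys, xs].sum())


def _lattice_midpoints(layout: ObjectLayout) -> tuple[list[tuple[int, int]], int]:
    """Midpoints of diagonally adjacent lattice cells and the min spacing."""
    xs = sorted({c[0] for c in layout.centers})
    ys = sorted({c[1] for c in layout.centers})
    if len(xs) < 2 or len(ys) < 2:
        raise ValueError("need at least a 2x2 object lattice for background ROIs")
    spacing = min(min(np.diff(xs)), min(np.diff(ys)))
    mids = [((xs[i] + xs[i + 1]) // 2, (ys[j] + ys[j + 1]) // 2)
            for j in range(len(ys) - 1) for i in range(len(xs) - 1)]
    return mids, int(spacing)


DETECTION_SIZE = 5  # px; ~2x the in-focus lateral FWHM of the effective PSF


def count_preserved(projection: np.ndarray, layout: ObjectLayout,
                    roi_size: int = 20, k_sigma: float = 5.0,
                    detection_size: int | None = None,
                    full_scale: float | None = None) -> QuantReport:
    """Count objects whose detection-window density clears the background.

    An object is preserved when its detection-window density D satisfies
    D > mu_bg + k_sigma * sd_bg over same-size windows at the lattice
    midpoints.  The detection window defaults to 5x5 px (clipped to the ROI
    and to half the lattice spacing); it is deliberately matched to the core
    of a processed point image rather than to the quantification ROI.  When
    the background is exactly uniform (sd == 0) the criterion degenerates to
    a small epsilon above the mean (1e-6 * window area * full-scale value).
    """
    projection = np.asarray(projection, dtype=np.float64)
    mids, spacing = _lattice_midpoints(layout)
    if len(mids) < 4:
        raise ValueError("fewer than 4 background ROIs available")
    if detection_size is None:
        det = max(1, min(DETECTION_SIZE, roi_size, spacing // 2))
    else:
        det = max(1, min(int(detection_size), spacing - 1))
    bg = np.array([integrated_density(projection, m, det) for m in mids])
    mu, sd = float(bg.mean()), float(bg.std(ddof=0))
    if sd > 0:
        threshold = mu + k_sigma * sd
    else:
        scale = full_scale if full_scale is not None else max(float(projection.max()), 1.0)
        threshold = mu + 1e-6 * det ** 2 * scale

    per_object = []
    for x, y, _z in layout.centers:
        dens = integrated_density(projection, (x, y), roi_size)
        det_dens = integrated_density(projection, (x, y), det)
        per_object.append(ObjectMeasure((x, y), dens, det_dens, det_dens > threshold))
    n = sum(m.preserved for m in per_object)
    return QuantReport(per_object, n, mu, sd, threshold, k_sigma, roi_size, det)


def apply_correction_factor(report: QuantReport, factor: float) -> QuantReport:
    """Multiply all densities by ``factor`` and recompute preserved flags.

    The threshold scales with the background statistics, so flags are
    invariant under a positive global factor.
    """
    if factor <= 0:
        raise ValueError("correction factor must be positive")
    threshold = report.threshold * factor
    per_object = [
        ObjectMeasure(m.center_xy, m.integrated_density * factor,
                      m.detection_density * factor,
                      m.detection_density * factor > threshold)
        for m in report.per_object
    ]
    n = sum(m.preserved for m in per_object)
    return QuantReport(per_object, n, report.background_mean * factor,
                       report.background_sd * factor, threshold, report.k_sigma,
                       report.roi_size, report.detection_size,
                       report.correction_factor * factor)
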