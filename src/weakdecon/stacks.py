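"""Reading, writing and bit-depth promotion of photon-counting TIFF stacks.

Stacks are single-channel multi-page TIFFs, one page per z-slice, z ascending,
with integer pixel values that encode detected photon counts through a linear
scale (``photons_per_code``).  The scale is kept in a plain-text sidecar file
next to the TIFF so the images stay openable in any viewer.

Very weak photon-counting data typically holds pixel values 0, 1 and 2.  To
give a Gaussian blur room for intermediate values, such 8-bit stacks are
promoted to 16-bit and multiplied by 256 (typical values become 0, 256, 512);
the photon scale is divided by 256 so the physical photon value of every
pixel is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

_SIDECAR_SUFFIX = ".meta.txt"


@dataclass
class EncodedStack:
    """An integer-encoded photon-count z-stack.

    Attributes
    ----------
    values : ndarray, (z, y, x), uint8 or uint16
    photons_per_code : float
        Photons represented by one intensity unit (e.g. 4/255 for the 8-bit
        encoding where code 255 corresponds to 4 photons).
    provenance : dict
        Free-form key/value metadata (simulation config, seeds, ...),
        persisted to the sidecar.
    """

    values: np.ndarray
    photons_per_code: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim == 2:
            self.values = self.values[None]
        if self.values.ndim != 3:
            raise ValueError("stack must be 2-D or 3-D (z, y, x)")
        if self.values.dtype not in (np.uint8, np.uint16):
            raise ValueError(f"unsupported dtype {self.values.dtype}; need uint8/uint16")
        if not self.photons_per_code > 0:
            raise ValueError("photons_per_code must be positive")

    @property
    def bit_depth(self) -> int:
        return 8 if self.values.dtype == np.uint8 else 16

    def to_photons(self) -> np.ndarray:
        """Decode to a float64 array of photons per voxel."""
        return self.values.astype(np.float64) * self.photons_per_code


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + _SIDECAR_SUFFIX)


def write_stack(stack: EncodedStack, path: str | Path) -> None:
    """Write a stack as multi-page TIFF plus a key=value sidecar.

    Output bytes are deterministic for identical input (fixed tag set, no
    timestamps).
    """
    path = Path(path)
    tifffile.imwrite(path, stack.values, photometric="minisblack")
    lines = [f"photons_per_code = {stack.photons_per_code!r}",
             f"bit_depth = {stack.bit_depth}"]
    for key in sorted(stack.provenance):
        lines.append(f"{key} = {stack.provenance[key]}")
    _sidecar_path(path).write_text("\n".join(lines) + "\n")


def read_stack(path: str | Path, photons_per_code: float | None = None) -> EncodedStack:
    """Read a multi-page TIFF stack; sidecar metadata overrides defaults.

    Without a sidecar or explicit argument, 8-bit stacks default to the
    4-photons-at-255 convention and 16-bit stacks to its /256 promotion.
    """
    path = Path(path)
    values = tifffile.imread(path)
    values = np.asarray(values)
    if values.ndim == 2:
        values = values[None]
    if values.ndim != 3:
        raise ValueError(f"{path}: expected a single-channel z-stack, got shape {values.shape}")
    if values.size == 0:
        raise ValueError(f"{path}: empty stack")
    if values.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"{path}: unsupported dtype {values.dtype}")
    provenance: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        for line in sidecar.read_text().splitlines():
            if "=" not in line:
                continue
            key, _, val = line.partition("=")
            provenance[key.strip()] = val.strip()
        if photons_per_code is None and "photons_per_code" in provenance:
            photons_per_code = float(provenance.pop("photons_per_code"))
        provenance.pop("bit_depth", None)
    if photons_per_code is None:
        photons_per_code = 4.0 / 255.0 if values.dtype == np.uint8 else 4.0 / 255.0 / 256.0
    return EncodedStack(values, photons_per_code, provenance)


def promote_16bit(stack: EncodedStack) -> EncodedStack:
    """Promote an 8-bit stack to 16-bit by multiplying codes by 256.

    The photon scale is divided by 256, so ``code * photons_per_code`` is
    invariant voxel by voxel.  255 * 256 = 65280 < 65535, so no overflow is
    possible.
    """
    if stack.bit_depth != 8:
        raise ValueError("promote_16bit expects an 8-bit stack")
    values = stack.values.astype(np.uint16) * np.uint16(256)
    return EncodedStack(values, stack.photons_per_code / 256.0, dict(stack.provenance))
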