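"""Per-pixel metric depth maps (z < 0 in front of the camera)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["DepthMap"]


@dataclass
class DepthMap:
    """Depth in mm on the pixel grid, with a validity mask.

    ``z`` is (H, W) float, negative for visible points; invalid pixels
    hold NaN.  ``step`` is the grid spacing in pixels (dx = dy).  When
    the map was produced by front propagation, ``seed_pixel`` (column,
    row) and ``seed_depth`` record the boundary condition; the output at
    the seed equals ``seed_depth`` exactly.
    """

    z: np.ndarray
    valid: np.ndarray
    step: float = 1.0
    seed_pixel: tuple[int, int] | None = None
    seed_depth: float | None = None

    def __post_init__(self):
        self.z = np.asarray(self.z, float)
        self.valid = np.asarray(self.valid, bool)
        if self.z.shape != self.valid.shape:
            raise ValueError("z and valid mask shapes differ")

    @property
    def shape(self):
        return self.z.shape

    def masked(self):
        return np.where(self.valid, self.z, np.nan)

    def save(self, path) -> None:
        """Write as a float32 TIFF (NaN for invalid pixels)."""
        tifffile.imwrite(str(path), self.masked().astype(np.float32))

    @classmethod
    def load(cls, path) -> "DepthMap":
        z = tifffile.imread(str(path)).astype(float)
        return cls(z=z, valid=np.isfinite(z))
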