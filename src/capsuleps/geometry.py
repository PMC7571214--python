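"""Camera/light geometry for near-point-light photometric stereo.

Conventions
-----------
The camera is an ideal pinhole at the origin of the camera frame
(xi, eta, zeta), looking down the negative zeta axis: visible scene
points have depth ``z < 0`` (millimetres).  Pixel coordinates ``(x, y)``
are continuous offsets from the principal point, x to the right and y
down, measured in pixels, as is the focal length ``f``.  A surface point
imaged at pixel ``(x, y)`` with depth ``z`` sits at

    M(x, y) = (-x z / f, -y z / f, z)        [mm]

Light source positions ``(xi_i, eta_i, zeta_i)`` are in millimetres in
the camera frame.  The mixed pixel/mm expressions used throughout
(``xi_i f / z + x`` in pixels, ``xi_i + x z / f`` in mm) are
dimensionally consistent under this convention; this module is the one
place where it is asserted.

All functions broadcast over numpy arrays of pixel coordinates and
depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, DegenerateNormalError

__all__ = [
    "CameraModel",
    "LightSource",
    "SurfacePoint",
    "light_direction_terms",
    "attenuation",
    "surface_normal",
]


@dataclass(frozen=True)
class CameraModel:
    """Pinhole intrinsics tying pixel coordinates to metric rays.

    Parameters
    ----------
    f : float
        Focal length in pixels (> 0).
    cx, cy : float
        Principal point in pixel (column, row) coordinates.
    width, height : int
        Image size in pixels.
    """

    f: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self):
        if self.f <= 0:
            raise ValueError(f"focal length must be positive, got {self.f}")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")

    def pixel_coords(self, col, row):
        """Convert (column, row) raster indices to centered (x, y)."""
        return np.asarray(col, float) - self.cx, np.asarray(row, float) - self.cy

    def raster_coords(self, x, y):
        """Inverse of :meth:`pixel_coords`."""
        return np.asarray(x, float) + self.cx, np.asarray(y, float) + self.cy

    def pixel_grid(self):
        """Centered (x, y) coordinate arrays for the full frame, shape (H, W)."""
        cols = np.arange(self.width, dtype=float)
        rows = np.arange(self.height, dtype=float)
        x, y = np.meshgrid(cols - self.cx, rows - self.cy)
        return x, y

    def surface_point_mm(self, x, y, z):
        """Camera-frame coordinates (xi, eta, zeta) of the point imaged
        at centered pixel (x, y) with depth z < 0.  Stacked on the last
        axis."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        z = np.asarray(z, float)
        return np.stack(
            np.broadcast_arrays(-x * z / self.f, -y * z / self.f, z), axis=-1
        )


def _unit(v):
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return tuple(float(c) / float(n) for c in v)


@dataclass(frozen=True)
class LightSource:
    """A near-point light source in the camera frame.

    ``position`` is (xi, eta, zeta) in mm.  ``principal_direction`` is
    the unit emission axis of the LED, by default (0, 0, -1), i.e.
    pointing into the scene alongside the optical axis.  ``intensity``
    is a dimensionless relative radiant scale (equal for all four LEDs
    of the default rig).
    """

    position: tuple[float, float, float]
    principal_direction: tuple[float, float, float] = (0.0, 0.0, -1.0)
    intensity: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "position", tuple(float(c) for c in self.position))
        object.__setattr__(
            self, "principal_direction", _unit(self.principal_direction)
        )
        if self.intensity <= 0:
            raise ValueError("light intensity must be positive")

    @property
    def xi(self) -> float:
        return self.position[0]

    @property
    def eta(self) -> float:
        return self.position[1]

    @property
    def zeta(self) -> float:
        return self.position[2]


@dataclass
class SurfacePoint:
    """A surface sample: pixel location, depth, and (optionally) the
    depth gradient in mm/pixel from which the normal follows."""

    x: float
    y: float
    z: float
    zx: float | None = None
    zy: float | None = None

    def __post_init__(self):
        if self.z >= 0:
            raise ValueError(f"visible points have z < 0, got z={self.z}")

    def position_mm(self, cam: CameraModel):
        return cam.surface_point_mm(self.x, self.y, self.z)


def light_direction_terms(x, y, z, light: LightSource, cam: CameraModel):
    """Illumination direction for the near point light source model.

    Returns ``(lbar, q, l)`` where ``lbar`` is the unnormalized
    direction with components stacked on the last axis,

        lbar = (xi f/z + x,  eta f/z + y,  zeta f/z - f),

    ``q = ||lbar||`` and ``l = lbar / q``.  For z < 0 the unit vector
    ``l`` points from the light toward the surface point (antiparallel
    to S - M).

    Raises
    ------
    DegenerateGeometryError
        If z = 0 anywhere, or q = 0 (the light coincides with the
        surface point).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    if np.any(z == 0):
        raise DegenerateGeometryError("z = 0: point on the camera plane")
    f = cam.f
    xi, eta, zeta = light.position
    lbar = np.stack(
        np.broadcast_arrays(xi * f / z + x, eta * f / z + y, zeta * f / z - f),
        axis=-1,
    )
    q = np.linalg.norm(lbar, axis=-1)
    if np.any(q == 0):
        raise DegenerateGeometryError("light source coincides with surface point")
    return lbar, q, lbar / q[..., None]


def attenuation(x, y, z, light: LightSource, cam: CameraModel):
    """Illuminance attenuation factors of a near point light source.

    Returns ``(a_d, a_r, a)``:

    * ``a_d = f^2 / (z^2 q^2)`` -- inverse-square falloff with the
      propagation distance ``||S - M||`` (units mm^-2);
    * ``a_r`` -- radial (cosine) falloff of the LED about its principal
      direction, the clamped absolute cosine between the propagation
      direction and the principal axis, in (0, 1];
    * ``a = a_d * a_r`` -- the combined factor.  For a light in the
      camera plane (zeta_i = 0) with principal direction (0, 0, -1)
      this equals ``f^3 / (z^2 q^3)`` exactly.
    """
    lbar, q, l = light_direction_terms(x, y, z, light, cam)
    z = np.asarray(z, float)
    a_d = cam.f**2 / (z**2 * q**2)
    # l points light->surface; the literal dot product with the emission
    # axis can come out negative purely from the sign convention, so the
    # attenuation is the clamped absolute cosine.
    cos = np.abs(l @ np.asarray(light.principal_direction))
    a_r = np.clip(cos, 0.0, 1.0)
    return a_d, a_r, a_d * a_r


def surface_normal(x, y, z, zx, zy, cam: CameraModel):
    """Unnormalized and unit surface normal from the depth gradient.

    ``nbar = (z/f)^2 * (f zx, f zy, z + x zx + y zy)`` with the gradient
    in mm/pixel.  Under the z < 0 convention ``nbar`` points *away*
    from the camera (a fronto-parallel plane has n = (0, 0, -1)); the
    outward normal used in rendering is ``-n``.

    Raises
    ------
    DegenerateNormalError
        If ``||nbar|| = 0`` anywhere.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    zx = np.asarray(zx, float)
    zy = np.asarray(zy, float)
    f = cam.f
    s = (z / f) ** 2
    nbar = np.stack(
        np.broadcast_arrays(s * f * zx, s * f * zy, s * (z + x * zx + y * zy)),
        axis=-1,
    )
    norm = np.linalg.norm(nbar, axis=-1)
    if np.any(norm == 0):
        raise DegenerateNormalError("zero-length surface normal")
    return nbar, nbar / norm[..., None]


def depth_gradient(z_map, valid=None):
    """Depth gradient (zx, zy) in mm/pixel from a discrete depth map.

    Central differences in the interior, one-sided at the borders
    (numpy.gradient).  ``valid`` is an optional mask; invalid pixels
    yield NaN gradients.
    """
    z = np.asarray(z_map, float)
    if valid is not None:
        z = np.where(valid, z, np.nan)
    zy, zx = np.gradient(z)
    return zx, zy
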