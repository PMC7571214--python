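"""Synthetic endoscopic scene generation.

Renders the four photometric-stereo images of an analytic test surface
under the capsule rig: a polyp-shaped object (spherical cap on a plane)
viewed by the pinhole camera and lit by one near-point LED at a time,
with Blinn-Phong reflectance, inverse-square and radial cosine
attenuation, a dark environment, and no interreflection or shadows.

The default surface places the background plane at -21.37 mm and a
4 mm-high spherical polyp cap (sphere radius 6 mm) on the optical
axis, so the apex sits at -17.37 mm.

Also provides an independent *mirror-point oracle*: the pixel and depth
at which the ideal specular condition (incident angle = reflected
angle) holds exactly for a given light, found by solving the reflection
geometry numerically.  Tests use it as ground truth for the
seed-depth estimator; the estimator itself never calls it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import imageio.v3 as iio
import tifffile
import yaml
from scipy import optimize

from .depthmap import DepthMap
from .geometry import CameraModel, LightSource
from .rig import Rig, default_rig

__all__ = [
    "SurfaceSpec",
    "RenderResult",
    "default_scene",
    "analytic_depth",
    "analytic_gradient",
    "render",
    "mirror_point_oracle",
    "write_render",
]

#: Default polyp color (linear RGB albedo), a desaturated mucosal pink.
DEFAULT_ALBEDO = (0.85, 0.45, 0.40)


@dataclass(frozen=True)
class SurfaceSpec:
    """Analytic test surface and its Blinn-Phong reflectance.

    Parameters
    ----------
    kind : {'plane', 'sphere_cap_on_plane', 'hemisphere'}
    base_depth : float
        Depth of the background plane in mm (< 0).
    cap_radius : float
        Radius of the cap's sphere in mm.
    cap_height : float or None
        Height of the cap above the plane; None means equal to
        ``cap_radius`` (a full hemisphere).  The default 4 mm-high cap
        on a 6 mm sphere keeps the apex at -17.37 mm while the rim
        slope stays below the view-ray tangency, so the depth map is
        continuous everywhere in the frame; a full hemisphere at this
        distance would show a genuine occlusion jump at its
        silhouette.
    cap_center : (float, float)
        Centered pixel coordinates (x, y) of the cap apex; (0, 0) puts
        the polyp on the optical axis.
    albedo : tuple
        Per-channel diffuse reflectance in [0, 1].
    k_d, k_s : float
        Diffuse and specular weights.
    shininess : float
        Blinn-Phong exponent; larger values give a tighter highlight.
    """

    kind: str = "sphere_cap_on_plane"
    base_depth: float = -21.37
    cap_radius: float = 6.0
    cap_height: float | None = 4.0
    cap_center: tuple[float, float] = (0.0, 0.0)
    albedo: tuple = DEFAULT_ALBEDO
    k_d: float = 0.8
    k_s: float = 0.6
    shininess: float = 300.0

    def __post_init__(self):
        if self.kind not in ("plane", "sphere_cap_on_plane", "hemisphere"):
            raise ValueError(f"unknown surface kind {self.kind!r}")
        if self.base_depth >= 0:
            raise ValueError("base_depth must be negative (in front of camera)")
        if self.cap_radius <= 0:
            raise ValueError("cap_radius must be positive")
        h = self.height
        if not (0 < h <= self.cap_radius):
            raise ValueError("cap_height must lie in (0, cap_radius]")
        if not all(0 <= a <= 1 for a in np.atleast_1d(self.albedo)):
            raise ValueError("albedo components must lie in [0, 1]")
        for name in ("k_d", "k_s"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def height(self) -> float:
        return self.cap_radius if self.cap_height is None else self.cap_height

    @property
    def apex_depth(self) -> float:
        """Depth of the cap apex: base_depth + cap height."""
        return self.base_depth + self.height

    def sphere_center(self, cam: CameraModel) -> np.ndarray:
        """Camera-frame center of the cap's sphere in mm.

        The apex (nearest sphere point along +zeta) images at
        ``cap_center``; the center sits ``cap_radius`` below it.
        """
        xc, yc = self.cap_center
        za = self.apex_depth
        return np.array(
            [-xc * za / cam.f, -yc * za / cam.f, self.base_depth - (self.cap_radius - self.height)]
        )


def default_scene() -> SurfaceSpec:
    """The default polyp scene used by the simulation studies."""
    return SurfaceSpec()


# ---------------------------------------------------------------------------
# analytic depth / gradient / normals

def _sphere_hit(spec: SurfaceSpec, cam: CameraModel, x, y):
    """Nearest ray-sphere intersection depth per pixel (NaN on miss).

    The ray through centered pixel (x, y) is P(z) = z * m with
    m = (-x/f, -y/f, 1); the nearest hit is the root with the larger z
    (closest to the camera).
    """
    f = cam.f
    C = spec.sphere_center(cam)
    mx, my = -np.asarray(x, float) / f, -np.asarray(y, float) / f
    A = mx * mx + my * my + 1.0
    B = -2.0 * (mx * C[0] + my * C[1] + C[2])
    Cc = C @ C - spec.cap_radius**2
    disc = B * B - 4.0 * A * Cc
    with np.errstate(invalid="ignore"):
        z = (-B + np.sqrt(disc)) / (2.0 * A)
    return np.where(disc >= 0, z, np.nan)


def analytic_depth(spec: SurfaceSpec, cam: CameraModel) -> DepthMap:
    """Ground-truth depth map of the analytic surface.

    Plane pixels sit exactly at ``base_depth``; cap pixels take the
    nearest ray-sphere intersection where it lies in front of the
    plane.  For the 'hemisphere' kind, rays missing the sphere are
    marked invalid.
    """
    x, y = cam.pixel_grid()
    if spec.kind == "plane":
        z = np.full(x.shape, spec.base_depth)
        return DepthMap(z=z, valid=np.ones(x.shape, bool))
    zs = _sphere_hit(spec, cam, x, y)
    if spec.kind == "hemisphere":
        valid = np.isfinite(zs)
        return DepthMap(z=np.where(valid, zs, np.nan), valid=valid)
    z = np.where(np.isfinite(zs) & (zs > spec.base_depth), zs, spec.base_depth)
    return DepthMap(z=z, valid=np.ones(x.shape, bool))


def _on_cap(spec: SurfaceSpec, cam: CameraModel, x, y, z):
    if spec.kind == "plane":
        return np.zeros(np.shape(z), bool)
    return np.asarray(z) > spec.base_depth + 1e-12


def analytic_gradient(spec: SurfaceSpec, cam: CameraModel, x, y, z):
    """Exact depth gradient (zx, zy) in mm/pixel at the given pixels.

    Implicit differentiation of the ray-sphere constraint on the cap;
    zero on the plane.  ``z`` must be the analytic depth at (x, y).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    zx = np.zeros(np.broadcast_shapes(x.shape, y.shape, z.shape))
    zy = np.zeros_like(zx)
    cap = _on_cap(spec, cam, x, y, z)
    if np.any(cap):
        f = cam.f
        C = spec.sphere_center(cam)
        xc, yc, zc = np.broadcast_to(x, cap.shape)[cap], np.broadcast_to(y, cap.shape)[cap], np.broadcast_to(z, cap.shape)[cap]
        # d = P - C with P = z * m
        dx = -xc * zc / f - C[0]
        dy = -yc * zc / f - C[1]
        dz = zc - C[2]
        dm = dx * (-xc / f) + dy * (-yc / f) + dz  # d . m
        zx[cap] = -(-zc / f * dx) / dm
        zy[cap] = -(-zc / f * dy) / dm
    return zx, zy


def _outward_normals(spec: SurfaceSpec, cam: CameraModel, x, y, z):
    """Geometric outward unit normals (toward the camera side), (..., 3)."""
    shape = np.broadcast_shapes(np.shape(x), np.shape(y), np.shape(z))
    N = np.zeros(shape + (3,))
    N[..., 2] = 1.0
    cap = _on_cap(spec, cam, x, y, z)
    if np.any(cap):
        P = cam.surface_point_mm(x, y, z)
        d = P[cap] - spec.sphere_center(cam)
        N[cap] = d / spec.cap_radius
    return N


# ---------------------------------------------------------------------------
# rendering

@dataclass
class RenderResult:
    """Four single-light renders plus the ground truth.

    ``images[k]`` is the (H, W, 3) linear-radiometry image rendered
    with only ``lights[active_sources[k]]`` switched on.
    """

    images: list
    ground_truth: DepthMap
    active_sources: list
    spec: SurfaceSpec
    rig: Rig

    def __post_init__(self):
        if len(self.images) != len(self.active_sources):
            raise ValueError("one active source per image required")


def render(spec: SurfaceSpec, rig: Rig, noise_sigma: float = 0.0,
           rng=None, active_sources=None) -> RenderResult:
    """Render one image per light source (Blinn-Phong, linear radiometry).

    Per pixel, with the surface point P, outward normal N, unit
    direction to the light lhat and to the camera vhat, half vector
    h = unit(lhat + vhat), and attenuation a (inverse-square times
    radial cosine):

        I_c = Phi * a * (k_d * rho_c * max(0, lhat.N)
                          + k_s * max(0, h.N)**shininess)

    The specular lobe carries the (white) source color rather than the
    surface albedo, which is what makes highlights low-saturation and
    detectable.  No shadows or interreflection are simulated; invalid
    pixels render as zero.

    ``noise_sigma`` adds zero-mean Gaussian noise in linear radiometry,
    expressed as a fraction of the noiseless image maximum (0 disables;
    pass a seeded ``numpy.random.Generator`` for reproducibility).
    """
    cam = rig.camera
    if active_sources is None:
        active_sources = list(range(len(rig.lights)))
    gt = analytic_depth(spec, cam)
    x, y = cam.pixel_grid()
    z = np.where(gt.valid, gt.z, spec.base_depth)  # placeholder; masked later
    P = cam.surface_point_mm(x, y, z)
    N = _outward_normals(spec, cam, x, y, z)
    vhat = -P / np.linalg.norm(P, axis=-1, keepdims=True)
    rho = np.atleast_1d(np.asarray(spec.albedo, float))
    if rng is None:
        rng = np.random.default_rng()

    images = []
    for k in active_sources:
        light = rig.lights[k]
        L = np.asarray(light.position) - P
        dist = np.linalg.norm(L, axis=-1)
        lhat = L / dist[..., None]
        a_d = 1.0 / dist**2
        prop = -lhat  # propagation direction, light -> surface
        a_r = np.clip(prop @ np.asarray(light.principal_direction), 0.0, 1.0)
        a = a_d * a_r
        diff = np.clip(np.sum(lhat * N, axis=-1), 0.0, None)
        h = lhat + vhat
        h /= np.linalg.norm(h, axis=-1, keepdims=True)
        spec_cos = np.clip(np.sum(h * N, axis=-1), 0.0, None)
        spec_term = spec_cos**spec.shininess
        img = light.intensity * a[..., None] * (
            spec.k_d * diff[..., None] * rho[None, None, :]
            + spec.k_s * spec_term[..., None]
        )
        img[~gt.valid] = 0.0
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma * img.max(), img.shape)
            img = np.clip(img, 0.0, None)
            img[~gt.valid] = 0.0
        images.append(img)
    return RenderResult(images=images, ground_truth=gt,
                        active_sources=list(active_sources), spec=spec, rig=rig)


# ---------------------------------------------------------------------------
# mirror-point oracle

def _surface_at(spec: SurfaceSpec, cam: CameraModel, x: float, y: float):
    """Scalar (z, N) at a pixel, or None if the ray misses the surface."""
    if spec.kind == "plane":
        z = spec.base_depth
    else:
        zs = float(_sphere_hit(spec, cam, x, y))
        if spec.kind == "hemisphere":
            if not np.isfinite(zs):
                return None
            z = zs
        else:
            z = zs if (np.isfinite(zs) and zs > spec.base_depth) else spec.base_depth
    N = _outward_normals(spec, cam, np.array(x), np.array(y), np.array(z))
    return z, np.asarray(N, float).reshape(3)


def _mirror_residual(spec, cam, light, x, y):
    """Tangential misalignment between the half vector and the normal."""
    hit = _surface_at(spec, cam, x, y)
    if hit is None:
        return None
    z, N = hit
    P = cam.surface_point_mm(x, y, z).reshape(3)
    tc = -P / np.linalg.norm(P)
    S = np.asarray(light.position, float)
    ts = S - P
    nrm = np.linalg.norm(ts)
    if nrm == 0:
        return None
    ts /= nrm
    h = tc + ts
    hn = np.linalg.norm(h)
    if hn == 0:
        return None
    h /= hn
    return np.cross(h, N)


def mirror_point_oracle(spec: SurfaceSpec, light: LightSource, cam: CameraModel,
                        tol: float = 1e-10):
    """Pixel and depth of the exact specular (mirror) point.

    Solves incident angle = reflected angle for the given surface,
    light, and camera by root finding on the reflection geometry:
    bisection along the symmetry axis when the configuration is
    mirror-symmetric (light on a coordinate axis, cap centered),
    otherwise a 2-D least-squares root find.  Returns ``((x, y), z)``
    in centered pixel coordinates and mm, or None when no mirror point
    falls inside the field of view.

    With the camera and light co-located at the origin this degenerates
    to retroreflection (normal antiparallel to the view ray).
    """
    xi, eta, _ = light.position
    half_w = cam.width / 2.0
    half_h = cam.height / 2.0

    # Degenerate co-located case: retroreflection along the line of
    # centers (sphere) or the principal axis (plane).
    if abs(xi) < 1e-12 and abs(eta) < 1e-12 and abs(light.position[2]) < 1e-12:
        if spec.kind == "plane":
            hit = _surface_at(spec, cam, 0.0, 0.0)
            return ((0.0, 0.0), hit[0])
        C = spec.sphere_center(cam)
        P = C * (1.0 - spec.cap_radius / np.linalg.norm(C))
        if P[2] <= spec.base_depth and spec.kind == "sphere_cap_on_plane":
            return None
        x = -P[0] * cam.f / P[2]
        y = -P[1] * cam.f / P[2]
        return ((x, y), float(P[2]))

    symmetric_cap = spec.kind == "plane" or spec.cap_center == (0.0, 0.0)
    if symmetric_cap and (abs(eta) < 1e-12 or abs(xi) < 1e-12):
        # 1-D bisection along the light's axis.  The mirror pixel lies
        # between the principal point and the light's image side.
        along_x = abs(eta) < 1e-12
        limit = half_w if along_x else half_h
        sign = np.sign(xi if along_x else eta)

        def g(t):
            x, y = (sign * t, 0.0) if along_x else (0.0, sign * t)
            r = _mirror_residual(spec, cam, light, x, y)
            if r is None:
                return np.nan
            return r[1] if along_x else -r[0]

        ts = np.linspace(1e-6, limit, 512)
        vals = np.array([g(t) for t in ts])
        ok = np.isfinite(vals)
        idx = np.where(ok[:-1] & ok[1:] & (vals[:-1] * vals[1:] < 0))[0]
        if idx.size == 0:
            return None
        t = optimize.brentq(g, ts[idx[0]], ts[idx[0] + 1], xtol=tol)
        x, y = (sign * t, 0.0) if along_x else (0.0, sign * t)
    else:
        # 2-D root find from the plane-mirror initial guess.
        z0 = spec.base_depth
        x0 = -(xi / 2.0) * cam.f / z0
        y0 = -(eta / 2.0) * cam.f / z0

        def res(p):
            r = _mirror_residual(spec, cam, light, p[0], p[1])
            if r is None:
                return np.array([1e3, 1e3])
            return np.array([r[0], r[1]])

        sol = optimize.least_squares(res, x0=[x0, y0], xtol=1e-14, ftol=1e-14)
        if not sol.success or np.linalg.norm(sol.fun) > 1e-6:
            return None
        x, y = sol.x

    if not (-half_w <= x <= half_w and -half_h <= y <= half_h):
        return None
    hit = _surface_at(spec, cam, float(x), float(y))
    if hit is None:
        return None
    return ((float(x), float(y)), float(hit[0]))


# ---------------------------------------------------------------------------
# file output

def write_render(result: RenderResult, outdir, fmt: str = "tiff",
                 seed: int | None = None) -> None:
    """Write the four images, ground-truth depth, and a scene manifest.

    ``fmt='tiff'`` keeps linear float radiometry; ``fmt='png'``
    quantizes to 16-bit scaled to the stack maximum.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    peak = max(img.max() for img in result.images)
    for k, img in zip(result.active_sources, result.images):
        if fmt == "tiff":
            tifffile.imwrite(str(outdir / f"image_{k}.tif"),
                             img.astype(np.float32))
        else:
            q = np.clip(img / peak * 65535.0, 0, 65535).astype(np.uint16)
            iio.imwrite(str(outdir / f"image_{k}.png"), q)
    result.ground_truth.save(outdir / "ground_truth.tif")
    manifest = {
        "surface": asdict(result.spec),
        "active_sources": result.active_sources,
        "format": fmt,
        "png_scale": float(peak) if fmt == "png" else None,
        "seed": seed,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
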