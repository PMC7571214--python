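"""Seed-depth estimation at specular highlight pixels.

The depth of a highlight pixel is the one unknown tying together two
facts about the same surface point:

* in the images where the point reflects *diffusely*, the ratio of two
  irradiance equations cancels albedo and the normal's magnitude and
  leaves a first-order PDE in depth,

      F_xi * zx + F_eta * zy = z * F_zeta,

  whose coefficients depend only on the pixel, the candidate depth and
  the two light positions;

* in the image where the point is *specular*, the mirror condition
  (incident angle = reflected angle) pins the depth gradient to a
  closed form (zx, zy) in terms of the same candidate depth.

Substituting the specular gradient into the ratio PDE yields a scalar
energy E(z) that vanishes at the true depth.  The estimator minimizes
the squared energy (summed over the usable Lambertian image pairs) by
a coarse grid scan over the camera's working range followed by bounded
local refinement.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import optimize

from .errors import DegenerateSpecularError, UnusablePixelError
from .geometry import CameraModel, LightSource

__all__ = [
    "RatioCoefficients",
    "SpecularGradientTerms",
    "SeedEstimate",
    "SeedResult",
    "ratio_coefficients",
    "specular_gradient_terms",
    "specular_gradient",
    "energy",
    "estimate_seed_depth",
]

#: Depth search interval in mm, the camera's stated working range
#: (depth of field 3 mm to 100 mm in front of the lens, z < 0).
DEFAULT_SEARCH = (-100.0, -3.0)


def _q(x, y, z, light: LightSource, f: float):
    xi, eta, zeta = light.position
    return np.sqrt((xi * f / z + x) ** 2 + (eta * f / z + y) ** 2
                   + (zeta * f / z - f) ** 2)


@dataclass
class RatioCoefficients:
    """PDE coefficients for one ordered Lambertian pair (delta1, delta2).

    Antisymmetric under swapping the pair: all three components change
    sign.  ``s = z * F_zeta`` is the source term of the upwind scheme.
    """

    F_xi: np.ndarray
    F_eta: np.ndarray
    F_zeta: np.ndarray
    z: np.ndarray

    @property
    def s(self):
        return self.z * self.F_zeta

    def residual(self, zx, zy):
        """PDE residual F_xi*zx + F_eta*zy - z*F_zeta (zero at truth)."""
        return self.F_xi * zx + self.F_eta * zy - self.s


def ratio_coefficients(x, y, z, I1, I2, light1: LightSource, light2: LightSource,
                       cam: CameraModel) -> RatioCoefficients:
    """Image-ratio PDE coefficients at pixel (x, y), candidate depth z.

    ``I1``/``I2`` are the illuminances of the two Lambertian images at
    this pixel; both must be positive and the pixel must lie outside
    both images' highlight masks (the caller enforces the masks).
    Broadcasts over arrays of z for grid scans.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    if np.any(np.asarray(I1) <= 0) or np.any(np.asarray(I2) <= 0):
        raise UnusablePixelError("zero illuminance in a Lambertian image")
    f = cam.f
    xi1, eta1, zeta1 = light1.position
    xi2, eta2, zeta2 = light2.position
    w1 = I1 * _q(x, y, z, light1, f) ** 4
    w2 = I2 * _q(x, y, z, light2, f) ** 4
    return RatioCoefficients(
        F_xi=w1 * (xi2 * f + zeta2 * x) - w2 * (xi1 * f + zeta1 * x),
        F_eta=w1 * (eta2 * f + zeta2 * y) - w2 * (eta1 * f + zeta1 * y),
        F_zeta=w2 * (zeta1 - z) - w1 * (zeta2 - z),
        z=z,
    )


@dataclass
class SpecularGradientTerms:
    """Mirror-condition terms at a candidate depth.

    ``b = sqrt(x^2 + y^2 + f^2) >= f`` is the pixel's ray length in
    pixels.  The G components encode the specular constraint so that
    zx = -z*G_xi/G_zeta, zy = -z*G_eta/G_zeta, and the seed energy is
    the bilinear form F.G.
    """

    b: np.ndarray
    G_xi: np.ndarray
    G_eta: np.ndarray
    G_zeta: np.ndarray
    z: np.ndarray

    def gradient(self):
        if np.any(self.G_zeta == 0):
            raise DegenerateSpecularError("vanishing specular denominator")
        return -self.z * self.G_xi / self.G_zeta, -self.z * self.G_eta / self.G_zeta


def specular_gradient_terms(x, y, z, sigma_light: LightSource,
                            cam: CameraModel) -> SpecularGradientTerms:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    f = cam.f
    xi, eta, zeta = sigma_light.position
    b = np.sqrt(x * x + y * y + f * f)
    q = _q(x, y, z, sigma_light, f)
    return SpecularGradientTerms(
        b=b,
        G_xi=x * z * q + (x * z + xi * f) * b,
        G_eta=y * z * q + (y * z + eta * f) * b,
        G_zeta=z * q * b**2 + z * b**3 + f * (x * xi + y * eta - f * zeta) * b,
        z=z,
    )


def specular_gradient(x, y, z, sigma_light: LightSource, cam: CameraModel):
    """Closed-form depth gradient (zx, zy) implied by the mirror
    condition at pixel (x, y) if the depth there is z.

    With the camera and light co-located this reduces to
    retroreflection: the returned gradient makes the surface normal
    parallel to the view ray.
    """
    return specular_gradient_terms(x, y, z, sigma_light, cam).gradient()


def energy(x, y, z, sigma_light: LightSource, delta_lights, delta_I,
           cam: CameraModel, combine: bool = False, normalized: bool = False):
    """Seed energy E(z) = F_xi G_xi + F_eta G_eta + F_zeta G_zeta.

    ``delta_lights``/``delta_I`` list the Lambertian sources and their
    illuminances at this pixel (two entries for a single pair, three
    for all pairs).  Returns one energy per unordered pair, stacked on
    the first axis, or — with ``combine=True`` — the sum of squared
    per-pair energies, which is what the estimator minimizes.

    ``normalized=True`` divides each pair's energy by the sum of the
    magnitudes of its three terms, giving a dimensionless residual
    suitable for tolerance checks and for combining pairs on a common
    scale.
    """
    if len(delta_lights) < 2 or len(delta_lights) != len(delta_I):
        raise UnusablePixelError("need at least two usable Lambertian images")
    g = specular_gradient_terms(x, y, z, sigma_light, cam)
    out = []
    for i, j in combinations(range(len(delta_lights)), 2):
        F = ratio_coefficients(x, y, z, delta_I[i], delta_I[j],
                               delta_lights[i], delta_lights[j], cam)
        t1 = F.F_xi * g.G_xi
        t2 = F.F_eta * g.G_eta
        t3 = F.F_zeta * g.G_zeta
        e = t1 + t2 + t3
        if normalized:
            scale = np.abs(t1) + np.abs(t2) + np.abs(t3)
            e = np.where(scale > 0, e / np.where(scale > 0, scale, 1.0), 0.0)
        out.append(e)
    out = np.stack(out, axis=0)
    return np.sum(out**2, axis=0) if combine else out


@dataclass
class SeedEstimate:
    """Depth estimate at one highlight pixel.

    ``pixel`` is in raster (column, row) coordinates.

    status: 'converged' | 'edge' (minimum at the search boundary,
    excluded from statistics) | 'ambiguous' (two well-separated energy
    minima of comparable depth, excluded).
    """

    pixel: tuple[int, int]
    z_hat: float
    energy_residual: float
    bracket: tuple[float, float]
    status: str


@dataclass
class SeedResult:
    per_pixel: list
    centroid: SeedEstimate
    sigma_index: int

    @property
    def converged(self):
        return [e for e in self.per_pixel if e.status == "converged"]


def _estimate_pixel(pixel, x, y, sigma_light, delta_lights, delta_I, cam,
                    search, n_grid, tol):
    lo, hi = search
    grid = np.linspace(lo, hi, n_grid)
    obj = energy(x, y, grid, sigma_light, delta_lights, delta_I, cam,
                 combine=True, normalized=True)
    k = int(np.argmin(obj))
    if k == 0 or k == n_grid - 1:
        return SeedEstimate(pixel, float(grid[k]), float(np.sqrt(obj[k])),
                            (lo, hi), "edge")
    # ambiguity: another well-separated local minimum of comparable depth
    interior = (obj[1:-1] < obj[:-2]) & (obj[1:-1] <= obj[2:])
    minima = np.where(interior)[0] + 1
    rivals = minima[(np.abs(minima - k) > 2)]
    if rivals.size and obj[rivals].min() <= 1.1 * obj[k]:
        return SeedEstimate(pixel, float(grid[k]), float(np.sqrt(obj[k])),
                            (lo, hi), "ambiguous")
    a, b = grid[k - 1], grid[k + 1]
    res = optimize.minimize_scalar(
        lambda z: float(energy(x, y, z, sigma_light, delta_lights, delta_I,
                               cam, combine=True, normalized=True)),
        bounds=(a, b), method="bounded", options={"xatol": tol},
    )
    return SeedEstimate(pixel, float(res.x), float(np.sqrt(res.fun)),
                        (float(a), float(b)), "converged")


def estimate_seed_depth(region, images, highlight_masks, rig,
                        search=DEFAULT_SEARCH, n_grid: int = 512,
                        tol: float = 1e-4, pair_mode: str = "combined") -> SeedResult:
    """Estimate the depth of every pixel of a specular highlight region.

    Parameters
    ----------
    region : HighlightRegion
        The sigma region (its ``source_index`` names the specular
        light); depths are estimated at each of its pixels and at its
        centroid.
    images : sequence of (H, W) float arrays
        Luminance illuminance maps, one per light source.
    highlight_masks : sequence of (H, W) bool arrays
        Each image's own highlight mask; a pixel inside image k's mask
        never contributes a Lambertian equation from image k.
    pair_mode : {'combined', 'single'}
        'combined' sums squared energies over all usable delta pairs;
        'single' uses only the two brightest delta images at the pixel.

    Returns a :class:`SeedResult`; the centroid estimate is the
    recommended boundary condition for depth-map reconstruction.
    """
    if pair_mode not in ("combined", "single"):
        raise ValueError(f"unknown pair_mode {pair_mode!r}")
    cam = rig.camera
    sigma = region.source_index
    sigma_light = rig.lights[sigma]
    delta_set = [k for k in range(len(images)) if k != sigma]

    rows, cols = np.nonzero(region.mask)
    estimates = []
    centroid_est = None
    c_col, c_row = region.centroid

    def run_one(col, row):
        x, y = cam.pixel_coords(col, row)
        usable = [k for k in delta_set
                  if not highlight_masks[k][row, col] and images[k][row, col] > 0]
        if len(usable) < 2:
            return None
        if pair_mode == "single":
            usable = sorted(usable, key=lambda k: -images[k][row, col])[:2]
            usable.sort()
        lights = [rig.lights[k] for k in usable]
        vals = [float(images[k][row, col]) for k in usable]
        return _estimate_pixel((col, row), float(x), float(y), sigma_light,
                               lights, vals, cam, search, n_grid, tol)

    for col, row in zip(cols.tolist(), rows.tolist()):
        est = run_one(col, row)
        if est is None:
            continue
        estimates.append(est)
        if est.pixel == (c_col, c_row):
            centroid_est = est

    if centroid_est is None:
        # centroid pixel unusable or (for a concave region) outside the
        # mask: estimate it directly
        centroid_est = run_one(c_col, c_row)
        if centroid_est is None:
            raise UnusablePixelError("centroid pixel has <2 Lambertian images")
    return SeedResult(per_pixel=estimates, centroid=centroid_est,
                      sigma_index=sigma)
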