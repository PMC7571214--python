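"""Whole-surface depth-map integration from the seed pixel.

The image-ratio PDE  F_xi zx + F_eta zy = z F_zeta  is discretized
with a first-order forward upwind scheme: the one-sided difference for
each derivative is taken from the neighbor selected by the sign of the
corresponding coefficient, giving the fixed-point update

    Z = (|F_xi| Z_upx + |F_eta| Z_upy + step * s) / (|F_xi| + |F_eta|),

with s = Z F_zeta.  Because F and s depend on the unknown Z itself,
each pixel is solved by fixed-point iteration initialized from its
accepted neighbors (with a bracketing root solve as fallback).

Propagation follows a fast-marching order: pixels are finalized once,
expanding outward from the seed over the 8-connected neighborhood.
Each pixel couples the ratio equations of *different light-source
pairs* across the eight principal directions (2 horizontal, 2
vertical, 4 diagonal): among the usable pairs, preferring the
brightest, the update uses the first whose sign-selected upwind
neighbors are already accepted; swapping the ordered pair negates F
and s, which is what makes both orientations of every stencil
admissible.  Diagonal stencils use step * sqrt(2).
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .depthmap import DepthMap
from .geometry import CameraModel
from .rig import Rig
from .seed import DEFAULT_SEARCH

__all__ = [
    "UpdateResult",
    "MarchState",
    "EvalResult",
    "upwind_update",
    "select_pair",
    "fast_march",
    "evaluate",
]

log = logging.getLogger(__name__)

_SQRT2 = math.sqrt(2.0)


def _pair_terms(x, y, z, I1, I2, l1, l2, f):
    """Scalar F_xi, F_eta, s for one pixel/depth/pair.

    Mirrors seed.ratio_coefficients on floats; kept flat for the inner
    march loop (a unit test pins the two implementations together).
    """
    xi1, eta1, ze1 = l1
    xi2, eta2, ze2 = l2
    inv = f / z
    t1 = xi1 * inv + x
    t2 = eta1 * inv + y
    t3 = ze1 * inv - f
    q2 = t1 * t1 + t2 * t2 + t3 * t3
    w1 = I1 * q2 * q2
    t1 = xi2 * inv + x
    t2 = eta2 * inv + y
    t3 = ze2 * inv - f
    q2 = t1 * t1 + t2 * t2 + t3 * t3
    w2 = I2 * q2 * q2
    fxi = w1 * (xi2 * f + ze2 * x) - w2 * (xi1 * f + ze1 * x)
    feta = w1 * (eta2 * f + ze2 * y) - w2 * (eta1 * f + ze1 * y)
    s = z * (w2 * (ze1 - z) - w1 * (ze2 - z))
    return fxi, feta, s, w1 + w2


@dataclass
class UpdateResult:
    z: float | None
    status: str          # converged | deferred | degenerate | no_converge
    iterations: int = 0
    stencil: str = ""    # 'xy', 'xg', 'yg', 'diagg', 'x', 'y', 'diag', 'root'
    pair: tuple | None = None


def _apply_once(z, x, y, pairs, f, neighbors, grads, step, deg_eps):
    """One application of the upwind fixed-point map at depth z.

    ``pairs`` is a preference-ordered sequence of candidate ratio
    equations ``(I1, I2, light1_pos, light2_pos, key)``.  Returns
    ``(T, stencil, key)`` or ``(None, reason, None)``.

    The characteristic line of each pair runs along +-(sgn F_xi,
    sgn F_eta); information can be pulled from either side (swapping
    the ordered pair negates F and s), so every stencil exists in two
    orientations.  Preference: the first pair with both one-sided axis
    differences on one side ('xy'); then a single dominant-axis
    difference completed by the lagged cross-gradient stored at the
    anchor neighbor ('xg'/'yg'); then the diagonal difference
    corrected by the lagged perpendicular gradient ('diagg'); then the
    uncorrected single-axis and diagonal forms of the preferred pair.
    """
    terms = []
    for I1, I2, l1, l2, key in pairs:
        fxi, feta, s, wsum = _pair_terms(x, y, z, I1, I2, l1, l2, f)
        afx = abs(fxi)
        afy = abs(feta)
        # ~ F magnitude for O(10 mm) light offsets
        if afx + afy <= deg_eps * wsum * f * 20.0:
            continue
        sx = 1 if fxi > 0 else (-1 if fxi < 0 else 0)
        sy = 1 if feta > 0 else (-1 if feta < 0 else 0)
        terms.append((fxi, feta, s, afx, afy, sx, sy, key,
                      (afx + afy) / wsum))
    if not terms:
        return None, "degenerate", None

    best = None
    for fxi, feta, s, afx, afy, sx, sy, key, cond in terms:
        for o in (1, -1):
            ax = neighbors.get((-o * sx, 0)) if sx else None
            ay = neighbors.get((0, -o * sy)) if sy else None
            if ax is not None and ay is not None:
                if best is None or cond > best[0]:
                    best = (cond, ((afx * ax + afy * ay + o * step * s)
                                   / (afx + afy), "xy", key))
                break
    if best is not None:
        return best[1]

    if grads:
        for fxi, feta, s, afx, afy, sx, sy, key, _c in terms:
            # only divide by a dominant |F|: a weak-axis division would
            # amplify the lagged-gradient error
            if afx >= afy and sx:
                name, af, cross_f, offs = "xg", afx, feta, [(-1, 0), (1, 0)]
                sgn = sx
            elif sy:
                name, af, cross_f, offs = "yg", afy, fxi, [(0, -1), (0, 1)]
                sgn = sy
            else:
                continue
            for o in (1, -1):
                off = (-o * sgn * abs(offs[0][0]), -o * sgn * abs(offs[0][1]))
                a = neighbors.get(off)
                g = grads.get(off)
                if a is not None and g is not None:
                    cross = cross_f * (g[1] if name == "xg" else g[0])
                    return a + o * step * (s - cross) / af, name, key
        for fxi, feta, s, afx, afy, sx, sy, key, _c in terms:
            if not (sx and sy):
                continue
            for o in (1, -1):
                off = (-o * sx, -o * sy)
                d = neighbors.get(off)
                g = grads.get(off)
                if d is not None and g is not None:
                    # split F into the diagonal component (one-sided
                    # difference over step*sqrt(2)) and the
                    # perpendicular component (lagged gradient)
                    fp = (-fxi * sy + feta * sx) / _SQRT2
                    gp = (-sy * g[0] + sx * g[1]) / _SQRT2
                    return (d + o * 2.0 * step * (s - fp * gp) / (afx + afy),
                            "diagg", key)

    fxi, feta, s, afx, afy, sx, sy, key, _c = terms[0]
    for o in (1, -1):
        if sx and afx > 0:
            ax = neighbors.get((-o * sx, 0))
            if ax is not None:
                return ax + o * step * s / afx, "x", key
        if sy and afy > 0:
            ay = neighbors.get((0, -o * sy))
            if ay is not None:
                return ay + o * step * s / afy, "y", key
    if sx and sy:
        for o in (1, -1):
            d = neighbors.get((-o * sx, -o * sy))
            if d is not None:
                return d + o * 2.0 * step * s / (afx + afy), "diag", key
    return None, "deferred", None


def upwind_update(x, y, neighbors, pairs, cam: CameraModel,
                  step: float = 1.0, z0: float | None = None,
                  tol: float = 1e-6, max_iter: int = 50,
                  deg_eps: float = 1e-12, neighbor_gradients=None) -> UpdateResult:
    """Solve the scalar upwind equation at one pixel.

    Parameters
    ----------
    x, y : float
        Centered pixel coordinates.
    neighbors : mapping (dx, dy) -> depth
        Accepted neighbor depths, keyed by pixel offset (dx right,
        dy down), 8-neighborhood.
    pairs : sequence of (I1, I2, light1, light2)
        Candidate ratio equations in preference order (brightest pair
        first); ``I`` are the pair's illuminances at this pixel,
        ordered by source index.  A single-element sequence reproduces
        the plain one-pair scheme.
    z0 : float, optional
        Initial depth; defaults to the mean of the supplied neighbors.
    neighbor_gradients : mapping (dx, dy) -> (zx, zy), optional
        Lagged depth-gradient estimates at the accepted neighbors
        (mm/pixel); when available they complete the single-axis and
        diagonal stencils to full first-order consistency.

    The pair/stencil choice and the upwind signs are re-selected from
    sgn(F) at every iteration; if the fixed point does not settle
    within ``max_iter`` iterations, the scalar equation is solved by
    bracketing root find on the same map.
    """
    if not neighbors:
        return UpdateResult(None, "deferred")
    f = cam.f
    grads = neighbor_gradients or {}
    flat = [(float(I1), float(I2), l1.position, l2.position, (l1, l2))
            for I1, I2, l1, l2 in pairs]
    if z0 is None:
        z0 = sum(neighbors.values()) / len(neighbors)
    z = z0
    stencil = ""
    key = None
    for it in range(1, max_iter + 1):
        T, stencil, key = _apply_once(z, x, y, flat, f, neighbors, grads,
                                      step, deg_eps)
        if T is None:
            return UpdateResult(None, stencil, iterations=it)
        if abs(T - z) < tol:
            return UpdateResult(T, "converged", iterations=it,
                                stencil=stencil, pair=key)
        z = T
        if not (-1e4 < z < -1e-3):
            break  # runaway iterate; try the bracketing solve

    # Fixed point did not settle: solve g(Z) = Z - T(Z) by brentq with
    # an expanding bracket around the initial guess.
    def g(zz):
        T, _, _ = _apply_once(zz, x, y, flat, f, neighbors, grads, step,
                              deg_eps)
        return zz - T if T is not None else np.nan

    for half in (0.5, 1.0, 2.0, 4.0, 8.0, 16.0):
        a, b = z0 - half, z0 + half
        ga, gb = g(a), g(b)
        if np.isfinite(ga) and np.isfinite(gb) and ga * gb < 0:
            root = optimize.brentq(g, a, b, xtol=tol)
            return UpdateResult(float(root), "converged",
                                iterations=max_iter, stencil="root", pair=key)
    return UpdateResult(z if -1e4 < z < -1e-3 else z0, "no_converge",
                        iterations=max_iter, stencil=stencil, pair=key)


def select_pair(images, highlight_masks=None, floor_rel: float = 1e-4):
    """Per-pixel preferred Lambertian pair.

    For every pixel, the two *usable* images (not in their own
    highlight mask, illuminance above ``floor_rel`` of that image's
    maximum) with the highest illuminance, ordered by source index.

    Returns ``(lo, hi, n_usable)`` integer arrays; pixels with fewer
    than two usable images get lo = hi = -1.
    """
    stack = np.stack([np.asarray(im, float) for im in images], axis=0)
    usable = np.ones(stack.shape, bool)
    for k in range(stack.shape[0]):
        usable[k] &= stack[k] > floor_rel * stack[k].max()
        if highlight_masks is not None:
            usable[k] &= ~np.asarray(highlight_masks[k], bool)
    vals = np.where(usable, stack, -np.inf)
    order = np.argsort(-vals, axis=0, kind="stable")
    first, second = order[0], order[1]
    lo = np.minimum(first, second).astype(np.int64)
    hi = np.maximum(first, second).astype(np.int64)
    n_usable = usable.sum(axis=0)
    bad = n_usable < 2
    lo[bad] = -1
    hi[bad] = -1
    return lo, hi, n_usable


@dataclass
class MarchState:
    """Bookkeeping of the fast march (mainly for inspection/tests)."""

    accepted: np.ndarray          # bool, pixel finalized
    pair_lo: np.ndarray           # preferred (brightest) pair per pixel
    pair_hi: np.ndarray
    stencil: np.ndarray           # update stencil actually used
    flags: np.ndarray             # 0 ok, 1 neighbor-mean fallback, 2 no-converge
    order: np.ndarray = None      # acceptance rank per pixel (-1 if never)
    pops: int = 0


def fast_march(images, highlight_masks, rig: Rig, seed_pixel, seed_depth,
               step: float = 1.0, floor_rel: float = 1e-4,
               working_range=DEFAULT_SEARCH, tol: float = 1e-6,
               max_iter: int = 50, demote_masks=None,
               return_state: bool = False):
    """Integrate the full depth map outward from the seed pixel.

    Parameters
    ----------
    images : sequence of (H, W) float arrays
        Luminance illuminance maps, one per light.
    highlight_masks : sequence of (H, W) bool arrays or None
        Per-image specular masks; masked pixels never contribute
        Lambertian equations from their own image.
    seed_pixel : (col, row)
        Raster coordinates of the boundary-condition pixel.
    seed_depth : float
        Depth (mm, < 0) imposed at the seed; reproduced exactly in the
        output.
    demote_masks : sequence of (H, W) bool arrays, optional
        Soft exclusion zones per image (typically a wider dilation of
        the highlight masks): the image stays usable there, but pairs
        containing it are preferred only when no cleaner pair has an
        admissible stencil.

    Propagation order is deterministic: pixels inside any highlight
    mask are reconstructed last; otherwise priority is the number of
    already-accepted neighbors (descending), then squared Euclidean
    distance from the seed (ascending), then pixel index, so the front
    stays circular and crosses curvature ridges radially.  Each pixel
    is finalized the first time it is popped with a solvable stencil.

    Returns a :class:`DepthMap` (and the :class:`MarchState` if
    ``return_state``).  Pixels the front cannot reach are left invalid.
    """
    cam = rig.camera
    H, W = np.asarray(images[0]).shape
    n_img = len(images)
    if highlight_masks is None:
        highlight_masks = [np.zeros((H, W), bool) for _ in images]
    lo_arr, hi_arr, _ = select_pair(images, highlight_masks, floor_rel)
    usable = np.ones((n_img, H, W), bool)
    for k in range(n_img):
        im = np.asarray(images[k], float)
        usable[k] = (im > floor_rel * im.max()) & ~np.asarray(highlight_masks[k], bool)
    in_hl = np.zeros((H, W), bool)
    for m in highlight_masks:
        in_hl |= np.asarray(m, bool)

    col0, row0 = int(seed_pixel[0]), int(seed_pixel[1])
    if not (0 <= col0 < W and 0 <= row0 < H):
        raise ValueError("seed pixel outside the frame")
    zlo, zhi = min(working_range), max(working_range)
    if not (zlo <= seed_depth <= zhi):
        raise ValueError(f"seed depth {seed_depth} outside working range")

    # flat scalar views for the inner loop
    imgs_flat = [np.asarray(im, float).reshape(-1).tolist() for im in images]
    usable_flat = [usable[k].reshape(-1).tolist() for k in range(n_img)]
    hl_flat = in_hl.reshape(-1).astype(np.int64).tolist()
    if demote_masks is not None:
        demote_flat = [np.asarray(m, bool).reshape(-1).tolist()
                       for m in demote_masks]
    else:
        demote_flat = None
    lights = rig.lights
    f = cam.f
    cx, cy = cam.cx, cam.cy

    Z = np.full(H * W, np.nan)
    accepted = np.zeros(H * W, bool)
    stencil = np.full(H * W, "", dtype=object)
    rank = np.full(H * W, -1, np.int32)
    n_rank = 0
    flags = np.zeros(H * W, np.uint8)
    n_acc = np.zeros(H * W, np.int16)
    pops_left = np.full(H * W, 9, np.int8)
    GX = np.zeros(H * W)
    GY = np.zeros(H * W)
    #: clamp for the lagged gradient estimates (mm/pixel); discrete
    #: differences across the occlusion rim would otherwise leak into
    #: the correction terms
    g_clip = 3.0

    idx0 = row0 * W + col0
    Z[idx0] = float(seed_depth)
    accepted[idx0] = True
    stencil[idx0] = "seed"
    rank[idx0] = 0
    n_rank = 1

    offsets = [(-1, -1), (0, -1), (1, -1), (-1, 0), (1, 0), (-1, 1), (0, 1), (1, 1)]
    heap = []
    counter = 0

    def push(col, row):
        nonlocal counter
        idx = row * W + col
        dist2 = (col - col0) ** 2 + (row - row0) ** 2
        counter += 1
        heapq.heappush(heap, (hl_flat[idx], -int(n_acc[idx]), dist2, idx, counter))

    def _axis_diff(idx, col_or_row, limit, stride):
        """Lagged one-axis gradient at a just-accepted pixel."""
        zc = Z[idx]
        lo_ok = col_or_row > 0 and accepted[idx - stride] and np.isfinite(Z[idx - stride])
        hi_ok = (col_or_row < limit - 1 and accepted[idx + stride]
                 and np.isfinite(Z[idx + stride]))
        if lo_ok and hi_ok:
            g = (Z[idx + stride] - Z[idx - stride]) / 2.0
        elif hi_ok:
            g = Z[idx + stride] - zc
        elif lo_ok:
            g = zc - Z[idx - stride]
        else:
            g = 0.0
        return min(max(g, -g_clip), g_clip)

    def accept(idx, zval, sten, flag=0):
        nonlocal n_rank
        Z[idx] = min(max(zval, zlo), zhi)
        accepted[idx] = True
        stencil[idx] = sten
        rank[idx] = n_rank
        n_rank += 1
        flags[idx] = flag
        row, col = divmod(idx, W)
        GX[idx] = _axis_diff(idx, col, W, 1)
        GY[idx] = _axis_diff(idx, row, H, W)
        for dx, dy in offsets:
            c, r = col + dx, row + dy
            if 0 <= c < W and 0 <= r < H:
                j = r * W + c
                if not accepted[j]:
                    n_acc[j] += 1
                    push(c, r)

    # bootstrap around the seed
    for dx, dy in offsets:
        c, r = col0 + dx, row0 + dy
        if 0 <= c < W and 0 <= r < H:
            n_acc[r * W + c] += 1
            push(c, r)

    pair_cache_idx = -1
    pops = 0
    while heap:
        _, _, _, idx, _ = heapq.heappop(heap)
        if accepted[idx]:
            continue
        pops += 1
        # candidate pairs at this pixel, brightest-sum first
        us = [(imgs_flat[k][idx], k) for k in range(n_img) if usable_flat[k][idx]]
        if len(us) < 2:
            accepted[idx] = True  # unreconstructable; leave NaN
            stencil[idx] = "unusable"
            continue
        us.sort(key=lambda t: -t[0])
        cand = []
        for a in range(len(us)):
            for b in range(a + 1, len(us)):
                Ia, ka = us[a]
                Ib, kb = us[b]
                if ka > kb:
                    ka, kb = kb, ka
                    Ia, Ib = Ib, Ia
                demoted = 0
                if demote_flat is not None:
                    demoted = demote_flat[ka][idx] + demote_flat[kb][idx]
                cand.append(((demoted, -(Ia + Ib)), (Ia, Ib, lights[ka], lights[kb])))
        cand.sort(key=lambda t: t[0])
        pairs = [c[1] for c in cand]
        row, col = divmod(idx, W)
        neighbors = {}
        grads = {}
        for dx, dy in offsets:
            c, r = col + dx, row + dy
            if 0 <= c < W and 0 <= r < H:
                j = r * W + c
                if accepted[j] and not np.isnan(Z[j]):
                    neighbors[(dx, dy)] = Z[j]
                    grads[(dx, dy)] = (GX[j], GY[j])
        if not neighbors:
            continue
        res = upwind_update(col - cx, row - cy, neighbors, pairs, cam,
                            step=step, tol=tol, max_iter=max_iter,
                            neighbor_gradients=grads)
        if res.status == "converged":
            accept(idx, res.z, res.stencil)
        elif res.status == "no_converge":
            accept(idx, res.z, res.stencil, flag=2)
        else:
            # deferred or degenerate: retry on later pushes; give up to
            # a neighbor-mean fallback once the neighborhood is full
            pops_left[idx] -= 1
            if pops_left[idx] <= 0 or (res.status == "degenerate"
                                       and len(neighbors) == 8):
                accept(idx, sum(neighbors.values()) / len(neighbors),
                       "mean", flag=1)

    valid = accepted & np.isfinite(Z)
    n_left = int(H * W - valid.sum())
    if n_left:
        log.warning("fast march left %d pixels unreconstructed", n_left)
    depth = DepthMap(z=Z.reshape(H, W), valid=valid.reshape(H, W), step=step,
                     seed_pixel=(col0, row0), seed_depth=float(seed_depth))
    if return_state:
        state = MarchState(accepted=accepted.reshape(H, W),
                           pair_lo=lo_arr, pair_hi=hi_arr,
                           stencil=stencil.reshape(H, W),
                           flags=flags.reshape(H, W),
                           order=rank.reshape(H, W), pops=pops)
        return depth, state
    return depth


@dataclass
class EvalResult:
    rmse_mm: float
    relative_rmse: float        # fraction, not percent
    error_map: np.ndarray       # signed, mm (NaN outside common mask)
    relative_error_map: np.ndarray
    n: int

    @property
    def relative_rmse_percent(self):
        return 100.0 * self.relative_rmse


def evaluate(pred: DepthMap, truth: DepthMap) -> EvalResult:
    """RMSE and relative RMSE of a reconstruction against ground truth.

    Per pixel over the common valid mask: error = Z - Z_true (mm) and
    relative error = |Z - Z_true| / |Z_true|; the aggregates are the
    root mean squares of each.
    """
    if pred.shape != truth.shape:
        raise ValueError("depth map shapes differ")
    mask = pred.valid & truth.valid
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty common valid mask")
    err = np.where(mask, pred.z - truth.z, np.nan)
    rel = np.abs(err) / np.abs(truth.z)
    rmse = float(np.sqrt(np.nanmean(err[mask] ** 2)))
    rel_rmse = float(np.sqrt(np.nanmean(rel[mask] ** 2)))
    return EvalResult(rmse_mm=rmse, relative_rmse=rel_rmse,
                      error_map=err, relative_error_map=rel, n=n)
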