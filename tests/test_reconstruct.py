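"""Upwind updates, pair selection, fast marching, evaluation."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import optimize

from capsuleps.depthmap import DepthMap
from capsuleps.rig import default_rig
from capsuleps.reconstruct import (
    _pair_terms,
    evaluate,
    fast_march,
    select_pair,
    upwind_update,
)
from capsuleps.scene import default_scene, render
from capsuleps.seed import ratio_coefficients

from helpers import gauss_seidel_solve


def test_pair_terms_pins_to_ratio_coefficients():
    """The march's flat-scalar coefficient path must agree with the
    reference implementation used by the seed module."""
    rig = default_rig()
    rng = np.random.default_rng(4)
    for _ in range(50):
        x, y = rng.uniform(-250, 250), rng.uniform(-200, 200)
        z = rng.uniform(-60, -6)
        I1, I2 = rng.uniform(0.1, 2.0, 2)
        l1, l2 = rig.lights[0], rig.lights[1]
        fxi, feta, s, _ = _pair_terms(x, y, z, I1, I2, l1.position,
                                      l2.position, rig.camera.f)
        F = ratio_coefficients(x, y, z, I1, I2, l1, l2, rig.camera)
        assert fxi == pytest.approx(float(F.F_xi), rel=1e-12)
        assert feta == pytest.approx(float(F.F_eta), rel=1e-12)
        assert s == pytest.approx(float(F.s), rel=1e-12)


def _pixel_pair(ns, col, row, i1, i2):
    return (float(ns.lum[i1][row, col]), float(ns.lum[i2][row, col]),
            ns.rig.lights[i1], ns.rig.lights[i2])


def test_update_fixed_point_on_plane(lambert_plane_small):
    """All upwind neighbors at the true plane depth and s(Z0) = 0:
    the update returns Z0."""
    ns = lambert_plane_small
    cam = ns.rig.camera
    col, row = 50, 40
    z0 = -21.37
    neighbors = {(dx, dy): z0 for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                 if (dx, dy) != (0, 0)}
    res = upwind_update(col - cam.cx, row - cam.cy, neighbors,
                        [_pixel_pair(ns, col, row, 0, 1)], cam)
    assert res.status == "converged"
    assert res.z == pytest.approx(z0, abs=1e-9)


def test_update_matches_bisection_oracle(lambert_polyp):
    """The fixed-point solve agrees with a brentq root of the same
    scalar equation to 1e-9."""
    ns = lambert_polyp
    cam = ns.rig.camera
    gt = ns.render.ground_truth.z
    for col, row in ((360, 250), (300, 220), (380, 300)):
        pair = _pixel_pair(ns, col, row, 0, 1)
        neighbors = {(dx, dy): gt[row + dy, col + dx]
                     for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                     if (dx, dy) != (0, 0)}
        res = upwind_update(col - cam.cx, row - cam.cy, neighbors, [pair],
                            cam, tol=1e-12)
        assert res.status == "converged" and res.stencil == "xy"

        I1, I2, l1, l2 = pair

        def g(Z):
            fxi, feta, s, _ = _pair_terms(col - cam.cx, row - cam.cy, Z,
                                          I1, I2, l1.position, l2.position,
                                          cam.f)
            sx = 1 if fxi > 0 else -1
            sy = 1 if feta > 0 else -1
            ax = neighbors[(-sx, 0)]
            ay = neighbors[(0, -sy)]
            return Z * (abs(fxi) + abs(feta)) - (abs(fxi) * ax
                                                 + abs(feta) * ay + s)

        root = optimize.brentq(g, res.z - 0.5, res.z + 0.5, xtol=1e-12)
        assert res.z == pytest.approx(root, abs=1e-9)


def test_update_defers_without_neighbors(lambert_plane_small):
    ns = lambert_plane_small
    cam = ns.rig.camera
    res = upwind_update(0.0, 0.0, {}, [_pixel_pair(ns, 50, 40, 0, 1)], cam)
    assert res.status == "deferred" and res.z is None


def test_select_pair_brightest_usable():
    shape = (4, 4)
    imgs = [np.full(shape, v) for v in (0.1, 0.5, 0.9, 0.7)]
    lo, hi, n = select_pair(imgs)
    assert np.all(lo == 2) and np.all(hi == 3)
    assert np.all(n == 4)


def test_select_pair_mask_gate_and_floor():
    shape = (3, 3)
    imgs = [np.full(shape, v) for v in (1.0, 0.8, 0.6, 0.4)]
    masks = [np.zeros(shape, bool) for _ in range(4)]
    masks[0][1, 1] = True               # brightest image masked at center
    lo, hi, n = select_pair(imgs, masks)
    assert (lo[1, 1], hi[1, 1]) == (1, 2)
    assert (lo[0, 0], hi[0, 0]) == (0, 1)
    # fewer than two usable images -> unreconstructable
    masks2 = [np.ones(shape, bool) for _ in range(4)]
    masks2[3][:] = False
    lo2, hi2, n2 = select_pair(imgs, masks2)
    assert np.all(lo2 == -1) and np.all(n2 == 1)


def test_plane_recovery_with_exact_seed(lambert_plane_small):
    """Noiseless plane, exact seed: the whole frame reconstructs to a
    relative RMSE far below 0.5%."""
    ns = lambert_plane_small
    cam = ns.rig.camera
    seed = (cam.width // 2, cam.height // 2)
    depth = fast_march(ns.lum, None, ns.rig, seed, -21.37)
    ev = evaluate(depth, ns.render.ground_truth)
    assert depth.valid.all()
    assert ev.relative_rmse < 0.005
    assert ev.rmse_mm < 0.02


def test_seed_pixel_reproduced_exactly(lambert_polyp_small):
    ns = lambert_polyp_small
    cam = ns.rig.camera
    seed = (cam.width // 2 + 5, cam.height // 2)
    z0 = float(ns.render.ground_truth.z[seed[1], seed[0]]) - 0.123
    depth = fast_march(ns.lum, None, ns.rig, seed, z0)
    assert depth.z[seed[1], seed[0]] == z0
    assert depth.seed_depth == z0


def test_march_is_deterministic(lambert_polyp_small):
    ns = lambert_polyp_small
    cam = ns.rig.camera
    seed = (cam.width // 2, cam.height // 2)
    z0 = float(ns.render.ground_truth.z[seed[1], seed[0]])
    a = fast_march(ns.lum, None, ns.rig, seed, z0)
    b = fast_march(ns.lum, None, ns.rig, seed, z0)
    assert np.array_equal(a.z, b.z, equal_nan=True)
    assert np.array_equal(a.valid, b.valid)


def test_rmse_monotone_in_seed_error(lambert_polyp_small):
    """Reconstruction RMSE is non-decreasing in |seed error| for each
    sign of the perturbation."""
    ns = lambert_polyp_small
    cam = ns.rig.camera
    seed = (cam.width // 2, cam.height // 2)
    z_true = float(ns.render.ground_truth.z[seed[1], seed[0]])
    rmse = {}
    for off in (0.0, 0.25, 0.5, 1.0, -0.25, -0.5, -1.0):
        d = fast_march(ns.lum, None, ns.rig, seed, z_true + off)
        rmse[off] = evaluate(d, ns.render.ground_truth).rmse_mm
    for chain in ((0.0, 0.25, 0.5, 1.0), (0.0, -0.25, -0.5, -1.0)):
        vals = [rmse[o] for o in chain]
        assert all(a <= b + 1e-9 for a, b in zip(vals, vals[1:])), rmse


def test_march_matches_gauss_seidel_on_crop(lambert_polyp_small):
    """On a small crop the single-pass march agrees with a brute-force
    iterative solution of the same discrete equations to <= 1e-3 mm."""
    ns = lambert_polyp_small
    cam = ns.rig.camera
    r0, c0 = cam.height // 2 - 16, cam.width // 2 - 16
    crop = [im[r0:r0 + 32, c0:c0 + 32] for im in ns.lum]
    from capsuleps.geometry import CameraModel
    from capsuleps.rig import Rig

    crop_cam = CameraModel(f=cam.f, cx=cam.cx - c0, cy=cam.cy - r0,
                           width=32, height=32)
    crop_rig = Rig(camera=crop_cam, lights=ns.rig.lights)
    seed = (16, 16)
    z0 = float(ns.render.ground_truth.z[r0 + 16, c0 + 16])
    fm, state = fast_march(crop, None, crop_rig, seed, z0, return_state=True)
    gs = gauss_seidel_solve(crop, crop_rig, seed, z0, upwind_update,
                            state.order, n_sweeps=200, tol=1e-9)
    diff = np.abs(fm.z - gs)[fm.valid]
    assert np.max(diff) <= 1e-3


def test_coarser_grid_reconstructs_worse(lambert_polyp_small):
    """First-order consistency: halving the resolution (same field of
    view) increases the reconstruction error."""
    ns = lambert_polyp_small
    cam = ns.rig.camera
    seed = (cam.width // 2, cam.height // 2)
    z0 = float(ns.render.ground_truth.z[seed[1], seed[0]])
    fine = evaluate(fast_march(ns.lum, None, ns.rig, seed, z0),
                    ns.render.ground_truth).rmse_mm

    coarse_rig = default_rig(80, 60, f=70.625)
    res = render(replace(default_scene(), k_s=0.0), coarse_rig)
    from capsuleps.radiometry import luminance

    lum = [luminance(im) for im in res.images]
    seed_c = (40, 30)
    z0c = float(res.ground_truth.z[30, 40])
    coarse = evaluate(fast_march(lum, None, coarse_rig, seed_c, z0c),
                      res.ground_truth).rmse_mm
    assert coarse > fine


def test_highlight_pixels_marched_last(polyp):
    """Pixels inside highlight masks carry the lowest propagation
    priority but are still reconstructed (from pairs excluding their
    specular image)."""
    ns = polyp
    col, row = ns.region.centroid
    z0 = float(ns.render.ground_truth.z[row, col])
    # crop to keep the march small: 96x96 around the seed
    r0, c0 = row - 48, col - 48
    crop = [im[r0:r0 + 96, c0:c0 + 96] for im in ns.lum]
    masks = [m[r0:r0 + 96, c0:c0 + 96] for m in ns.masks]
    from capsuleps.geometry import CameraModel
    from capsuleps.rig import Rig

    cam = ns.rig.camera
    crop_cam = CameraModel(f=cam.f, cx=cam.cx - c0, cy=cam.cy - r0,
                           width=96, height=96)
    crop_rig = Rig(camera=crop_cam, lights=ns.rig.lights)
    depth, state = fast_march(crop, masks, crop_rig, (48, 48), z0,
                              return_state=True)
    inside = masks[ns.region.source_index]
    # pixels where fewer than two images survive the masks (the overlap
    # of all four dilated disks) are unreconstructable by construction
    _, _, n_usable = select_pair(crop, masks)
    reachable = inside & (n_usable >= 2)
    assert reachable.sum() > 0.9 * inside.sum()
    assert depth.valid[reachable].all()
    assert np.isfinite(depth.z[reachable]).all()


# ---------------------------------------------------------------------------
# evaluation

def test_evaluate_identical_maps():
    z = np.full((8, 8), -20.0)
    d = DepthMap(z=z, valid=np.ones_like(z, bool))
    ev = evaluate(d, d)
    assert ev.rmse_mm == 0.0 and ev.relative_rmse == 0.0


def test_evaluate_constant_offset_closed_form():
    z0, e = -20.0, 0.37
    truth = DepthMap(z=np.full((6, 9), z0), valid=np.ones((6, 9), bool))
    pred = DepthMap(z=np.full((6, 9), z0 + e), valid=np.ones((6, 9), bool))
    ev = evaluate(pred, truth)
    assert ev.rmse_mm == pytest.approx(e)
    assert ev.relative_rmse == pytest.approx(e / abs(z0))
    assert ev.relative_rmse_percent == pytest.approx(100 * e / abs(z0))


def test_evaluate_matches_direct_summation_oracle():
    rng = np.random.default_rng(9)
    truth = -20.0 + rng.normal(0, 1, (30, 40))
    pred = truth + rng.normal(0, 0.3, truth.shape)
    valid = rng.random(truth.shape) > 0.1
    ev = evaluate(DepthMap(z=pred, valid=valid),
                  DepthMap(z=truth, valid=np.ones_like(valid)))
    acc = n = 0
    acc_rel = 0.0
    for r in range(truth.shape[0]):
        for c in range(truth.shape[1]):
            if valid[r, c]:
                d = pred[r, c] - truth[r, c]
                acc += d * d
                acc_rel += (abs(d) / abs(truth[r, c])) ** 2
                n += 1
    assert ev.rmse_mm == pytest.approx(np.sqrt(acc / n), abs=1e-12)
    assert ev.relative_rmse == pytest.approx(np.sqrt(acc_rel / n), abs=1e-12)
    assert ev.n == n


def test_evaluate_errors():
    a = DepthMap(z=np.full((4, 4), -20.0), valid=np.zeros((4, 4), bool))
    with pytest.raises(ValueError):
        evaluate(a, a)
    b = DepthMap(z=np.full((5, 4), -20.0), valid=np.ones((5, 4), bool))
    with pytest.raises(ValueError):
        evaluate(a, b)
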