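"""Independent oracles used by the tests.

Everything here is deliberately written from first principles (plain
vector geometry, brute-force iteration) rather than through the package
APIs it is used to check.
"""

import numpy as np


def unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def surface_point(x, y, z, f):
    """Camera-frame position of the point imaged at centered pixel (x, y)."""
    return np.stack(np.broadcast_arrays(-x * z / f, -y * z / f, z), axis=-1)


def lambert_intensity(P, N, light_pos, rho=1.0):
    """Near-point-source Lambertian irradiance at a surface point.

    Inverse-square falloff, cosine radial falloff about the -z emission
    axis, times the incidence cosine.  Pure vector geometry.
    """
    P = np.asarray(P, float)
    L = np.asarray(light_pos, float) - P
    dist = np.linalg.norm(L, axis=-1)
    lhat = L / dist[..., None]
    a = (1.0 / dist**2) * lhat[..., 2]      # radial cosine: prop dir vs -z
    return a * rho * np.clip(np.sum(lhat * np.asarray(N), axis=-1), 0, None)


def gauss_seidel_solve(images, rig, seed_pixel, seed_depth, upwind_update,
                       order, n_sweeps=400, tol=1e-10, rng_seed=123):
    """Brute-force iterative re-solution of the march's discrete system.

    The image-ratio transport equation has no relaxation mechanism, so
    its discrete form is well-posed only together with a causal
    dependency structure: each pixel's stencil may draw on neighbors
    that precede it in ``order`` (the march's acceptance ranks).  This
    oracle initializes every pixel at the seed depth and Gauss-Seidel
    sweeps the grid in *randomized* pixel orders, re-solving each pixel
    from the current values of its causally admissible neighbors, until
    the largest update falls below ``tol``.  It shares only the local
    single-pixel solver with the fast march; the global strategy
    (iterate-to-convergence in arbitrary order) is entirely different.
    """
    cam = rig.camera
    H, W = images[0].shape
    col0, row0 = seed_pixel
    Z = np.full((H, W), float(seed_depth))
    lights = rig.lights
    n = len(images)
    rng = np.random.default_rng(rng_seed)
    pix = [(r, c) for r in range(H) for c in range(W)
           if (r, c) != (row0, col0) and order[r, c] >= 0]

    for it in range(n_sweeps):
        delta = 0.0
        rng.shuffle(pix)
        for r, c in pix:
            vals = sorted(((images[k][r, c], k) for k in range(n)),
                          key=lambda t: -t[0])
            pairs = []
            for a in range(n):
                for b in range(a + 1, n):
                    Ia, ka = vals[a]
                    Ib, kb = vals[b]
                    if ka > kb:
                        ka, kb = kb, ka
                        Ia, Ib = Ib, Ia
                    pairs.append((Ia, Ib, lights[ka], lights[kb]))
            neighbors = {}
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    if dx == dy == 0:
                        continue
                    rr, cc = r + dy, c + dx
                    if (0 <= rr < H and 0 <= cc < W
                            and 0 <= order[rr, cc] < order[r, c]):
                        neighbors[(dx, dy)] = Z[rr, cc]
            res = upwind_update(c - cam.cx, r - cam.cy, neighbors, pairs, cam,
                                z0=Z[r, c], tol=1e-9)
            if res.z is not None:
                delta = max(delta, abs(res.z - Z[r, c]))
                Z[r, c] = res.z
        if delta < tol:
            break
    return Z
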