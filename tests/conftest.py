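"""Shared fixtures: rigs and rendered scenes reused across the suite.

Rendering is cheap (vectorized) but fast-marching a full 640x480 frame
is not, so the expensive pipeline runs are session-scoped and shared
between the unit tests and the acceptance tests.
"""

from dataclasses import replace
from types import SimpleNamespace

import numpy as np
import pytest

from capsuleps import detect as _detect
from capsuleps.pipeline import run_pipeline
from capsuleps.radiometry import luminance
from capsuleps.rig import default_rig
from capsuleps.scene import SurfaceSpec, default_scene, render


@pytest.fixture(scope="session")
def rig():
    """Full-resolution capsule rig (640x480, f=565 px, LEDs at 5.5 mm)."""
    return default_rig()


@pytest.fixture(scope="session")
def small_rig():
    """Same field of view at quarter resolution, for march-heavy tests."""
    return default_rig(160, 120, f=141.25)


def _stack(spec, rig_, mask_dilation=18, demote_dilation=30):
    res = render(spec, rig_)
    lum = [luminance(im) for im in res.images]
    regions = _detect.detect_stack(res.images)
    ns = SimpleNamespace(spec=spec, rig=rig_, render=res, lum=lum,
                         regions=regions, region=None, masks=None, demote=None)
    if any(regions):
        region, _ = _detect.select_seed_region(regions)
        ns.region = region
        ns.masks = _detect.combined_masks(regions, lum[0].shape,
                                          n_images=len(lum),
                                          dilate=mask_dilation)
        ns.demote = _detect.combined_masks(regions, lum[0].shape,
                                           n_images=len(lum),
                                           dilate=demote_dilation)
    return ns


@pytest.fixture(scope="session")
def polyp(rig):
    """Default polyp scene rendered under the default rig, with
    detection products (regions, hard and soft masks)."""
    return _stack(default_scene(), rig)


@pytest.fixture(scope="session")
def lambert_polyp(rig):
    """Same scene with the specular lobe switched off (k_s = 0)."""
    return _stack(replace(default_scene(), k_s=0.0), rig)


@pytest.fixture(scope="session")
def lambert_polyp_small(small_rig):
    """Quarter-resolution Lambertian polyp for march-heavy tests."""
    return _stack(replace(default_scene(), k_s=0.0), small_rig)


@pytest.fixture(scope="session")
def lambert_plane_small(small_rig):
    """Quarter-resolution Lambertian fronto-parallel plane."""
    return _stack(SurfaceSpec(kind="plane", k_s=0.0), small_rig)


@pytest.fixture(scope="session")
def full_pipeline(rig):
    """The end-to-end run: render, detect, estimate the centroid seed,
    fast-march, evaluate.  Shared by the exact-seed reconstruction and
    seed-estimator acceptance checks."""
    return run_pipeline(rig=rig)


@pytest.fixture(scope="session")
def seed_result(polyp):
    """Per-pixel seed-depth estimates over the selected highlight region."""
    from capsuleps.seed import estimate_seed_depth

    return estimate_seed_depth(polyp.region, polyp.lum, polyp.masks, polyp.rig)
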