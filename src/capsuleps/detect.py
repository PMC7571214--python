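"""Specular highlight detection and seed-region selection.

Highlight pixels are simultaneously bright and desaturated (the
specular lobe reflects the white source color rather than the tissue
albedo).  Detection thresholds saturation below ``saturation_max`` and
intensity above ``intensity_min`` (by default relative to the image
maximum, which makes detection invariant to global exposure scaling),
groups surviving pixels by 8-connectivity, drops specks, and reports
intensity-weighted centroids.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
from skimage import measure

from .errors import SeedUnavailableError

__all__ = ["HighlightRegion", "detect_highlights", "select_seed_region",
           "detect_stack", "save_regions"]


@dataclass
class HighlightRegion:
    """A detected specular region in one image.

    ``centroid`` is the intensity-weighted mean pixel of the region in
    raster (column, row) coordinates, rounded to the nearest pixel.
    ``source_index`` is the light that was active in the image the
    region was found in.
    """

    mask: np.ndarray
    centroid: tuple[int, int]
    source_index: int
    area: int

    def __post_init__(self):
        if self.area <= 0 or not self.mask.any():
            raise ValueError("highlight region must be nonempty")


def _saturation_intensity(image):
    """HSV-style saturation and channel-mean intensity of a float image."""
    img = np.asarray(image, float)
    if img.ndim == 2:
        return None, img
    mx = img.max(axis=-1)
    mn = img.min(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(mx > 0, (mx - mn) / mx, 0.0)
    return sat, img.mean(axis=-1)


def detect_highlights(image, source_index: int = 0, saturation_max: float = 0.3,
                      intensity_min: float = 0.9, intensity_mode: str = "relative",
                      min_area: int = 5) -> list[HighlightRegion]:
    """Find specular highlight regions in a single image.

    Parameters
    ----------
    image : array
        (H, W, 3) color or (H, W) intensity image, linear float.
        Grayscale input falls back to the intensity rule alone.
    saturation_max, intensity_min : float
        Detection gates.  ``intensity_min`` is a fraction of the image
        maximum in 'relative' mode, a quantile in 'quantile' mode, or
        an absolute level in 'absolute' mode.
    min_area : int
        Regions smaller than this many pixels are dropped as noise.

    Returns regions sorted by descending area; empty list if nothing
    qualifies.
    """
    sat, inten = _saturation_intensity(image)
    if intensity_mode == "relative":
        thresh = intensity_min * inten.max()
    elif intensity_mode == "quantile":
        thresh = np.quantile(inten, intensity_min)
    elif intensity_mode == "absolute":
        thresh = intensity_min
    else:
        raise ValueError(f"unknown intensity_mode {intensity_mode!r}")
    cand = inten > thresh
    if sat is not None:
        cand &= sat < saturation_max
    labels = measure.label(cand, connectivity=2)
    regions = []
    for props in measure.regionprops(labels, intensity_image=inten):
        if props.area < min_area:
            continue
        mask = labels == props.label
        # intensity-weighted centroid, (row, col) -> (col, row)
        r, c = props.centroid_weighted
        centroid = (int(round(c)), int(round(r)))
        regions.append(HighlightRegion(mask=mask, centroid=centroid,
                                       source_index=source_index,
                                       area=int(props.area)))
    regions.sort(key=lambda reg: -reg.area)
    return regions


def detect_stack(images, active_sources=None, **kwargs):
    """Run detection on each image of a photometric-stereo stack.

    Returns a list (one entry per image) of region lists.
    """
    if active_sources is None:
        active_sources = list(range(len(images)))
    return [
        detect_highlights(img, source_index=k, **kwargs)
        for img, k in zip(images, active_sources)
    ]


def select_seed_region(regions_per_image) -> tuple[HighlightRegion, list[int]]:
    """Choose the seed (sigma) region and the Lambertian delta set.

    The largest-area region across all images wins; ties go to the
    lowest source index.  The remaining sources form the delta set,
    whose images provide the Lambertian ratio equations.  Every image's
    own highlight mask is excluded from its Lambertian use downstream.

    Raises
    ------
    SeedUnavailableError
        If no image contains any highlight region.
    """
    best = None
    all_sources = set()
    for regions in regions_per_image:
        for reg in regions:
            all_sources.add(reg.source_index)
            if best is None or (reg.area, -reg.source_index) > (best.area, -best.source_index):
                best = reg
    # sources present in the stack, regardless of detections
    n_images = len(regions_per_image)
    if best is None:
        raise SeedUnavailableError("no specular highlight found in any image")
    delta = [k for k in range(n_images) if k != best.source_index]
    return best, delta


def combined_masks(regions_per_image, shape, n_images=None, dilate: int = 0):
    """Per-image boolean highlight masks (union of that image's regions).

    ``dilate`` grows each mask by that many binary-dilation steps.
    The thresholded region only covers the core of the specular lobe;
    its tails still violate the Lambertian model for another one or
    two dozen pixels, so downstream consumers dilate the exclusion
    masks well past the detected core.
    """
    from scipy import ndimage

    if n_images is None:
        n_images = len(regions_per_image)
    masks = [np.zeros(shape, bool) for _ in range(n_images)]
    for i, regions in enumerate(regions_per_image):
        for reg in regions:
            masks[i] |= reg.mask
    if dilate > 0:
        masks = [ndimage.binary_dilation(m, iterations=dilate) if m.any() else m
                 for m in masks]
    return masks


def save_regions(regions_per_image, path) -> None:
    """Write a JSON manifest of all detected regions."""
    doc = [
        [
            {"centroid": list(map(int, reg.centroid)), "area": reg.area,
             "source_index": reg.source_index}
            for reg in regions
        ]
        for regions in regions_per_image
    ]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
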