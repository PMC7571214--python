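"""Camera response inversion and illuminance-map pre-filtering.

Raw pixel values relate to sensor illuminance through the camera's
radiometric response.  The calibration experiment that measures the
response is out of scope here; this module consumes its result (a
response model) and inverts it, then optionally denoises the resulting
float illuminance maps (Gaussian blur against white noise, median
filter against salt-and-pepper noise).

The synthetic pipeline uses the linear response: rendered intensities
are already proportional to illuminance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["ResponseModel", "to_illuminance", "denoise", "luminance"]


@dataclass(frozen=True)
class ResponseModel:
    """Monotone map from normalized illuminance to normalized pixel value.

    kind 'linear': identity.
    kind 'gamma':  v = e**(1/gamma)  (display gamma; inverse e = v**gamma).
    kind 'lut':    monotone table of (input, output) samples on [0, 1],
                   inverted by interpolation.
    """

    kind: str = "linear"
    gamma: float = 2.2
    lut_in: tuple = ()
    lut_out: tuple = ()

    def __post_init__(self):
        if self.kind not in ("linear", "gamma", "lut"):
            raise ValueError(f"unknown response kind {self.kind!r}")
        if self.kind == "gamma" and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.kind == "lut":
            vin = np.asarray(self.lut_in, float)
            vout = np.asarray(self.lut_out, float)
            if vin.size < 2 or vin.size != vout.size:
                raise ValueError("LUT needs >= 2 paired samples")
            if np.any(np.diff(vin) <= 0) or np.any(np.diff(vout) <= 0):
                raise ValueError("LUT must be strictly monotone")

    @classmethod
    def linear(cls) -> "ResponseModel":
        return cls(kind="linear")

    @classmethod
    def from_gamma(cls, gamma: float) -> "ResponseModel":
        return cls(kind="gamma", gamma=gamma)

    @classmethod
    def from_lut(cls, lut_in, lut_out) -> "ResponseModel":
        return cls(kind="lut", lut_in=tuple(lut_in), lut_out=tuple(lut_out))

    @classmethod
    def from_dict(cls, doc: dict) -> "ResponseModel":
        kind = doc.get("kind", "linear")
        if kind == "linear":
            return cls.linear()
        if kind == "gamma":
            return cls.from_gamma(float(doc["gamma"]))
        return cls.from_lut(doc["lut_in"], doc["lut_out"])

    def to_dict(self) -> dict:
        if self.kind == "linear":
            return {"kind": "linear"}
        if self.kind == "gamma":
            return {"kind": "gamma", "gamma": self.gamma}
        return {"kind": "lut", "lut_in": list(self.lut_in),
                "lut_out": list(self.lut_out)}

    def forward(self, e):
        """Illuminance -> pixel value, both normalized to [0, 1]."""
        e = np.asarray(e, float)
        if self.kind == "linear":
            return e
        if self.kind == "gamma":
            return np.power(np.clip(e, 0.0, None), 1.0 / self.gamma)
        return np.interp(e, self.lut_in, self.lut_out)

    def inverse(self, v):
        """Pixel value -> illuminance, both normalized to [0, 1]."""
        v = np.asarray(v, float)
        if self.kind == "linear":
            return v
        if self.kind == "gamma":
            return np.power(np.clip(v, 0.0, None), self.gamma)
        return np.interp(v, self.lut_out, self.lut_in)


def to_illuminance(raw, model: ResponseModel | None = None):
    """Convert a raw image to a float illuminance map.

    Integer images are normalized by their dtype maximum first; float
    images are used as-is.  The response inverse is applied per pixel
    (per channel for RGB).  Pixel ordering is preserved because the
    response is strictly monotone.
    """
    raw = np.asarray(raw)
    if np.issubdtype(raw.dtype, np.integer):
        img = raw.astype(float) / np.iinfo(raw.dtype).max
    else:
        img = raw.astype(float)
    if model is None or model.kind == "linear":
        return img
    return model.inverse(img)


def denoise(illum, sigma: float = 1.0, median_size: int = 3, mask=None):
    """Gaussian blur (sigma px) then median filter (median_size box).

    Works per channel for multichannel maps.  If ``mask`` is given,
    masked-out pixels are left untouched.
    """
    illum = np.asarray(illum, float)
    out = np.empty_like(illum)
    chans = illum[..., None] if illum.ndim == 2 else illum
    res = np.empty_like(chans)
    for c in range(chans.shape[-1]):
        g = ndimage.gaussian_filter(chans[..., c], sigma=sigma)
        res[..., c] = ndimage.median_filter(g, size=median_size)
    out = res[..., 0] if illum.ndim == 2 else res
    if mask is not None:
        out = np.where(np.asarray(mask, bool), out, illum)
    return out


def luminance(img):
    """Channel-mean luminance of an RGB map (identity for 2-D maps).

    All PDE computations run on luminance; color is only used for
    highlight detection.
    """
    img = np.asarray(img, float)
    return img if img.ndim == 2 else img.mean(axis=-1)
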