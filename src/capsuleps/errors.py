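"""Exception types raised by the reconstruction pipeline."""


class CapsulePSError(Exception):
    """Base class for all package errors."""


class DegenerateGeometryError(CapsulePSError):
    """Light source coincides with the surface point, or z = 0."""


class DegenerateNormalError(CapsulePSError):
    """The unnormalized surface normal has zero length."""


class DegenerateSpecularError(CapsulePSError):
    """The specular-gradient denominator vanishes at this pixel."""


class SeedUnavailableError(CapsulePSError):
    """No specular highlight was found in any input image."""


class UnusablePixelError(CapsulePSError):
    """A pixel has no usable Lambertian image pair (zero illuminance or
    masked in every candidate image)."""
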