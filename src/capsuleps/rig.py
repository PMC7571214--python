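"""Rig configuration: camera + four LED light sources, YAML round-trip.

The default rig mirrors the capsule-endoscope head used throughout this
package: a 640x480 pinhole camera with f = 565 px and four identical
LEDs placed around the lens at 5.5 mm centrifugal distance, in the
camera plane (zeta = 0), principal directions along -z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .geometry import CameraModel, LightSource
from .radiometry import ResponseModel

__all__ = ["Rig", "default_rig", "load_rig", "save_rig"]


@dataclass
class Rig:
    camera: CameraModel
    lights: list[LightSource]
    response: ResponseModel = field(default_factory=ResponseModel.linear)

    def __post_init__(self):
        if len(self.lights) < 2:
            raise ValueError("a photometric-stereo rig needs at least two lights")


def default_rig(width: int = 640, height: int = 480, f: float = 565.0,
                led_distance: float = 5.5) -> Rig:
    """The standard capsule-head rig.

    Lights are indexed 0..3 counterclockwise starting on the +x axis:
    (+d, 0), (0, +d), (-d, 0), (0, -d), all at zeta = 0 mm.

    The principal point defaults to (width/2, height/2), which puts a
    pixel row and column exactly on each symmetry axis of the rig.

    When ``width``/``height`` are scaled, pass an ``f`` scaled by the
    same factor to keep the field of view; the scene geometry is
    unchanged.
    """
    cam = CameraModel(f=f, cx=width / 2.0, cy=height / 2.0,
                      width=width, height=height)
    d = led_distance
    lights = [
        LightSource(position=(d, 0.0, 0.0)),
        LightSource(position=(0.0, d, 0.0)),
        LightSource(position=(-d, 0.0, 0.0)),
        LightSource(position=(0.0, -d, 0.0)),
    ]
    return Rig(camera=cam, lights=lights)


def load_rig(path) -> Rig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    c = doc["camera"]
    cam = CameraModel(f=float(c["f"]), cx=float(c["cx"]), cy=float(c["cy"]),
                      width=int(c["width"]), height=int(c["height"]))
    lights = [
        LightSource(
            position=tuple(l["position_mm"]),
            principal_direction=tuple(l.get("principal_direction", (0, 0, -1))),
            intensity=float(l.get("intensity", 1.0)),
        )
        for l in doc["lights"]
    ]
    resp = ResponseModel.from_dict(doc.get("response", {"kind": "linear"}))
    return Rig(camera=cam, lights=lights, response=resp)


def save_rig(rig: Rig, path) -> None:
    doc = {
        "camera": {
            "f": rig.camera.f, "cx": rig.camera.cx, "cy": rig.camera.cy,
            "width": rig.camera.width, "height": rig.camera.height,
        },
        "lights": [
            {
                "position_mm": list(l.position),
                "principal_direction": list(l.principal_direction),
                "intensity": l.intensity,
            }
            for l in rig.lights
        ],
        "response": rig.response.to_dict(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
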