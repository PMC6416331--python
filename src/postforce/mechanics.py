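"""Cantilever mechanics and channel-flow arithmetic for block-and-post sensors.

The force sensor is a slender PDMS micropost: a platelet aggregate that
envelops the post tip pulls it toward the upstream block, and Euler-Bernoulli
beam theory converts the tip deflection ``delta`` into a force

    F = (3 pi E D^4 / 64 H^3) * delta

with ``E`` the elastic modulus of the elastomer, ``D`` the post diameter and
``H`` its height.  Two device generations share a similar bending stiffness:
the first uses 4 um x 15 um posts, the second 6 um x 25 um posts so the same
force produces a larger, easier-to-image deflection on a bench-top system.

Unit conventions (package-wide): lengths in micrometres, forces in
nanonewtons, moduli in pascals.  Bending stiffness is reported in N/m
(1 N/m = 1000 nN/um); deflection->force conversion happens at the um/nN
boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "InvalidGeometryError",
    "PostGeometry",
    "DeviceGeneration",
    "ChannelSection",
    "GEN1",
    "GEN2",
    "bending_stiffness",
    "deflection_to_force",
    "wall_shear_rate",
    "flow_rate_for_shear",
]


class InvalidGeometryError(ValueError):
    """Raised when a geometry violates its physical invariants."""


@dataclass(frozen=True)
class PostGeometry:
    """Dimensions and modulus of one flexible post.

    Parameters
    ----------
    elastic_modulus : float
        Young's modulus of the elastomer, Pa.
    diameter : float
        Post diameter, um.
    height : float
        Post height, um.  Must exceed the diameter (slender-beam assumption).
    """

    elastic_modulus: float
    diameter: float
    height: float

    def __post_init__(self) -> None:
        for name in ("elastic_modulus", "diameter", "height"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise InvalidGeometryError(f"{name} must be finite and positive, got {v!r}")
        if self.diameter >= self.height:
            raise InvalidGeometryError(
                f"slender-cantilever assumption requires diameter < height "
                f"(got D={self.diameter} um, H={self.height} um)"
            )


@dataclass(frozen=True)
class DeviceGeneration:
    """One device design: post geometry plus block footprint and array pitch.

    ``block_footprint`` is (width, depth) in um, ``block_height`` in um,
    ``array_pitch`` the centre-to-centre spacing of the staggered sensor
    array in um.
    """

    name: str
    post: PostGeometry
    block_footprint: tuple[float, float]
    block_height: float
    array_pitch: float

    def __post_init__(self) -> None:
        if self.block_height <= 0 or self.array_pitch <= 0:
            raise InvalidGeometryError("block_height and array_pitch must be positive")
        if any(d <= 0 for d in self.block_footprint):
            raise InvalidGeometryError("block footprint dimensions must be positive")


PDMS_MODULUS_PA = 3.8e6

#: First-generation design: 4 um x 15 um posts, 15x15 um blocks 25 um tall.
GEN1 = DeviceGeneration(
    name="gen1",
    post=PostGeometry(elastic_modulus=PDMS_MODULUS_PA, diameter=4.0, height=15.0),
    block_footprint=(15.0, 15.0),
    block_height=25.0,
    array_pitch=60.0,
)

#: Second-generation design: 6 um x 25 um posts, 25x25 um blocks 15 um tall.
GEN2 = DeviceGeneration(
    name="gen2",
    post=PostGeometry(elastic_modulus=PDMS_MODULUS_PA, diameter=6.0, height=25.0),
    block_footprint=(25.0, 25.0),
    block_height=15.0,
    array_pitch=80.0,
)

GENERATIONS = {"gen1": GEN1, "gen2": GEN2}


@dataclass(frozen=True)
class ChannelSection:
    """Rectangular flow-channel cross-section: width in mm, height in um.

    The parallel-plate shear formula assumes a wide shallow channel; a
    ``UserWarning`` is emitted when width < 10 x height.
    """

    width_mm: float
    height_um: float
    warn: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_um <= 0:
            raise InvalidGeometryError("channel dimensions must be positive")
        if self.warn and self.width_mm * 1000.0 < 10.0 * self.height_um:
            warnings.warn(
                "channel aspect ratio w/h < 10: parallel-plate shear formula "
                "is approximate for this section",
                UserWarning,
                stacklevel=3,
            )


def bending_stiffness(geom: PostGeometry) -> float:
    """Bending stiffness k = 3 pi E D^4 / (64 H^3) of a post, in N/m.

    1 N/m = 1000 nN/um, so gen1's 0.0424 N/m is the 42.4 nN of force per
    micrometre of deflection quoted for the first-generation sensors.

    Examples
    --------
    >>> round(bending_stiffness(GEN1.post), 4)
    0.0424
    """
    E = geom.elastic_modulus            # Pa
    D = geom.diameter * 1e-6            # m
    H = geom.height * 1e-6              # m
    return 3.0 * math.pi * E * D**4 / (64.0 * H**3)


def deflection_to_force(deflection_um, geom: PostGeometry):
    """Convert tip deflection (um, signed) to force (nN, same sign).

    Positive deflection is toward the paired block (contractile).  Accepts
    scalars or arrays.
    """
    k = bending_stiffness(geom)
    # F[N] = k * (delta * 1e-6); in nN that is k * delta * 1e3
    return k * deflection_um * 1.0e3


def wall_shear_rate(flow_rate_ul_min: float, section: ChannelSection) -> float:
    """Wall shear rate (1/s) of a wide rectangular channel at a given flow rate.

    Uses the infinite-parallel-plate result ``gamma = 6 Q / (w h^2)``.
    ``flow_rate_ul_min`` in uL/min.
    """
    if flow_rate_ul_min < 0:
        raise ValueError("flow rate must be non-negative")
    q = flow_rate_ul_min * 1e-9 / 60.0          # m^3/s
    w = section.width_mm * 1e-3                 # m
    h = section.height_um * 1e-6                # m
    return 6.0 * q / (w * h * h)


def flow_rate_for_shear(shear_rate_per_s: float, section: ChannelSection) -> float:
    """Flow rate (uL/min) producing a target wall shear rate; inverse of
    :func:`wall_shear_rate`."""
    if shear_rate_per_s < 0:
        raise ValueError("shear rate must be non-negative")
    w = section.width_mm * 1e-3
    h = section.height_um * 1e-6
    q = shear_rate_per_s * w * h * h / 6.0      # m^3/s
    return q * 60.0 / 1e-9
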