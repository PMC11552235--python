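"""Physical parameters of the buried-capsule experiment.

Defaults follow the betaine-capsule setup: a 1 mL gel capsule shaped as a
prolate ellipsoid (full axes 16 mm x 6.3 mm x 6.3 mm) buried with its long
axis horizontal, amino-acid-like diffusivity ``D = 1e-9 m^2/s``, a 30-minute
trial, a sensory threshold at the permissive end of the 10–100 uM range, and
surface sampling of the topmost 0.5 mm of sand.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace  # noqa: F401  (replace re-exported for sweeps)

__all__ = ["PhysicalParams", "SpatialPoint", "ellipsoid_volume"]


#: A location in the tank, metres.  z = 0 is the sand/water interface,
#: z > 0 is sand (downward), z < 0 is water.
SpatialPoint = tuple[float, float, float]


def ellipsoid_volume(a_major: float, a_minor: float) -> float:
    """Volume of a prolate ellipsoid from its FULL axis lengths: (pi/6) a b^2."""
    return math.pi / 6.0 * a_major * a_minor**2


@dataclass(frozen=True)
class PhysicalParams:
    """All symbols of the diffusion model, strict SI.

    Attributes
    ----------
    D : diffusivity, m^2/s
    T : temperature, K
    eta : dynamic viscosity of water, Pa*s
    r_mol : molecular hydrodynamic radius, m
    c0 : capsule molar concentration, mol/m^3 (1 mM == 1 mol/m^3)
    V : capsule volume used for the total released moles M = c0*V, m^3
    a_major, a_minor : FULL axis lengths of the prolate capsule, m
    depth_l : burial depth of the capsule centre below the interface, m
    c_star : sensory detection threshold, mol/m^3
    t_max : trial duration, s
    layer_depth : thickness of the surface sand layer sampled by the legs, m
    """

    D: float = 1e-9
    T: float = 293.0
    eta: float = 1.0e-3
    r_mol: float = 2.15e-10
    c0: float = 100.0          # 100 mM
    V: float = 1.0e-6          # 1 mL
    a_major: float = 16.0e-3
    a_minor: float = 6.3e-3
    depth_l: float = 5.0e-3
    c_star: float = 0.01       # 10 uM
    t_max: float = 1800.0
    layer_depth: float = 0.5e-3
    volume_from_axes: bool = False

    def __post_init__(self) -> None:
        for name in ("D", "T", "eta", "r_mol", "c0", "V", "a_major", "a_minor",
                     "depth_l", "c_star", "t_max", "layer_depth"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ValueError(f"PhysicalParams.{name} must be a finite positive number, got {value!r}")
        if self.volume_from_axes:
            v_geom = ellipsoid_volume(self.a_major, self.a_minor)
            if abs(self.V - v_geom) > 0.01 * v_geom:
                raise ValueError(
                    f"V={self.V:g} m^3 inconsistent with axes-derived volume {v_geom:g} m^3 (>1%)"
                )
        if self.depth_l <= self.a_minor / 2.0:
            warnings.warn(
                "depth_l <= a_minor/2: the capsule pokes through the sand surface; "
                "the free-interface interpretation assumes it is fully buried",
                stacklevel=2,
            )

    @classmethod
    def from_axes(cls, **kwargs) -> "PhysicalParams":
        """Construct with V derived from the capsule axes (geometrically consistent)."""
        tmp = dict(kwargs)
        a_major = tmp.get("a_major", cls.a_major)
        a_minor = tmp.get("a_minor", cls.a_minor)
        tmp["V"] = ellipsoid_volume(a_major, a_minor)
        tmp["volume_from_axes"] = True
        return cls(**tmp)

    @property
    def geometric_volume(self) -> float:
        """Volume of the ellipsoid defined by the axes, m^3 (may differ from V)."""
        return ellipsoid_volume(self.a_major, self.a_minor)

    @property
    def total_moles(self) -> float:
        """Total released moles M = c0 * V."""
        return self.c0 * self.V

    @property
    def source_density(self) -> float:
        """Uniform molar density of the source, mol/m^3: M spread over the ellipsoid."""
        return self.total_moles / self.geometric_volume
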