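"""Point-source diffusion physics for chemicals spreading through water-logged sand.

A small molecule released at a point inside sand spreads by molecular diffusion
with diffusivity ``D`` (Stokes–Einstein).  Two bounding treatments of the
sand/water interface at ``z = 0`` are provided:

* *free interface* — still water above the sand; the interface is ignored and
  the concentration is the free-space heat kernel.
* *Dirichlet* — fast flow above the sand dilutes everything away instantly,
  pinning the concentration to zero at the interface; enforced with a mirror
  (image) sink at the reflected source position.

Coordinates: ``z = 0`` is the sand/water interface, ``z > 0`` is inside the
sand (increasing downward), ``z < 0`` is open water.  Strict SI units
throughout: metres, seconds, mol/m^3 (1 mM == 1 mol/m^3).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "BOLTZMANN",
    "stokes_einstein",
    "diffusion_length",
    "point_source_free",
    "point_source_dirichlet",
]

#: Boltzmann constant, J/K (CODATA exact value).
BOLTZMANN = 1.380649e-23


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.all(np.isfinite(value)) or np.any(np.asarray(value) <= 0):
            raise ValueError(f"{name} must be finite and strictly positive, got {value!r}")


def stokes_einstein(T: float, eta: float, r_mol: float) -> float:
    """Diffusivity of a spherical molecule: ``D = kT / (6 pi eta r)``.

    Parameters
    ----------
    T : float
        Temperature, K.
    eta : float
        Dynamic viscosity of water, Pa*s.
    r_mol : float
        Hydrodynamic radius of the molecule, m.

    Returns
    -------
    float
        Diffusivity, m^2/s.  For sub-nanometre molecules in room-temperature
        water this lands in the familiar 1e-10 to 1e-9 m^2/s range.
    """
    _require_positive(T=T, eta=eta, r_mol=r_mol)
    return BOLTZMANN * T / (6.0 * np.pi * eta * r_mol)


def diffusion_length(D: float, t) -> np.ndarray | float:
    """Characteristic distance ``sqrt(D t)`` travelled by diffusion in time ``t``."""
    _require_positive(D=D)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = np.sqrt(D * t)
    return float(out) if out.ndim == 0 else out


def _as_points(p) -> np.ndarray:
    """Coerce to an array of shape (..., 3)."""
    arr = np.asarray(p, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError(f"points must have a trailing axis of length 3, got shape {arr.shape}")
    return arr


def point_source_free(dM: float, source, probe, D: float, t: float):
    """Concentration from an instantaneous point release with no boundary.

    ``c = dM / (4 pi D t)^{3/2} * exp(-r^2 / (4 D t))`` with ``r`` the
    source–probe distance; the prefactor is the standard free-space heat
    kernel (``8 (pi D t)^{3/2} == (4 pi D t)^{3/2}``).

    ``source`` and ``probe`` are (..., 3) arrays (m); broadcasting applies.
    Returns concentration in mol/m^3.
    """
    _require_positive(D=D, t=t)
    if np.any(np.asarray(dM) < 0):
        raise ValueError("dM must be non-negative")
    src = _as_points(source)
    prb = _as_points(probe)
    r2 = np.sum((prb - src) ** 2, axis=-1)
    norm = (4.0 * np.pi * D * t) ** 1.5
    out = dM / norm * np.exp(-r2 / (4.0 * D * t))
    return float(out) if np.ndim(out) == 0 else out


def point_source_dirichlet(dM: float, source, probe, D: float, t: float):
    """Point release in sand with an absorbing (c = 0) sand/water interface.

    Method of images: the free kernel minus the kernel of a mirror source at
    ``(xs, ys, -zs)``.  Identically zero on the interface ``z = 0``; requires
    the real source to sit in sand (``zs >= 0``).
    """
    _require_positive(D=D, t=t)
    src = _as_points(source)
    if np.any(src[..., 2] < 0):
        raise ValueError("source must lie in sand (z >= 0) for the Dirichlet scenario")
    image = src * np.array([1.0, 1.0, -1.0])
    out = point_source_free(dM, src, probe, D, t) - point_source_free(dM, image, probe, D, t)
    return float(out) if np.ndim(out) == 0 else out
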