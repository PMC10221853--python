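"""Closed-form interaction potentials in reduced Lennard-Jones units.

Three interaction families make up the model:

* a truncated-and-shifted Lennard-Jones pair potential between beads
  (the purely repulsive WCA limit at ``epsilon=1, rc=2**(1/6)``),
* a FENE spring between chemically bonded neighbours,
* an integrated 9-3 wall acting on the distance from an implicit planar
  surface (repulsive when cut at its minimum ``(2/5)**(1/6)``, attractive
  when cut further out).

All energies are in units of kBT, lengths in bead diameters.  Each potential
is truncated so the energy is exactly zero beyond its cutoff, with the shift
chosen to make the energy continuous there.

The scalar :func:`effective_wall_strength` ranks wall attractiveness by the
Boltzmann-weighted integral I = int_0^zc exp(-W(z)) dz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

__all__ = [
    "PairSpec",
    "WallSpec",
    "BondSpec",
    "WCA_CUTOFF",
    "WALL_REPULSIVE_CUTOFF",
    "pair_energy_force",
    "fene_energy_force",
    "wall_energy_force",
    "effective_wall_strength",
]

#: Cutoff of the purely repulsive WCA potential (LJ minimum), 2^(1/6).
WCA_CUTOFF: float = 2.0 ** (1.0 / 6.0)

#: Cutoff that truncates the 9-3 wall at its minimum, (2/5)^(1/6) ~ 0.858.
WALL_REPULSIVE_CUTOFF: float = (2.0 / 5.0) ** (1.0 / 6.0)

#: Separations below this raise instead of silently overflowing.
_MIN_SEPARATION = 1e-6


class GeometryError(ValueError):
    """Raised for non-physical separations (r <= 0 or below overflow guard)."""


class BondOverstretchError(RuntimeError):
    """Raised when a FENE bond reaches or exceeds its maximum extension."""


@dataclass(frozen=True)
class PairSpec:
    """Truncated-and-shifted LJ pair interaction (eps-LJ-rc notation).

    Parameters
    ----------
    epsilon : energy depth (kBT).
    rc : cutoff radius (bead diameters); the energy vanishes for r >= rc.
    """

    epsilon: float = 1.0
    rc: float = WCA_CUTOFF

    def __post_init__(self) -> None:
        if self.rc <= 0:
            raise ValueError(f"pair cutoff must be positive, got rc={self.rc}")
        if self.epsilon < 0:
            raise ValueError(f"pair epsilon must be >= 0, got {self.epsilon}")

    @property
    def shift(self) -> float:
        """Unshifted LJ energy at the cutoff; subtracted so V(rc) = 0."""
        return 4.0 * self.epsilon * (self.rc ** -12 - self.rc ** -6)


@dataclass(frozen=True)
class WallSpec:
    """9-3 wall interaction for one implicit planar surface.

    ``side`` selects which plane the distance is measured from: ``"lower"``
    uses z itself (wall at z=0), ``"upper"`` uses H - z (wall at z=H).
    ``style`` allows an LJ-form z-wall (12-6 in the wall distance) as the
    alternative reading of the polar-bead wall row of the interaction matrix.
    """

    epsilon: float = 1.0
    zc: float = WALL_REPULSIVE_CUTOFF
    side: str = "lower"
    style: str = "93"  # "93" | "lj"

    def __post_init__(self) -> None:
        if self.zc <= 0:
            raise ValueError(f"wall cutoff must be positive, got zc={self.zc}")
        if self.epsilon < 0:
            raise ValueError(f"wall epsilon must be >= 0, got {self.epsilon}")
        if self.side not in ("lower", "upper"):
            raise ValueError(f"wall side must be 'lower' or 'upper', got {self.side!r}")
        if self.style not in ("93", "lj"):
            raise ValueError(f"wall style must be '93' or 'lj', got {self.style!r}")

    @property
    def repulsive(self) -> bool:
        """True when truncated at the 9-3 minimum (no attractive well)."""
        return abs(self.zc - WALL_REPULSIVE_CUTOFF) < 1e-12


@dataclass(frozen=True)
class BondSpec:
    """FENE bond: V(r) = -(k R^2 / 2) ln[1 - (r/R)^2], divergent at r = R.

    Defaults are the standard Kremer-Grest values k=30, R=1.5.  Bonded
    neighbours additionally interact through the WCA pair term (and through
    nothing else), the usual bead-spring convention.
    """

    kfene: float = 30.0
    rfene: float = 1.5

    def __post_init__(self) -> None:
        if self.kfene <= 0 or self.rfene <= 0:
            raise ValueError("FENE parameters must be positive")


def _check_separation(r: float, what: str) -> None:
    if r <= 0:
        raise GeometryError(f"{what} must be positive, got {r}")
    if r < _MIN_SEPARATION:
        raise GeometryError(
            f"{what}={r} below overflow guard {_MIN_SEPARATION}; "
            "energies would overflow double precision"
        )


def pair_energy_force(r: float, spec: PairSpec) -> tuple[float, float]:
    """Energy and scalar force of the truncated-shifted LJ pair potential.

    Returns ``(V, f)`` with ``f = -dV/dr``; both are exactly zero for
    ``r >= rc``.
    """
    _check_separation(r, "pair separation r")
    if r >= spec.rc:
        return 0.0, 0.0
    inv6 = r ** -6
    energy = 4.0 * spec.epsilon * (inv6 * inv6 - inv6) - spec.shift
    force = 24.0 * spec.epsilon * (2.0 * inv6 * inv6 - inv6) / r
    return energy, force


def fene_energy_force(r: float, spec: BondSpec) -> tuple[float, float]:
    """Energy and scalar force (-dV/dr) of a FENE bond of length ``r``.

    Raises :class:`BondOverstretchError` at ``r >= rfene`` — in a running
    simulation that is an integrator blow-up, not a recoverable state.
    """
    if r < 0:
        raise GeometryError(f"bond length must be >= 0, got {r}")
    if r >= spec.rfene:
        raise BondOverstretchError(
            f"FENE bond overstretched: r={r} >= RFENE={spec.rfene}"
        )
    x2 = (r / spec.rfene) ** 2
    energy = -0.5 * spec.kfene * spec.rfene ** 2 * math.log1p(-x2)
    force = -spec.kfene * r / (1.0 - x2)
    return energy, force


def _wall_93(z: float, epsilon: float, zc: float) -> tuple[float, float]:
    shift = epsilon * ((2.0 / 15.0) * zc ** -9 - zc ** -3)
    inv3 = z ** -3
    energy = epsilon * ((2.0 / 15.0) * inv3 ** 3 - inv3) - shift
    # -dV/dz = eps * ( (6/5) z^-10 - 3 z^-4 )
    force = epsilon * ((6.0 / 5.0) * z ** -10 - 3.0 * z ** -4)
    return energy, force


def _wall_lj(z: float, epsilon: float, zc: float) -> tuple[float, float]:
    shift = 4.0 * epsilon * (zc ** -12 - zc ** -6)
    inv6 = z ** -6
    energy = 4.0 * epsilon * (inv6 * inv6 - inv6) - shift
    force = 24.0 * epsilon * (2.0 * inv6 * inv6 - inv6) / z
    return energy, force


def wall_energy_force(z: float, spec: WallSpec) -> tuple[float, float]:
    """Energy and scalar z-force of the implicit wall on a bead.

    ``z`` is the distance from the wall *plane* (already ``H - z`` for the
    upper wall); the returned force is along the outward wall normal, so the
    caller negates it for the upper wall.
    """
    _check_separation(z, "wall distance z")
    if z >= spec.zc:
        return 0.0, 0.0
    if spec.style == "93":
        return _wall_93(z, spec.epsilon, spec.zc)
    return _wall_lj(z, spec.epsilon, spec.zc)


def wall_minimum(spec: WallSpec) -> tuple[float, float]:
    """Location and depth of the 9-3 well: z* = (2/5)^(1/6), W(z*)."""
    zstar = WALL_REPULSIVE_CUTOFF
    if zstar >= spec.zc:
        return spec.zc, 0.0
    return zstar, wall_energy_force(zstar, spec)[0]


def effective_wall_strength(epsilon: float, zc: float, style: str = "93") -> float:
    """Effective interaction strength I = int_0^zc exp(-W(z)) dz.

    The integrand vanishes (to double precision) where the repulsive core
    pushes W above ~700, so the quadrature runs on (delta, zc] with delta
    at that underflow point.  For epsilon -> 0, I -> zc exactly.
    """
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    if zc <= 0:
        raise ValueError(f"zc must be positive, got {zc}")
    spec = WallSpec(epsilon=epsilon, zc=zc, style=style)
    if epsilon == 0.0:
        return zc

    def integrand(z: float) -> float:
        e, _ = wall_energy_force(max(z, _MIN_SEPARATION), spec)
        return math.exp(-e) if e < 700.0 else 0.0

    # find the underflow point delta: W monotonically decreasing near the core
    lo, hi = _MIN_SEPARATION, min(zc, WALL_REPULSIVE_CUTOFF)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if wall_energy_force(mid, spec)[0] > 700.0:
            lo = mid
        else:
            hi = mid
    delta = lo
    val, _err = quad(integrand, delta, zc, limit=500, epsabs=1e-10, epsrel=1e-9)
    return float(val)


def dimer_equilibrium_length(
    bond: BondSpec = BondSpec(), pair: PairSpec = PairSpec()
) -> float:
    """Bond length minimising FENE + WCA for an isolated dimer (~0.96)."""
    from scipy.optimize import minimize_scalar

    def v(r: float) -> float:
        return fene_energy_force(r, bond)[0] + pair_energy_force(r, pair)[0]

    res = minimize_scalar(
        v, bounds=(0.3, bond.rfene - 1e-9), method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)
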