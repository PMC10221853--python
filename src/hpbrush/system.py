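"""Simulation state containers: box geometry, bead taxonomy, interaction table.

Bead types
----------
==========  ====  =============================================================
name        code  meaning
==========  ====  =============================================================
R            0    repulsive coating bead (mobile backbone)
R_tethered   1    coating anchor bead, immobile at z=0, feels no wall
w            2    water bead (WCA monomer)
H            3    hydrophobic protein bead (mutually attractive)
P            4    polar protein bead
A            5    attractive backbone bead (doped coating site)
A_ligand     6    immobile ligand bead fixed at altitude z_lig
==========  ====  =============================================================

The interaction matrix follows the model's conventions: every bead pair is
WCA except H-H (deep short-ranged attraction driving hydrophobic collapse)
and P-A / P-A_ligand (the doping attraction); the upper wall repels
everything, the lower wall repels coating/water/A beads at the 9-3 minimum
cutoff and attracts protein beads with a configurable eps-W-zc well;
tethered anchors feel no wall at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .potentials import (
    BondSpec,
    PairSpec,
    WallSpec,
    WCA_CUTOFF,
    WALL_REPULSIVE_CUTOFF,
)

__all__ = [
    "BoxGeometry",
    "InteractionTable",
    "ParticleSystem",
    "BEAD_TYPES",
    "TYPE_R",
    "TYPE_R_TETHERED",
    "TYPE_W",
    "TYPE_H",
    "TYPE_P",
    "TYPE_A",
    "TYPE_A_LIGAND",
    "default_interaction_table",
]

TYPE_R = 0
TYPE_R_TETHERED = 1
TYPE_W = 2
TYPE_H = 3
TYPE_P = 4
TYPE_A = 5
TYPE_A_LIGAND = 6

BEAD_TYPES: tuple[str, ...] = ("R", "R_tethered", "w", "H", "P", "A", "A_ligand")
N_TYPES = len(BEAD_TYPES)

_PROTEIN_TYPES = (TYPE_H, TYPE_P)


@dataclass(frozen=True)
class BoxGeometry:
    """Rectangular box, periodic in x and y, implicit walls at z=0 and z=H.

    ``periodic_z=True`` turns off both walls and wraps z as well (used for
    bulk fixtures such as the single-protein water box when walls are not
    wanted).  Defaults are the full production geometry.
    """

    lx: float = 54.29
    ly: float = 64.44
    h: float = 20.0
    periodic_z: bool = False

    def __post_init__(self) -> None:
        if min(self.lx, self.ly, self.h) <= 0:
            raise ValueError("all box lengths must be positive")

    @property
    def area(self) -> float:
        """Tethering-surface area A = Lx * Ly."""
        return self.lx * self.ly

    @property
    def volume(self) -> float:
        return self.area * self.h


@dataclass
class InteractionTable:
    """Symmetric (type, type) -> PairSpec map plus per-type wall specs.

    ``lower_wall[t]`` / ``upper_wall[t]`` may be ``None`` (no wall force for
    that type; used for tethered anchors).
    """

    pair: dict[tuple[int, int], PairSpec] = field(default_factory=dict)
    lower_wall: dict[int, WallSpec | None] = field(default_factory=dict)
    upper_wall: dict[int, WallSpec | None] = field(default_factory=dict)
    bond: BondSpec = field(default_factory=BondSpec)

    def pair_spec(self, ti: int, tj: int) -> PairSpec:
        key = (min(ti, tj), max(ti, tj))
        return self.pair[key]

    def set_pair(self, ti: int, tj: int, spec: PairSpec) -> None:
        self.pair[(min(ti, tj), max(ti, tj))] = spec

    def max_pair_cutoff(self) -> float:
        return max(s.rc for s in self.pair.values())

    def as_arrays(self) -> dict[str, np.ndarray]:
        """Dense per-type tables consumed by the compiled kernels."""
        eps = np.zeros((N_TYPES, N_TYPES))
        rc = np.zeros((N_TYPES, N_TYPES))
        for i in range(N_TYPES):
            for j in range(i, N_TYPES):
                s = self.pair_spec(i, j)
                eps[i, j] = eps[j, i] = s.epsilon
                rc[i, j] = rc[j, i] = s.rc
        walls = {}
        for name, table in (("lo", self.lower_wall), ("hi", self.upper_wall)):
            weps = np.zeros(N_TYPES)
            wzc = np.zeros(N_TYPES)  # zc <= 0 encodes "no wall"
            wstyle = np.zeros(N_TYPES, dtype=np.int64)
            for t in range(N_TYPES):
                spec = table.get(t)
                if spec is None:
                    wzc[t] = -1.0
                else:
                    weps[t] = spec.epsilon
                    wzc[t] = spec.zc
                    wstyle[t] = 0 if spec.style == "93" else 1
            walls[f"wall_{name}_eps"] = weps
            walls[f"wall_{name}_zc"] = wzc
            walls[f"wall_{name}_style"] = wstyle
        return {"pair_eps": eps, "pair_rc": rc, **walls}


def default_interaction_table(
    protein_wall: WallSpec | None = None,
    ap_pair: PairSpec | None = None,
    hh_epsilon: float = 120.0,
    hh_rc: float = 1.19,
    p_wall_style: str = "93",
    bond: BondSpec | None = None,
) -> InteractionTable:
    """Interaction matrix of the model with its configurable entries.

    Parameters
    ----------
    protein_wall : attractive lower-wall spec for protein beads (H and P);
        ``None`` gives the purely repulsive wall (the undoped, unattractive
        reference).
    ap_pair : attraction of A/A_ligand beads toward polar P beads,
        default 1LJ1.5.
    hh_epsilon, hh_rc : hydrophobic attraction, default 120LJ1.19 as printed
        (note: with truncation+shift at 1.19 the effective well depth is
        ~10.5 kBT).
    p_wall_style : "93" (default: protein beads feel the 9-3 wall as a whole)
        or "lj" for the LJ-form z-wall alternative for P beads.
    """
    wca = PairSpec()
    table = InteractionTable(bond=bond or BondSpec())
    for i in range(N_TYPES):
        for j in range(i, N_TYPES):
            table.set_pair(i, j, wca)
    table.set_pair(TYPE_H, TYPE_H, PairSpec(epsilon=hh_epsilon, rc=hh_rc))
    ap = ap_pair or PairSpec(epsilon=1.0, rc=1.5)
    table.set_pair(TYPE_P, TYPE_A, ap)
    table.set_pair(TYPE_P, TYPE_A_LIGAND, ap)

    repulsive_lo = WallSpec(epsilon=1.0, zc=WALL_REPULSIVE_CUTOFF, side="lower")
    repulsive_hi = WallSpec(epsilon=1.0, zc=WALL_REPULSIVE_CUTOFF, side="upper")
    for t in range(N_TYPES):
        table.lower_wall[t] = repulsive_lo
        table.upper_wall[t] = repulsive_hi
    # tethered anchors are exempt from both walls
    table.lower_wall[TYPE_R_TETHERED] = None
    table.upper_wall[TYPE_R_TETHERED] = None
    if protein_wall is not None:
        for t in _PROTEIN_TYPES:
            style = p_wall_style if t == TYPE_P else "93"
            table.lower_wall[t] = WallSpec(
                epsilon=protein_wall.epsilon, zc=protein_wall.zc,
                side="lower", style=style,
            )
    return table


@dataclass
class ParticleSystem:
    """Complete simulation state.

    Positions are stored *unwrapped*: the dynamics kernels apply minimum-image
    wrapping internally, so chain metrics never need re-unwrapping.  Bonds are
    0-based index pairs; ``molecule`` groups beads into chains/proteins
    (water beads get molecule id -1).
    """

    box: BoxGeometry
    positions: np.ndarray  # (n, 3) float64
    velocities: np.ndarray  # (n, 3) float64
    types: np.ndarray  # (n,) int64
    molecule: np.ndarray  # (n,) int64
    mobile: np.ndarray  # (n,) bool
    bonds: np.ndarray  # (nb, 2) int64
    interactions: InteractionTable = field(default_factory=default_interaction_table)

    @classmethod
    def empty(cls, box: BoxGeometry,
              interactions: InteractionTable | None = None) -> "ParticleSystem":
        return cls(
            box=box,
            positions=np.zeros((0, 3)),
            velocities=np.zeros((0, 3)),
            types=np.zeros(0, dtype=np.int64),
            molecule=np.zeros(0, dtype=np.int64),
            mobile=np.zeros(0, dtype=bool),
            bonds=np.zeros((0, 2), dtype=np.int64),
            interactions=interactions or default_interaction_table(),
        )

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def add_beads(
        self,
        positions: np.ndarray,
        types: np.ndarray | int,
        molecule: np.ndarray | int = -1,
        mobile: np.ndarray | bool = True,
        velocities: np.ndarray | None = None,
    ) -> np.ndarray:
        """Append beads; returns the new bead indices."""
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        n = positions.shape[0]
        start = self.n_beads
        self.positions = np.vstack([self.positions, positions])
        self.velocities = np.vstack(
            [self.velocities,
             np.zeros((n, 3)) if velocities is None else np.asarray(velocities)]
        )
        self.types = np.concatenate(
            [self.types, np.broadcast_to(np.asarray(types, dtype=np.int64), (n,))]
        )
        self.molecule = np.concatenate(
            [self.molecule, np.broadcast_to(np.asarray(molecule, dtype=np.int64), (n,))]
        )
        self.mobile = np.concatenate(
            [self.mobile, np.broadcast_to(np.asarray(mobile, dtype=bool), (n,))]
        )
        return np.arange(start, start + n)

    def add_bonds(self, pairs: np.ndarray) -> None:
        pairs = np.atleast_2d(np.asarray(pairs, dtype=np.int64))
        self.bonds = np.vstack([self.bonds, pairs])

    def wrapped_positions(self) -> np.ndarray:
        """Positions wrapped into the primary box (for output only)."""
        pos = self.positions.copy()
        pos[:, 0] %= self.box.lx
        pos[:, 1] %= self.box.ly
        if self.box.periodic_z:
            pos[:, 2] %= self.box.h
        return pos

    def molecule_indices(self, mol_id: int) -> np.ndarray:
        return np.nonzero(self.molecule == mol_id)[0]

    def chains(self, types: tuple[int, ...] | None = None) -> list[np.ndarray]:
        """Bead-index lists of all molecules, optionally filtered by the
        bead types they contain (e.g. protein molecules via (H, P))."""
        out = []
        for mol in np.unique(self.molecule[self.molecule >= 0]):
            idx = self.molecule_indices(mol)
            if types is None or np.isin(self.types[idx], types).any():
                out.append(idx)
        return out

    def min_pair_distance(self, exclude_bonded: bool = False) -> float:
        """Smallest wrapped pairwise distance (scipy cKDTree; xy periodic).

        With ``exclude_bonded=True``, bonded neighbour pairs are ignored —
        the construction invariant is min distance >= 1 for *non-bonded*
        pairs (bonds sit at the FENE+WCA equilibrium ~0.96).
        """
        from scipy.spatial import cKDTree

        if self.n_beads < 2:
            return np.inf
        pos = self.wrapped_positions()
        # emulate mixed periodicity with an oversized z period
        zbox = self.box.h if self.box.periodic_z else 1e6 + self.positions[:, 2].max()
        tree = cKDTree(pos, boxsize=[self.box.lx, self.box.ly, zbox])
        if not exclude_bonded:
            d, _ = tree.query(pos, k=2)
            return float(d[:, 1].min())
        bonded = {(min(i, j), max(i, j)) for i, j in self.bonds}
        k = min(self.n_beads, 6)
        d, nbr = tree.query(pos, k=k)
        best = np.inf
        for i in range(self.n_beads):
            for m in range(1, k):
                j = int(nbr[i, m])
                if (min(i, j), max(i, j)) not in bonded:
                    best = min(best, d[i, m])
                    break
        return float(best)

    def maxwell_velocities(self, temperature: float, rng: np.random.Generator) -> None:
        """Draw Maxwell-Boltzmann velocities for mobile beads (unit mass)
        and zero the net momentum of the mobile set."""
        n = self.n_beads
        v = rng.normal(0.0, np.sqrt(temperature), size=(n, 3))
        v[~self.mobile] = 0.0
        nm = int(self.mobile.sum())
        if nm > 0:
            v[self.mobile] -= v[self.mobile].mean(axis=0)
        self.velocities = v

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            box=self.box,
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            types=self.types.copy(),
            molecule=self.molecule.copy(),
            mobile=self.mobile.copy(),
            bonds=self.bonds.copy(),
            interactions=self.interactions,
        )
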