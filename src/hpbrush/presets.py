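"""Deterministic miniature systems for tests and examples.

Every preset builds in milliseconds-to-seconds and runs 10^4 MD steps in
well under a minute on one CPU.  Fixture proteins use a synthetic compact
(serpentine) start conformation rather than an MD-collapsed library — these
systems exercise the machinery, they do not reproduce production physics.
"""

from __future__ import annotations

import numpy as np

from .builder import (
    BOND_LENGTH,
    build_coating,
    fill_water,
    generate_hp_sequence,
    place_proteins,
    single_protein_box,
)
from .potentials import PairSpec, WallSpec
from .system import (
    BoxGeometry,
    InteractionTable,
    ParticleSystem,
    TYPE_W,
    default_interaction_table,
)

__all__ = ["make_fixture", "PRESETS", "compact_conformation"]


def compact_conformation(n_beads: int, spacing: float = 1.05) -> np.ndarray:
    """Serpentine walk on a cubic grid: a compact, overlap-free chain start.

    Consecutive beads are ``spacing`` apart (a valid FENE bond length) and
    non-consecutive beads at least ``spacing`` — a stand-in for a collapsed
    globule usable without running MD (synthetic; fixture plumbing only).
    """
    side = int(np.ceil(n_beads ** (1.0 / 3.0)))
    coords = []
    x = y = z = 0
    xdir = ydir = 1
    while len(coords) < n_beads:
        coords.append((x, y, z))
        if 0 <= x + xdir < side:
            x += xdir
        elif 0 <= y + ydir < side:
            y += ydir
            xdir = -xdir
        else:
            z += 1
            xdir = -xdir
            ydir = -ydir
    out = np.array(coords, float) * spacing
    return out - out.mean(axis=0)


def _dimer(seed: int, stretch: float = 1.2) -> ParticleSystem:
    """Two FENE+WCA-bonded beads in a periodic box, started stretched."""
    box = BoxGeometry(lx=8.0, ly=8.0, h=8.0, periodic_z=True)
    system = ParticleSystem.empty(box)
    pos = np.array([[4.0 - stretch / 2, 4.0, 4.0], [4.0 + stretch / 2, 4.0, 4.0]])
    idx = system.add_beads(pos, np.array([0, 0]), molecule=0)
    system.add_bonds([[idx[0], idx[1]]])
    system.maxwell_velocities(1.0, np.random.default_rng(seed))
    return system


def _ideal_gas_slab(seed: int, n_beads: int = 240) -> ParticleSystem:
    """Non-interacting beads between repulsive walls (flat-profile oracle)."""
    box = BoxGeometry(lx=8.0, ly=8.0, h=10.0)
    table = default_interaction_table()
    for key in list(table.pair):
        table.pair[key] = PairSpec(epsilon=0.0, rc=table.pair[key].rc)
    system = ParticleSystem.empty(box, table)
    rng = np.random.default_rng(seed)
    pos = np.column_stack(
        [
            rng.uniform(0, box.lx, n_beads),
            rng.uniform(0, box.ly, n_beads),
            rng.uniform(1.0, box.h - 1.0, n_beads),
        ]
    )
    system.add_beads(pos, TYPE_W, molecule=-1)
    system.maxwell_velocities(1.0, rng)
    return system


def _mini_mushroom(
    seed: int,
    wall: WallSpec | None = None,
    interactions: InteractionTable | None = None,
    density: float = 0.65,
) -> ParticleSystem:
    """3x3 chains of N=10, 2 proteins of Np=12, 12^3 box, water at n=0.65.

    Chains start serpentine-folded below z=4 so the proteins fit above them;
    proteins use the synthetic compact conformation.
    """
    box = BoxGeometry(lx=12.0, ly=12.0, h=12.0)
    rng = np.random.default_rng(seed)
    table = interactions or default_interaction_table(protein_wall=wall)
    system = build_coating(box, g=9, n=10, interactions=table, max_height=4.0)
    coil = compact_conformation(12)
    library = [
        {"positions": coil, "sequence": generate_hp_sequence(12, 0.25, rng), "rg": 0.0}
        for _ in range(2)
    ]
    hmax = float(
        np.mean([system.positions[idx, 2].max() for idx in system.chains()])
    )
    place_proteins(system, library, hmax=hmax, clearance=1.0, seed=seed)
    fill_water(system, density=density, rng=rng)
    system.maxwell_velocities(1.0, rng)
    return system


PRESETS = ("dimer", "ideal-gas-slab", "mini-mushroom", "single-protein")


def make_fixture(name: str, seed: int = 0, **overrides) -> ParticleSystem:
    """Deterministic miniature :class:`ParticleSystem` by preset name.

    Presets: ``dimer`` (bonded pair for FENE/WCA checks), ``ideal-gas-slab``
    (non-interacting beads between walls), ``mini-mushroom`` (tiny coating +
    2 proteins + water), ``single-protein`` (one S-type HP chain in a water
    slab, the collapse fixture).  Keyword overrides are forwarded to the
    preset builder.
    """
    builders = {
        "dimer": _dimer,
        "ideal-gas-slab": _ideal_gas_slab,
        "mini-mushroom": _mini_mushroom,
        "single-protein": single_protein_box,
    }
    if name not in builders:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    return builders[name](seed=seed, **overrides)
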