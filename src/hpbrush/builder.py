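"""System construction: tethered coatings, HP proteins, doping, water fill.

The construction pipeline for a production system is

1. :func:`build_coating` — G chains of N beads on a near-square anchor
   lattice, rodlike (or hairpin-folded) start, anchors immobile at z=0;
2. :func:`apply_doping` — retype one bead per chain (middle/random/terminal)
   or insert immobile ligand beads at fixed altitude;
3. :func:`sample_protein_library` — collapse a single HP chain in water and
   harvest snapshots;
4. :func:`place_proteins` — distribute the library copies on a grid above
   the coating;
5. :func:`fill_water` — insert water beads up to the target density with
   every pairwise distance >= 1.

Everything is deterministic given (parameters, seed).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.spatial import cKDTree

from .potentials import dimer_equilibrium_length
from .system import (
    BoxGeometry,
    InteractionTable,
    ParticleSystem,
    TYPE_A,
    TYPE_A_LIGAND,
    TYPE_H,
    TYPE_P,
    TYPE_R,
    TYPE_R_TETHERED,
    TYPE_W,
    default_interaction_table,
)

__all__ = [
    "build_coating",
    "generate_hp_sequence",
    "build_protein_rod",
    "sample_protein_library",
    "apply_doping",
    "place_proteins",
    "fill_water",
    "anchor_lattice",
    "classify_regime",
    "ConstructionError",
]

#: FENE(30,1.5)+WCA equilibrium bond length, used for all initial chains.
BOND_LENGTH = 0.960897


class ConstructionError(RuntimeError):
    """A system could not be built under the stated geometric constraints."""


def anchor_lattice(box: BoxGeometry, g: int) -> np.ndarray:
    """G near-uniform anchor points on the x-y plane.

    Uses the (nx, ny) grid with nx*ny >= G whose cell aspect ratio is closest
    to square at spacing ~ sqrt(A/G), keeping the first G sites in row-major
    order.  Jitter-free.
    """
    if g < 1:
        raise ConstructionError("need at least one chain")
    best = None
    for nx in range(1, g + 1):
        ny = math.ceil(g / nx)
        # cost: deviation of the cell from square
        cost = abs(box.lx / nx - box.ly / ny)
        if best is None or cost < best[0]:
            best = (cost, nx, ny)
    _, nx, ny = best
    xs = (np.arange(nx) + 0.5) * box.lx / nx
    ys = (np.arange(ny) + 0.5) * box.ly / ny
    pts = np.array([(x, y) for y in ys for x in xs])
    return pts[:g]


def _vertical_chain(
    n_beads: int, h: float, fold: bool, max_height: float | None = None
) -> np.ndarray:
    """z-offsets (and x-offsets) of a tethered chain start conformation.

    Straight rod normal to the surface when it fits below ``max_height``
    (default: just under the wall at z=H); otherwise a serpentine folded
    within that height, with unit lateral offsets so fold arms stay a bead
    diameter apart.  Returns (n_beads, 3) offsets relative to the anchor
    (bead 0 at the origin).
    """
    b = BOND_LENGTH
    top = (h - 1.5) if max_height is None else min(max_height, h - 1.5)
    rod_height = (n_beads - 1) * b
    out = np.zeros((n_beads, 3))
    if rod_height <= top:
        out[:, 2] = np.arange(n_beads) * b
        return out
    if not fold:
        raise ConstructionError(
            f"rodlike start of {n_beads} beads (height {rod_height:.2f}) "
            f"does not fit below the wall at H={h}; enable folding"
        )
    # serpentine: vertical arms joined by unit sideways turns
    z, direction, arm = 0.0, 1.0, 0
    for i in range(n_beads):
        out[i] = (1.05 * arm, 0.0, z)
        nz = z + direction * b
        if nz > top or nz < 0.6:
            direction *= -1.0
            arm += 1
        else:
            z = nz
    return out


def build_coating(
    box: BoxGeometry,
    g: int,
    n: int = 50,
    interactions: InteractionTable | None = None,
    fold: bool = True,
    max_height: float | None = None,
) -> ParticleSystem:
    """Tethered coating of ``g`` chains of ``n`` beads each.

    Anchors (type R_tethered, immobile, exactly at z=0) sit on the
    :func:`anchor_lattice`; chains start rodlike normal to the surface with
    bond length ~0.96, serpentine-folded when the rod would not fit under
    the upper wall (or under ``max_height``).  The grafting density is
    sigma = g/A.
    """
    system = ParticleSystem.empty(box, interactions or default_interaction_table())
    anchors = anchor_lattice(box, g)
    offsets = _vertical_chain(n, box.h, fold, max_height)
    for c in range(g):
        pos = offsets + np.array([anchors[c, 0], anchors[c, 1], 0.0])
        types = np.full(n, TYPE_R, dtype=np.int64)
        types[0] = TYPE_R_TETHERED
        mobile = np.ones(n, dtype=bool)
        mobile[0] = False
        idx = system.add_beads(pos, types, molecule=c, mobile=mobile)
        system.add_bonds(np.column_stack([idx[:-1], idx[1:]]))
    return system


def grafting_density(system: ParticleSystem) -> float:
    """sigma = G/A from the anchor count."""
    g = int((system.types == TYPE_R_TETHERED).sum())
    return g / system.box.area


def classify_regime(rg2: float, sigma: float) -> str:
    """Coating regime from measured Rg^2 vs the area per chain Sigma=1/sigma.

    brush: Rg^2 > Sigma; mushroom: Rg^2 < Sigma/2; intermediate between.
    The brush boundary is the model's definition; the mushroom/intermediate
    split at Sigma/2 is this package's reading of "Rg^2 << Sigma".
    """
    sig_area = 1.0 / sigma
    if rg2 > sig_area:
        return "brush"
    if rg2 < 0.5 * sig_area:
        return "mushroom"
    return "intermediate"


def generate_hp_sequence(
    n_beads: int, hp: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Random H/P type sequence with exactly round(hp * n_beads) H beads.

    Deterministic given the seed; different seeds give the same composition
    in a different order.
    """
    if not 0.0 < hp < 1.0:
        raise ValueError(f"hydrophobicity ratio must be in (0, 1), got {hp}")
    n_h = round(hp * n_beads)
    if n_h in (0, n_beads):
        warnings.warn(
            f"degenerate HP composition: {n_h} hydrophobic of {n_beads} beads",
            stacklevel=2,
        )
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    seq = np.full(n_beads, TYPE_P, dtype=np.int64)
    seq[rng.choice(n_beads, size=n_h, replace=False)] = TYPE_H
    return seq


def build_protein_rod(
    sequence: np.ndarray, start: np.ndarray, axis: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Rodlike start conformation along ``axis`` from ``start``; returns
    (positions, bond index offsets 0..Np-2)."""
    axis = np.array([1.0, 0.0, 0.0]) if axis is None else np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    n = len(sequence)
    pos = np.asarray(start, float) + np.outer(np.arange(n) * BOND_LENGTH, axis)
    return pos, np.column_stack([np.arange(n - 1), np.arange(1, n)])


def single_protein_box(
    np_beads: int = 40,
    hp: float = 0.25,
    density: float = 0.65,
    seed: int = 0,
    margin: float = 2.0,
    section: float = 9.0,
    interactions: InteractionTable | None = None,
) -> ParticleSystem:
    """One HP chain, rodlike start, in an xy-periodic water slab at ``density``.

    The box is elongated along x so the rod fits (Lx = rod + margin), with a
    ``section`` x ``section`` cross-section and repulsive walls top and
    bottom.  Used for the protein-library equilibration runs.
    """
    rod = (np_beads - 1) * BOND_LENGTH
    box = BoxGeometry(lx=rod + margin, ly=section, h=section)
    rng = np.random.default_rng(seed)
    system = ParticleSystem.empty(box, interactions or default_interaction_table())
    seq = generate_hp_sequence(np_beads, hp, rng)
    pos, bonds = build_protein_rod(
        seq, start=np.array([margin / 2, section / 2, section / 2])
    )
    idx = system.add_beads(pos, seq, molecule=0, mobile=True)
    system.add_bonds(idx[bonds])
    n_total = round(density * box.volume)
    fill_water(system, n_total=n_total, rng=rng)
    system.maxwell_velocities(1.0, rng)
    return system


def sample_protein_library(
    np_beads: int = 40,
    hp: float = 0.25,
    gp: int = 24,
    seed: int = 0,
    t_run: float = 5000.0,
    t_collect_from: float | None = None,
    md_config=None,
    density: float = 0.65,
) -> list[dict]:
    """Equilibrate single HP chains in water and harvest ``gp`` conformations.

    Each copy gets a different random HP sequence (same composition).  To keep
    the copies independent, each is collapsed in its own run seeded from
    ``seed``; snapshots are taken at evenly spaced times in the trailing part
    of each run (after ``t_collect_from``, default 60% of ``t_run``).

    Returns a list of dicts with keys ``positions`` (centred coordinates),
    ``sequence`` and ``rg``.  A copy whose final Rg is still above half the
    rodlike value triggers a non-collapse warning but is returned anyway.
    """
    from .analysis import chain_metrics
    from .dynamics import IntegratorConfig, run_md

    if md_config is None:
        md_config = IntegratorConfig()
    t_collect_from = 0.6 * t_run if t_collect_from is None else t_collect_from
    rod_rg = math.sqrt((np_beads ** 2 - 1) / 12.0) * BOND_LENGTH
    library = []
    for copy in range(gp):
        sub_seed = (seed * 7919 + copy) % (2 ** 31)
        system = single_protein_box(np_beads, hp, density, seed=sub_seed)
        protein = system.molecule_indices(0)
        steps = int(round(t_run / md_config.dt))
        stride = max(1, int(round((t_run - t_collect_from) / md_config.dt)) // 8)
        cfg = IntegratorConfig(
            dt=md_config.dt,
            temperature=md_config.temperature,
            thermostat=md_config.thermostat,
            damping=md_config.damping,
            steps=steps,
            seed=sub_seed,
            traj_stride=stride,
            log_stride=max(1, steps // 50),
        )
        traj = run_md(system, cfg, selection=protein)
        keep = traj.times >= t_collect_from
        frames = traj.positions[keep]
        snap = frames[-1] if len(frames) else system.positions[protein]
        metrics = chain_metrics(snap)
        if metrics.rg > 0.5 * rod_rg:
            warnings.warn(
                f"protein copy {copy} has Rg={metrics.rg:.2f}, above half the "
                f"rodlike value {rod_rg:.2f}: not collapsed", stacklevel=2,
            )
        library.append(
            {
                "positions": snap - snap.mean(axis=0),
                "sequence": system.types[protein].copy(),
                "rg": metrics.rg,
            }
        )
    return library


def equilibrate_single_protein(
    np_beads: int = 40,
    hp: float = 0.25,
    density: float = 0.65,
    seed: int = 0,
    t_collapse: float = 1000.0,
    rg_collapsed: float = 2.5,
    max_anneal_rounds: int = 4,
    t_hot: float = 150.0,
    temp_hot: float = 2.0,
    t_cool: float = 400.0,
    t_sample: float = 750.0,
    md_config=None,
) -> dict:
    """Collapse one HP chain from a rodlike start to its equilibrium globule.

    Plain NVT at T=1 traps a substantial fraction of random HP sequences in
    metastable multi-cluster ("pearl necklace") states near Rg ~ 3.5: each
    missing H-H contact costs ~10 kBT, so those states carry negligible
    equilibrium weight yet survive ~10^6-step runs.  The protocol is
    therefore adaptive: a plain NVT collapse segment, then — only while the
    trailing Rg stays above ``rg_collapsed`` (the gap between globule
    ~1.9-2.1 and necklace >~2.7) — heat/quench rounds (``t_hot`` at
    ``temp_hot`` lets cluster merging cross its barrier, ``t_cool`` re-
    equilibrates at T=1), and finally ``t_sample`` of T=1 production.
    Replicas that collapse on their own are never heated.

    The stationary ``rg`` is sqrt of the trailing-30% mean of Rg^2 over the
    whole trace (the window sits in the T=1 production/cool segments);
    ``equilibrated`` flags both a sub-threshold final Rg and 5% agreement
    between the halves of the averaging window.
    """
    from .analysis import chain_metrics, stationary_average
    from .dynamics import IntegratorConfig, run_md

    if md_config is None:
        md_config = IntegratorConfig()
    system = single_protein_box(np_beads, hp, density, seed=seed)
    protein = system.molecule_indices(0)
    times: list[np.ndarray] = []
    rg2: list[np.ndarray] = []
    state = {"vxi": 0.0, "t0": 0.0}

    def _segment(temperature: float, duration: float) -> np.ndarray:
        steps = int(round(duration / md_config.dt))
        cfg = IntegratorConfig(
            dt=md_config.dt,
            temperature=temperature,
            thermostat=md_config.thermostat,
            damping=md_config.damping,
            steps=steps,
            seed=seed,
            log_stride=max(1, steps // 4),
            traj_stride=1000,
            skin=md_config.skin,
        )
        traj = run_md(system, cfg, selection=protein, t0=state["t0"],
                      thermostat_state=state["vxi"])
        state["vxi"] = getattr(traj, "thermostat_state", 0.0)
        state["t0"] = float(traj.times[-1])
        times.append(traj.times)
        seg = np.array([chain_metrics(f).rg2 for f in traj.positions])
        rg2.append(seg)
        return seg

    def _trailing_rg(seg: np.ndarray) -> float:
        return float(np.sqrt(seg[-max(1, len(seg) // 2):].mean()))

    seg = _segment(md_config.temperature, t_collapse)
    rounds = 0
    while _trailing_rg(seg) > rg_collapsed and rounds < max_anneal_rounds:
        _segment(temp_hot, t_hot)
        seg = _segment(md_config.temperature, t_cool)
        rounds += 1
    seg = _segment(md_config.temperature, t_sample)

    all_rg2 = np.concatenate(rg2)
    stat, _ = stationary_average(all_rg2, 0.3)
    tail = all_rg2[int(np.floor(len(all_rg2) * 0.7)):]
    half = len(tail) // 2
    a, b = tail[:half].mean(), tail[half:].mean()
    return {
        "rg": float(np.sqrt(stat)),
        "times": np.concatenate(times),
        "rg2": all_rg2,
        "anneal_rounds": rounds,
        "equilibrated": bool(
            _trailing_rg(seg) <= rg_collapsed
            and abs(a - b) / max(a, b) < 0.05
        ),
        "system": system,
    }


def apply_doping(
    system: ParticleSystem,
    mode: str,
    sigma_lig: float = 0.023,
    z_lig: float = 3.0,
    seed: int = 0,
) -> ParticleSystem:
    """Retype one coating bead per chain to A, or insert immobile ligands.

    Modes: ``none`` (identity), ``middle`` (1-based bead ceil(N/2) of every
    chain), ``random`` (one non-tethered bead per chain, seeded; the free end
    may be selected), ``terminal`` (the free-end bead), ``ligand``
    (round(sigma_lig*A) immobile A_ligand beads on a uniform xy lattice at
    z=z_lig, each replacing the nearest water bead so the total count is
    conserved).  Doping never changes bead count, bonds or positions (ligand
    mode swaps water beads in place).
    """
    if mode == "none":
        return system
    if mode in ("middle", "random", "terminal"):
        rng = np.random.default_rng(seed)
        chains = [
            idx
            for idx in system.chains()
            if (system.types[idx] == TYPE_R_TETHERED).any()
        ]
        if not chains:
            raise ConstructionError("system contains no tethered coating chains")
        for idx in chains:
            # order beads along the chain: anchor first
            idx = idx[np.argsort(idx)]
            n = len(idx)
            if mode == "middle":
                pick = idx[math.ceil(n / 2) - 1]
            elif mode == "terminal":
                pick = idx[-1]
            else:
                pick = idx[rng.integers(1, n)]
            system.types[pick] = TYPE_A
        return system
    if mode == "ligand":
        n_lig = round(sigma_lig * system.box.area)
        waters = np.nonzero(system.types == TYPE_W)[0]
        if len(waters) < n_lig:
            raise ConstructionError(
                f"need {n_lig} water beads to convert to ligands, have {len(waters)}"
            )
        sites2d = anchor_lattice(system.box, n_lig)
        sites = np.column_stack([sites2d, np.full(n_lig, z_lig)])
        # jitter sites that clash with coating/protein beads
        solid = np.nonzero(system.types != TYPE_W)[0]
        if len(solid):
            tree = cKDTree(
                system.wrapped_positions()[solid],
                boxsize=[system.box.lx, system.box.ly,
                         1e6 + abs(system.positions[:, 2]).max()],
            )
            rng = np.random.default_rng(seed)
            for k in range(n_lig):
                for _ in range(200):
                    d, _i = tree.query(sites[k] % [system.box.lx, system.box.ly, 1e9])
                    if d >= 1.0:
                        break
                    sites[k, :2] = (
                        sites[k, :2] + rng.uniform(-0.6, 0.6, 2)
                    ) % [system.box.lx, system.box.ly]
                else:
                    raise ConstructionError("could not place ligand away from coating")
        # each ligand replaces the nearest water bead
        wtree = cKDTree(
            system.wrapped_positions()[waters],
            boxsize=[system.box.lx, system.box.ly,
                     1e6 + abs(system.positions[:, 2]).max()],
        )
        used: set[int] = set()
        for k in range(n_lig):
            dists, order = wtree.query(
                sites[k] % [system.box.lx, system.box.ly, 1e9], k=min(64, len(waters))
            )
            for cand in np.atleast_1d(order):
                w = waters[cand]
                if w not in used:
                    used.add(int(w))
                    break
            else:
                raise ConstructionError("ran out of water beads near ligand sites")
            system.types[w] = TYPE_A_LIGAND
            system.positions[w] = sites[k]
            system.velocities[w] = 0.0
            system.mobile[w] = False
        return system
    raise ValueError(f"unknown doping mode {mode!r}")


def place_proteins(
    system: ParticleSystem,
    library: list[dict],
    hmax: float,
    clearance: float = 1.0,
    seed: int = 0,
    max_retries: int = 200,
) -> ParticleSystem:
    """Distribute library conformations on a uniform xy grid above the coating.

    Each copy gets a random in-plane rotation (seeded) and is placed with its
    lowest bead at z = hmax + clearance; placements clashing (pair distance
    < 1) with existing beads are retried with xy jitter up to ``max_retries``
    times before a :class:`ConstructionError`.
    """
    rng = np.random.default_rng(seed)
    gp = len(library)
    grid = anchor_lattice(system.box, gp)
    next_mol = int(system.molecule.max()) + 1 if system.n_beads else 0
    for k, entry in enumerate(library):
        coords = np.asarray(entry["positions"], float)
        seq = np.asarray(entry["sequence"], np.int64)
        placed = False
        for attempt in range(max_retries):
            theta = rng.uniform(0, 2 * np.pi)
            c, s = np.cos(theta), np.sin(theta)
            rot = coords @ np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]]).T
            jitter = rng.uniform(-1.0, 1.0, 2) if attempt else np.zeros(2)
            xy = (grid[k] + jitter) % [system.box.lx, system.box.ly]
            shift = np.array(
                [xy[0], xy[1], hmax + clearance - rot[:, 2].min()]
            )
            cand = rot + shift
            if cand[:, 2].max() > system.box.h - 1.0:
                continue
            if system.n_beads:
                tree = cKDTree(
                    system.wrapped_positions(),
                    boxsize=[system.box.lx, system.box.ly,
                             1e6 + abs(system.positions[:, 2]).max() + system.box.h],
                )
                d, _ = tree.query(
                    cand % [system.box.lx, system.box.ly, 1e9], k=1
                )
                if d.min() < 1.0:
                    continue
            idx = system.add_beads(cand, seq, molecule=next_mol + k, mobile=True)
            system.add_bonds(np.column_stack([idx[:-1], idx[1:]]))
            placed = True
            break
        if not placed:
            raise ConstructionError(
                f"could not place protein copy {k} without overlap "
                f"after {max_retries} retries"
            )
    return system


def fill_water(
    system: ParticleSystem,
    n_total: int | None = None,
    density: float | None = None,
    rng: np.random.Generator | int = 0,
    method: str = "lattice",
    z_margin: float = 0.9,
    max_attempts_factor: int = 400,
) -> ParticleSystem:
    """Insert water beads until the system holds ``n_total`` beads.

    Either ``n_total`` or ``density`` (n_total = round(density * V)) must be
    given.  Every pairwise distance ends up >= 1 (wrapped in xy).

    method="lattice" (default): candidate sites on a jittered cubic lattice
    whose spacing guarantees the minimum distance; sites within 1 of existing
    beads are dropped and a random subset of the survivors is kept.  Robust
    at the production density n=0.65.

    method="random": plain rejection sampling; practical only at low density.
    """
    if (n_total is None) == (density is None):
        raise ValueError("give exactly one of n_total or density")
    if n_total is None:
        n_total = round(density * system.box.volume)
    needed = n_total - system.n_beads
    if needed < 0:
        raise ConstructionError(
            f"system already has {system.n_beads} beads > target {n_total}"
        )
    if needed == 0:
        return system
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    box = system.box
    lo_z = 0.0 if box.periodic_z else z_margin
    hi_z = box.h if box.periodic_z else box.h - z_margin
    slab = hi_z - lo_z
    if slab <= 0:
        raise ConstructionError("no z-range available for water insertion")

    existing = system.wrapped_positions()
    zper = box.h if box.periodic_z else 1e6 + box.h
    tree = cKDTree(existing, boxsize=[box.lx, box.ly, zper]) if len(existing) else None

    if method == "lattice":
        # spacing a >= 1 + 2*jitter keeps any two lattice sites >= 1 apart;
        # densify progressively (down to the a=1 close-packed cubic limit)
        # because sites within 1 of existing beads are dropped, which can
        # starve the supply near a dense coating
        a0 = (box.lx * box.ly * slab / (needed * 1.15 + 32)) ** (1.0 / 3.0)
        spacings = sorted({max(1.0, a0 / f) for f in (1.0, 1.1, 1.25, 1.5)},
                          reverse=True)
        for a in spacings:
            nx = max(1, int(box.lx // a))
            ny = max(1, int(box.ly // a))
            nz = max(1, int(slab // a))
            ax, ay, az = box.lx / nx, box.ly / ny, slab / nz
            amin = min(ax, ay, az)
            if amin < 1.0:
                continue
            jit = 0.5 * (amin - 1.0)
            gx, gy, gz = np.meshgrid(
                (np.arange(nx) + 0.5) * ax,
                (np.arange(ny) + 0.5) * ay,
                lo_z + (np.arange(nz) + 0.5) * az,
                indexing="ij",
            )
            sites = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
            sites += rng.uniform(-jit, jit, size=sites.shape)
            if tree is not None:
                d, _ = tree.query(sites % [box.lx, box.ly, zper], k=1)
                sites = sites[d >= 1.0]
            if len(sites) >= needed:
                keep = rng.choice(len(sites), size=needed, replace=False)
                system.add_beads(sites[keep], TYPE_W, molecule=-1, mobile=True)
                return system
        raise ConstructionError(
            f"lattice water fill could not place {needed} beads at min "
            "distance 1 (density too high)"
        )

    if method == "random":
        accepted = np.zeros((0, 3))
        attempts = 0
        budget = max_attempts_factor * needed
        while len(accepted) < needed and attempts < budget:
            m = min(4096, budget - attempts)
            cand = np.column_stack(
                [
                    rng.uniform(0, box.lx, m),
                    rng.uniform(0, box.ly, m),
                    rng.uniform(lo_z, hi_z, m),
                ]
            )
            attempts += m
            if tree is not None:
                d, _ = tree.query(cand % [box.lx, box.ly, zper], k=1)
                cand = cand[d >= 1.0]
            for c in cand:
                if len(accepted) >= needed:
                    break
                if len(accepted):
                    dd = accepted - c
                    dd[:, 0] -= box.lx * np.rint(dd[:, 0] / box.lx)
                    dd[:, 1] -= box.ly * np.rint(dd[:, 1] / box.ly)
                    if box.periodic_z:
                        dd[:, 2] -= box.h * np.rint(dd[:, 2] / box.h)
                    if (np.sum(dd * dd, axis=1) < 1.0).any():
                        continue
                accepted = np.vstack([accepted, c])
        if len(accepted) < needed:
            raise ConstructionError(
                f"rejection sampling placed only {len(accepted)}/{needed} water "
                "beads; density too high for method='random'"
            )
        system.add_beads(accepted, TYPE_W, molecule=-1, mobile=True)
        return system
    raise ValueError(f"unknown water fill method {method!r}")
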