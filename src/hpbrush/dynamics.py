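"""NVT/NVE molecular dynamics on a :class:`~hpbrush.system.ParticleSystem`.

Velocity-Verlet integration with a single Nose-Hoover thermostat (coupling
time = ``damping``) or a BAOAB Langevin thermostat (friction 1/``damping``),
xy-periodic minimum image, immobile-bead constraints (tethers, ligands), and
a cell/Verlet neighbour list rebuilt on half-skin displacement.

Degrees of freedom for the kinetic temperature count mobile beads only.
A bead escaping past z=0 or z=H, an overstretched FENE bond, or a velocity
blow-up aborts the run with a diagnostic rather than silently continuing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import build_neighbors, compute_forces_kernel, run_md_kernel
from .potentials import PairSpec
from .system import ParticleSystem

__all__ = ["IntegratorConfig", "Trajectory", "compute_forces", "run_md", "MDError"]

_THERMOSTATS = {"none": 0, "nose-hoover": 1, "langevin": 2}

_STATUS_MESSAGES = {
    1: "FENE bond overstretched (r >= RFENE)",
    2: "wall-feeling bead escaped the slab (z <= 0 or z >= H)",
    3: "velocity blow-up",
    4: "neighbour-list capacity overflow",
}


class MDError(RuntimeError):
    """Simulation abort; carries the last completed step."""

    def __init__(self, message: str, steps_done: int):
        super().__init__(message)
        self.steps_done = steps_done


@dataclass(frozen=True)
class IntegratorConfig:
    """MD run settings in reduced units.

    ``dt=0.005`` and Nose-Hoover damping time 1 at T=1 are the production
    protocol; ``thermostat="none"`` gives NVE.
    """

    dt: float = 0.005
    temperature: float = 1.0
    thermostat: str = "nose-hoover"
    damping: float = 1.0
    steps: int = 10_000
    seed: int = 0
    skin: float = 0.3
    log_stride: int = 100
    traj_stride: int = 1000

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.thermostat not in _THERMOSTATS:
            raise ValueError(
                f"unknown thermostat {self.thermostat!r}; "
                f"choose from {sorted(_THERMOSTATS)}"
            )
        if self.thermostat != "none" and self.damping <= 0:
            raise ValueError("thermostatted runs need damping > 0")
        if self.thermostat != "none" and self.temperature < 0:
            raise ValueError("temperature must be >= 0")


@dataclass
class Trajectory:
    """Frames of a bead subset plus the thermodynamic log.

    ``positions`` has shape (frames, len(selection), 3), unwrapped.  ``thermo``
    columns: time, temperature, potential, kinetic and, for biased runs, the
    reaction-coordinate sample ``bias_z``.
    """

    times: np.ndarray
    positions: np.ndarray
    selection: np.ndarray
    thermo: pd.DataFrame
    box: object = None

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def frame(self, i: int) -> np.ndarray:
        return self.positions[i]


def _exclusion_arrays(n: int, bonds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-bead 1-2 exclusion table (bonded pairs skip the pair table)."""
    counts = np.zeros(n, dtype=np.int64)
    for i, j in bonds:
        counts[i] += 1
        counts[j] += 1
    width = max(1, int(counts.max()) if n else 1)
    excl = np.full((n, width), -1, dtype=np.int64)
    fill = np.zeros(n, dtype=np.int64)
    for i, j in bonds:
        excl[i, fill[i]] = j
        fill[i] += 1
        excl[j, fill[j]] = i
        fill[j] += 1
    return excl, fill


def _kernel_tables(system: ParticleSystem) -> dict:
    tab = system.interactions
    arrays = tab.as_arrays()
    eps = arrays["pair_eps"]
    rc = arrays["pair_rc"]
    shift = 4.0 * eps * (rc ** -12.0 - rc ** -6.0)
    wca = PairSpec()
    return dict(
        pair_eps=eps,
        pair_rc2=rc ** 2,
        pair_shift=shift,
        kfene=tab.bond.kfene,
        rfene2=tab.bond.rfene ** 2,
        wca_eps=wca.epsilon,
        wca_rc2=wca.rc ** 2,
        wca_shift=wca.shift,
        wl_eps=arrays["wall_lo_eps"],
        wl_zc=arrays["wall_lo_zc"],
        wl_style=arrays["wall_lo_style"],
        wh_eps=arrays["wall_hi_eps"],
        wh_zc=arrays["wall_hi_zc"],
        wh_style=arrays["wall_hi_style"],
    )


def compute_forces(
    system: ParticleSystem,
    bias_indices: np.ndarray | None = None,
    bias_k: float = 0.0,
    bias_l: float = 1.0,
    skin: float = 0.3,
) -> tuple[np.ndarray, float]:
    """Forces on every bead and the total potential energy.

    Forces on immobile beads are computed and reported (they are what the
    constraint absorbs) but never integrated.  Wall forces act along z only;
    pair forces obey Newton's third law by construction.
    """
    n = system.n_beads
    t = _kernel_tables(system)
    excl, n_excl = _exclusion_arrays(n, system.bonds)
    rlist = float(np.sqrt(t["pair_rc2"].max())) + skin
    cap = max(1024, n * 64)
    box = system.box
    bias_idx = (
        np.asarray(bias_indices, dtype=np.int64)
        if bias_indices is not None
        else np.zeros(0, dtype=np.int64)
    )
    for _ in range(4):
        pi = np.zeros(cap, dtype=np.int64)
        pj = np.zeros(cap, dtype=np.int64)
        npairs = build_neighbors(
            system.positions, box.lx, box.ly, box.h, box.periodic_z, rlist, pi, pj
        )
        if npairs >= 0:
            break
        cap *= 4
    else:
        raise MDError("neighbour list overflow", 0)
    forces = np.zeros((n, 3))
    pe, status, _ = compute_forces_kernel(
        system.positions, system.types, system.bonds, excl, n_excl,
        box.lx, box.ly, box.h, box.periodic_z,
        t["pair_eps"], t["pair_rc2"], t["pair_shift"],
        t["kfene"], t["rfene2"], t["wca_eps"], t["wca_rc2"], t["wca_shift"],
        t["wl_eps"], t["wl_zc"], t["wl_style"],
        t["wh_eps"], t["wh_zc"], t["wh_style"],
        pi, pj, npairs, bias_idx, bias_k, bias_l, forces,
    )
    if status != 0:
        raise MDError(_STATUS_MESSAGES[status], 0)
    return forces, float(pe)


def run_md(
    system: ParticleSystem,
    config: IntegratorConfig,
    selection: np.ndarray | None = None,
    bias_indices: np.ndarray | None = None,
    bias_k: float = 0.0,
    bias_l: float = 1.0,
    t0: float = 0.0,
    thermostat_state: float = 0.0,
) -> Trajectory:
    """Integrate the system in place for ``config.steps`` steps.

    ``selection`` restricts saved trajectory frames to a bead subset (all
    beads by default).  A harmonic z-spring on the centre of mass of
    ``bias_indices`` implements the steered-MD bias; its sampled COM
    altitude appears in the thermo log as ``bias_z``.

    Returns the :class:`Trajectory`; ``trajectory.thermostat_state`` carries
    the Nose-Hoover velocity for seamless continuation runs.
    """
    n = system.n_beads
    box = system.box
    t = _kernel_tables(system)
    excl, n_excl = _exclusion_arrays(n, system.bonds)
    rlist = float(np.sqrt(t["pair_rc2"].max())) + config.skin
    sel = (
        np.arange(n, dtype=np.int64)
        if selection is None
        else np.asarray(selection, dtype=np.int64)
    )
    bias_idx = (
        np.asarray(bias_indices, dtype=np.int64)
        if bias_indices is not None
        else np.zeros(0, dtype=np.int64)
    )

    n_log = config.steps // config.log_stride
    n_frames = config.steps // config.traj_stride
    traj_pos = np.zeros((n_frames, sel.shape[0], 3))
    traj_time = np.zeros(n_frames)
    log = {k: np.zeros(n_log) for k in ("time", "temp", "pe", "ke", "z")}

    cap = max(1024, n * 64)
    status = 4
    for _ in range(4):
        pi = np.zeros(cap, dtype=np.int64)
        pj = np.zeros(cap, dtype=np.int64)
        status, steps_done, vxi = run_md_kernel(
            system.positions, system.velocities, system.types, system.mobile,
            system.bonds, excl, n_excl,
            box.lx, box.ly, box.h, box.periodic_z,
            t["pair_eps"], t["pair_rc2"], t["pair_shift"],
            t["kfene"], t["rfene2"], t["wca_eps"], t["wca_rc2"], t["wca_shift"],
            t["wl_eps"], t["wl_zc"], t["wl_style"],
            t["wh_eps"], t["wh_zc"], t["wh_style"],
            bias_idx, bias_k, bias_l,
            config.dt, config.steps, _THERMOSTATS[config.thermostat],
            config.temperature, config.damping, config.seed, thermostat_state,
            config.log_stride, config.traj_stride, sel,
            config.skin, rlist, pi, pj,
            traj_pos, traj_time,
            log["time"], log["temp"], log["pe"], log["ke"], log["z"],
            t0,
        )
        if status != 4:
            break
        cap *= 4
    if status != 0:
        raise MDError(
            f"MD aborted after {steps_done} steps: {_STATUS_MESSAGES[status]}",
            steps_done,
        )

    thermo = pd.DataFrame(
        {
            "time": log["time"],
            "temperature": log["temp"],
            "potential": log["pe"],
            "kinetic": log["ke"],
            "bias_z": log["z"],
        }
    )
    traj = Trajectory(
        times=traj_time, positions=traj_pos, selection=sel, thermo=thermo, box=box
    )
    traj.thermostat_state = vxi
    return traj
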