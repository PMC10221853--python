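"""File formats: XYZ and LAMMPS-dump trajectories, LAMMPS-data snapshots,
HDF5 system containers.

Conventions: bead indices are 1-based in files (LAMMPS convention) and
0-based in memory — the conversion lives entirely in this module.  Bead type
codes map to 1-based type ids in files, with the legend written as a comment
where the format allows.  Coordinates are written with 9 significant digits
so round-trips stay below integration noise.
"""

from __future__ import annotations

import numpy as np

from .system import (
    BEAD_TYPES,
    BoxGeometry,
    ParticleSystem,
    default_interaction_table,
)

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_xyz",
    "read_xyz",
    "write_lammps_dump",
    "read_lammps_dump",
    "write_lammps_data",
    "save_system",
    "load_system",
]

_FMT = "{:.9g}"


def write_xyz(path, frames: np.ndarray, types: np.ndarray | None = None,
              times: np.ndarray | None = None) -> None:
    """Multi-frame XYZ; element column holds the bead type name."""
    frames = np.atleast_3d(np.asarray(frames, float))
    if frames.ndim == 2:
        frames = frames[None]
    n = frames.shape[1]
    names = (
        [BEAD_TYPES[t] for t in types] if types is not None else ["X"] * n
    )
    with open(path, "w") as fh:
        for f, frame in enumerate(frames):
            if frame.shape[0] != n:
                raise ValueError("inconsistent bead counts across frames")
            t = times[f] if times is not None else f
            fh.write(f"{n}\n")
            fh.write(f"t={_FMT.format(t)}\n")
            for name, (x, y, z) in zip(names, frame):
                fh.write(
                    f"{name} {_FMT.format(x)} {_FMT.format(y)} {_FMT.format(z)}\n"
                )


def read_xyz(path) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Returns (frames (F,n,3), element names, times)."""
    frames, times, names = [], [], []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n = int(lines[i])
        comment = lines[i + 1]
        times.append(float(comment.split("=", 1)[1]) if "=" in comment else len(frames))
        block = lines[i + 2 : i + 2 + n]
        coords = np.array([list(map(float, ln.split()[1:4])) for ln in block])
        if not frames:
            names = [ln.split()[0] for ln in block]
        frames.append(coords)
        i += 2 + n
    return np.array(frames), names, np.array(times)


def write_lammps_dump(
    path,
    frames: np.ndarray,
    types: np.ndarray,
    box: BoxGeometry,
    times: np.ndarray | None = None,
    dt: float = 1.0,
) -> None:
    """LAMMPS-dump dialect with ``ITEM: ATOMS id type x y z`` records."""
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    n = frames.shape[1]
    zflag = "pp" if box.periodic_z else "ff"
    with open(path, "w") as fh:
        for f, frame in enumerate(frames):
            if frame.shape[0] != n:
                raise ValueError("inconsistent bead counts across frames")
            step = int(round((times[f] if times is not None else f) / dt))
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{step}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{n}\n")
            fh.write(f"ITEM: BOX BOUNDS pp pp {zflag}\n")
            fh.write(f"0.0 {_FMT.format(box.lx)}\n")
            fh.write(f"0.0 {_FMT.format(box.ly)}\n")
            fh.write(f"0.0 {_FMT.format(box.h)}\n")
            fh.write("ITEM: ATOMS id type x y z\n")
            for i in range(n):
                fh.write(
                    f"{i + 1} {types[i] + 1} "
                    f"{_FMT.format(frame[i, 0])} {_FMT.format(frame[i, 1])} "
                    f"{_FMT.format(frame[i, 2])}\n"
                )


def read_lammps_dump(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (frames (F,n,3), 0-based type codes, timesteps)."""
    frames, steps, types = [], [], None
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        if not lines[i].startswith("ITEM: TIMESTEP"):
            i += 1
            continue
        steps.append(int(lines[i + 1]))
        n = int(lines[i + 3])
        # skip box bounds (3 lines) and the ATOMS header
        start = i + 9
        rows = sorted(
            (lines[start + k].split() for k in range(n)), key=lambda r: int(r[0])
        )
        coords = np.array([[float(r[2]), float(r[3]), float(r[4])] for r in rows])
        if types is None:
            types = np.array([int(r[1]) - 1 for r in rows], dtype=np.int64)
        frames.append(coords)
        i = start + n
    return np.array(frames), types, np.array(steps)


def write_trajectory(trajectory, path, dialect: str = "lammps-dump",
                     types: np.ndarray | None = None, dt: float = 1.0) -> None:
    """Write a :class:`~hpbrush.dynamics.Trajectory` in the chosen dialect."""
    if dialect == "xyz":
        write_xyz(path, trajectory.positions, types, trajectory.times)
    elif dialect == "lammps-dump":
        if types is None:
            raise ValueError("lammps-dump dialect needs the bead type array")
        box = trajectory.box or BoxGeometry()
        write_lammps_dump(path, trajectory.positions, types, box,
                          trajectory.times, dt)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (xyz | lammps-dump)")


def read_trajectory(path, dialect: str = "lammps-dump"):
    if dialect == "xyz":
        return read_xyz(path)
    if dialect == "lammps-dump":
        return read_lammps_dump(path)
    raise ValueError(f"unknown dialect {dialect!r} (xyz | lammps-dump)")


def write_lammps_data(system: ParticleSystem, path) -> None:
    """LAMMPS-data-compatible snapshot (atom style molecular), with the
    bead-type legend as a comment."""
    n = system.n_beads
    legend = " ".join(f"{i + 1}={name}" for i, name in enumerate(BEAD_TYPES))
    pos = system.wrapped_positions()
    with open(path, "w") as fh:
        fh.write(f"tethered-coating system; types: {legend}\n\n")
        fh.write(f"{n} atoms\n{len(system.bonds)} bonds\n\n")
        fh.write(f"{len(BEAD_TYPES)} atom types\n1 bond types\n\n")
        fh.write(f"0.0 {_FMT.format(system.box.lx)} xlo xhi\n")
        fh.write(f"0.0 {_FMT.format(system.box.ly)} ylo yhi\n")
        fh.write(f"0.0 {_FMT.format(system.box.h)} zlo zhi\n\n")
        fh.write("Masses\n\n")
        for t in range(len(BEAD_TYPES)):
            fh.write(f"{t + 1} 1.0\n")
        fh.write("\nAtoms # molecular\n\n")
        for i in range(n):
            fh.write(
                f"{i + 1} {int(system.molecule[i]) + 1} {int(system.types[i]) + 1} "
                f"{_FMT.format(pos[i, 0])} {_FMT.format(pos[i, 1])} "
                f"{_FMT.format(pos[i, 2])}\n"
            )
        if len(system.bonds):
            fh.write("\nBonds\n\n")
            for b, (i, j) in enumerate(system.bonds):
                fh.write(f"{b + 1} 1 {i + 1} {j + 1}\n")


def save_system(system: ParticleSystem, path) -> None:
    """Full-state HDF5 snapshot (positions, velocities, types, bonds, box)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["lx"] = system.box.lx
        f.attrs["ly"] = system.box.ly
        f.attrs["h"] = system.box.h
        f.attrs["periodic_z"] = system.box.periodic_z
        f.attrs["type_legend"] = ",".join(BEAD_TYPES)
        for name in ("positions", "velocities", "types", "molecule", "mobile",
                     "bonds"):
            f.create_dataset(name, data=getattr(system, name))


def load_system(path, interactions=None) -> ParticleSystem:
    import h5py

    with h5py.File(path, "r") as f:
        box = BoxGeometry(
            lx=float(f.attrs["lx"]), ly=float(f.attrs["ly"]),
            h=float(f.attrs["h"]), periodic_z=bool(f.attrs["periodic_z"]),
        )
        return ParticleSystem(
            box=box,
            positions=f["positions"][...],
            velocities=f["velocities"][...],
            types=f["types"][...].astype(np.int64),
            molecule=f["molecule"][...].astype(np.int64),
            mobile=f["mobile"][...].astype(bool),
            bonds=f["bonds"][...].astype(np.int64),
            interactions=interactions or default_interaction_table(),
        )
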