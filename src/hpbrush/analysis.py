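"""Observables: chain metrics, asphericity, adsorption, density profiles.

Conventions
-----------
* Chain coordinates are assumed unwrapped (the dynamics layer stores them
  unwrapped, so no re-unwrapping is needed here).
* The gyration radius reported for an ensemble is <Rg^2>^(1/2), matching the
  model's bookkeeping; the end-to-end value is <R^2>^(1/2).
* A protein counts as adsorbed at a frame when its centre of mass lies below
  the mean coating height minus the protein gyration radius.
* Stationary averages use the trailing 30% of a time series by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChainMetrics",
    "ShapeRecord",
    "DensityProfile",
    "AdsorptionSeries",
    "chain_metrics",
    "gyration_tensor",
    "asphericity",
    "adsorbed_fraction",
    "density_profile",
    "stationary_average",
    "dry_height",
    "coating_height",
]


@dataclass(frozen=True)
class ChainMetrics:
    """Single-chain size metrics: Rg, end-to-end distance R, height h."""

    rg: float
    r_end: float
    height: float

    @property
    def rg2(self) -> float:
        return self.rg ** 2


@dataclass(frozen=True)
class ShapeRecord:
    """Gyration-tensor shape of one conformation.

    ``eigenvalues`` are R1 >= R2 >= R3 with R1+R2+R3 = Rg^2; ``alpha`` is the
    asphericity in [0, 1] (0 spherical, 1 rodlike).  ``alpha_diagonal`` is
    the non-rotation-invariant reading using raw diagonal elements, kept as
    a diagnostic of how much the two conventions diverge.
    """

    eigenvalues: tuple[float, float, float]
    alpha: float
    alpha_diagonal: float

    @property
    def rg2(self) -> float:
        return float(sum(self.eigenvalues))


@dataclass
class DensityProfile:
    """Bead number density rho(z) = counts / (A * dz * frames)."""

    z: np.ndarray
    rho: np.ndarray
    bin_width: float
    area: float
    n_frames: int

    def integral(self) -> float:
        """Mean selected-bead count per frame: sum rho * A * dz."""
        return float(self.rho.sum() * self.area * self.bin_width)


@dataclass
class AdsorptionSeries:
    """fadsp(t): fraction of proteins adsorbed per frame."""

    times: np.ndarray
    fraction: np.ndarray
    hmax: np.ndarray
    rg_protein: float


def chain_metrics(coords: np.ndarray) -> ChainMetrics:
    """Rg, end-to-end distance and height of one ordered bead chain.

    Rg^2 = N^-1 sum (r_i - r_cm)^2; R = |r_N - r_1|; h = max z_i.
    """
    coords = np.asarray(coords, float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("chain_metrics needs an (N, 3) array with N >= 1")
    com = coords.mean(axis=0)
    rg2 = float(np.mean(np.sum((coords - com) ** 2, axis=1)))
    r_end = float(np.linalg.norm(coords[-1] - coords[0]))
    return ChainMetrics(rg=np.sqrt(rg2), r_end=r_end, height=float(coords[:, 2].max()))


def gyration_tensor(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, float)
    d = coords - coords.mean(axis=0)
    return d.T @ d / len(d)


def asphericity(coords: np.ndarray) -> ShapeRecord:
    """Shape descriptor from the gyration-tensor eigenvalues.

    alpha = [(R1-R2)^2 + (R2-R3)^2 + (R3-R1)^2] / [2 (R1+R2+R3)^2], using the
    eigenvalues (rotation-invariant; the raw-diagonal variant is reported as
    a diagnostic only).
    """
    coords = np.asarray(coords, float)
    if coords.shape[0] < 2:
        raise ValueError("asphericity needs at least 2 beads")
    s = gyration_tensor(coords)
    if np.trace(s) < 1e-14:
        raise ValueError("all beads coincident: asphericity undefined")
    eigs = np.sort(np.linalg.eigvalsh(s))[::-1]

    def _alpha(r1: float, r2: float, r3: float) -> float:
        num = (r1 - r2) ** 2 + (r2 - r3) ** 2 + (r3 - r1) ** 2
        return num / (2.0 * (r1 + r2 + r3) ** 2)

    diag = np.sort(np.diag(s))[::-1]
    return ShapeRecord(
        eigenvalues=(float(eigs[0]), float(eigs[1]), float(eigs[2])),
        alpha=float(_alpha(*eigs)),
        alpha_diagonal=float(_alpha(*diag)),
    )


def coating_height(positions: np.ndarray, chains: list[np.ndarray]) -> float:
    """hmax = <h>: mean over chains of the per-chain maximum bead altitude."""
    return float(np.mean([positions[idx, 2].max() for idx in chains]))


def adsorbed_fraction(
    trajectory,
    protein_chains: list[np.ndarray],
    rg_protein: float,
    coating_chains: list[np.ndarray] | None = None,
    hmax: float | None = None,
) -> AdsorptionSeries:
    """Fraction of proteins adsorbed per frame.

    A protein is adsorbed when COM_z < hmax - Rg_p.  The coating-height
    reference is recomputed per frame from ``coating_chains`` (the default
    and recommended mode: adsorption itself shifts the coating height), or
    held at the supplied static ``hmax``.

    Chain index lists refer to positions *within the trajectory selection*.
    """
    if rg_protein <= 0:
        raise ValueError("protein gyration radius must be positive")
    if (coating_chains is None) == (hmax is None):
        raise ValueError("give exactly one of coating_chains or hmax")
    nf = trajectory.n_frames
    frac = np.zeros(nf)
    href = np.zeros(nf)
    for f in range(nf):
        pos = trajectory.positions[f]
        h = coating_height(pos, coating_chains) if coating_chains else hmax
        href[f] = h
        coms = np.array([pos[idx, 2].mean() for idx in protein_chains])
        frac[f] = np.mean(coms < h - rg_protein)
    return AdsorptionSeries(
        times=trajectory.times.copy(), fraction=frac, hmax=href, rg_protein=rg_protein
    )


def density_profile(
    trajectory,
    selection_mask: np.ndarray,
    area: float,
    h: float,
    bin_width: float = 0.2,
    trailing_fraction: float | None = None,
) -> DensityProfile:
    """z number-density histogram of the selected beads.

    ``selection_mask`` picks beads within the trajectory's stored subset.
    With ``trailing_fraction`` set, only that trailing share of the frames
    contributes (the stationary window).
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if not np.any(selection_mask):
        raise ValueError("empty selection")
    frames = trajectory.positions[:, selection_mask, 2]
    if trailing_fraction is not None:
        start = int(np.floor(len(frames) * (1.0 - trailing_fraction)))
        frames = frames[start:]
    n_frames = len(frames)
    edges = np.arange(0.0, h + bin_width, bin_width)
    counts, _ = np.histogram(frames.ravel(), bins=edges)
    rho = counts / (area * bin_width * n_frames)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(
        z=centers, rho=rho, bin_width=bin_width, area=area, n_frames=n_frames
    )


def stationary_average(
    series: np.ndarray, fraction: float = 0.3
) -> tuple[float, float]:
    """Mean and standard error over the trailing ``fraction`` of a series."""
    series = np.asarray(series, float)
    if series.size == 0:
        raise ValueError("empty series")
    start = int(np.floor(series.size * (1.0 - fraction)))
    tail = series[start:]
    sem = float(tail.std(ddof=1) / np.sqrt(tail.size)) if tail.size > 1 else 0.0
    return float(tail.mean()), sem


def dry_height(sigma: float, n: int, density: float) -> float:
    """Dry coating height hdry = sigma * N / n (the collapsed-layer reference)."""
    if density <= 0:
        raise ValueError("bead number density must be positive")
    return sigma * n / density
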