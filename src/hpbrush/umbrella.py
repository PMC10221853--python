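"""Umbrella sampling along z and the WHAM free-energy estimator.

The steered-MD protocol tethers a single protein's centre of mass to the
lower wall with a harmonic z-spring of rest length ``lspring`` (~ the protein
gyration radius).  Unusually, the umbrella ladder varies the spring
*stiffness*, not the window centre: window j uses k_j = j * dk, from a free
window (k=0) up to k_max, beyond which the stationary spring extension no
longer changes because the protein has reached the surface.

WHAM combines the biased histograms h_j(z) into the unbiased probability
P(z) by iterating

    P(z) = sum_j g_j^-1 h_j(z) / sum_j N_j g_j^-1 exp[-beta (w_j(z) - f_j)]
    exp(-beta f_j) = int_0^Lz exp(-beta w_j(z)) P(z) dz

to self-consistency, and reports PMF(z) = -(1/beta) ln P(z)/P(z0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UmbrellaWindow",
    "WHAMConfig",
    "PMFProfile",
    "bias_energy",
    "umbrella_schedule",
    "run_umbrella_protocol",
    "wham_solve",
    "sample_biased_windows",
    "integrated_autocorrelation_time",
]


@dataclass
class UmbrellaWindow:
    """One biased run: spring constant, rest length and the COM z samples."""

    kspring: float
    lspring: float
    samples: np.ndarray
    g: float = 1.0  # statistical inefficiency factor (1+2*tau)^-1
    tau: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, float)
        if self.kspring < 0:
            raise ValueError("spring constant must be >= 0")
        if not 0.0 < self.g <= 1.0:
            raise ValueError("g must be in (0, 1]")

    @property
    def n(self) -> int:
        return self.samples.size


@dataclass
class WHAMConfig:
    """WHAM estimator settings.

    ``z0`` picks the PMF reference: a float pins the zero at that altitude's
    bin; ``None`` (default) uses the sampled bin farthest from the lower wall
    with nonzero probability — a bulk reference.
    """

    beta: float = 1.0
    lz: float = 20.0
    bin_width: float = 0.1
    tol: float = 1e-6
    max_iter: int = 100_000
    z0: float | None = None

    def edges(self) -> np.ndarray:
        return np.arange(0.0, self.lz + self.bin_width * 0.5, self.bin_width)


@dataclass
class PMFProfile:
    """WHAM output: bin centres, PMF (kBT), unbiased P(z), convergence info."""

    z: np.ndarray
    pmf: np.ndarray
    p: np.ndarray
    f_windows: np.ndarray
    iterations: int
    converged: bool
    bin_width: float = 0.1

    def sampled(self) -> np.ndarray:
        """Mask of bins that received any samples (P > 0)."""
        return self.p > 0


def bias_energy(z: float | np.ndarray, k: float, l: float = 1.0):
    """Harmonic spring bias w(z) = (k/2)(z - l)^2 on the COM altitude."""
    return 0.5 * k * (np.asarray(z, float) - l) ** 2


def umbrella_schedule(
    dk: float = 0.005,
    k_max: float = 0.3,
    t_window: float = 500.0,
    stride: int = 10,
    dt: float = 0.005,
) -> dict:
    """Window ladder bookkeeping: stiffnesses and samples per window.

    With the production protocol (dk=0.005 up to 0.3, t=500 per window at
    dt=0.005, saving every 10 steps) this gives 61 windows of 10^4 samples.
    """
    n_windows = int(round(k_max / dk)) + 1
    ks = dk * np.arange(n_windows)
    steps = int(round(t_window / dt))
    if steps % stride != 0:
        warnings.warn(
            f"window length {steps} steps not divisible by stride {stride}; "
            "rounding down", stacklevel=2,
        )
    return {
        "k": ks,
        "n_windows": n_windows,
        "steps_per_window": steps,
        "samples_per_window": steps // stride,
    }


def run_umbrella_protocol(
    system,
    protein_molecule: int,
    dk: float = 0.005,
    k_max: float = 0.3,
    lspring: float = 1.0,
    t_window: float = 500.0,
    stride: int = 10,
    seed: int = 0,
    md_config=None,
    burn_in: float = 0.1,
) -> list[UmbrellaWindow]:
    """Run the stiffness-ladder umbrella protocol on one protein.

    Windows run in ascending k, each continuing from the previous window's
    final state (the protein starts outside the coating and is pulled in as
    the spring stiffens); the first ``burn_in`` fraction of each window's
    samples is discarded as inter-window equilibration.  The system is
    mutated in place.
    """
    from .dynamics import IntegratorConfig, run_md

    protein = system.molecule_indices(protein_molecule)
    if protein.size == 0:
        raise ValueError(f"no beads in molecule {protein_molecule}")
    sched = umbrella_schedule(dk, k_max, t_window, stride,
                              md_config.dt if md_config else 0.005)
    if md_config is None:
        md_config = IntegratorConfig()
    windows: list[UmbrellaWindow] = []
    vxi = 0.0
    t0 = 0.0
    for j, k in enumerate(sched["k"]):
        cfg = IntegratorConfig(
            dt=md_config.dt,
            temperature=md_config.temperature,
            thermostat=md_config.thermostat,
            damping=md_config.damping,
            steps=sched["steps_per_window"],
            seed=(seed * 613 + j) % (2 ** 31),
            log_stride=stride,
            traj_stride=max(stride, sched["steps_per_window"]),
            skin=md_config.skin,
        )
        traj = run_md(
            system, cfg, selection=protein,
            bias_indices=protein, bias_k=float(k), bias_l=lspring,
            t0=t0, thermostat_state=vxi,
        )
        vxi = getattr(traj, "thermostat_state", 0.0)
        t0 = float(traj.thermo["time"].iloc[-1])
        samples = traj.thermo["bias_z"].to_numpy()
        cut = int(np.floor(len(samples) * burn_in))
        windows.append(
            UmbrellaWindow(kspring=float(k), lspring=lspring, samples=samples[cut:])
        )
    return windows


def integrated_autocorrelation_time(x: np.ndarray, c: float = 5.0) -> float:
    """Integrated autocorrelation time with Sokal's adaptive windowing."""
    x = np.asarray(x, float)
    n = x.size
    if n < 4:
        return 0.0
    xc = x - x.mean()
    var = np.dot(xc, xc) / n
    if var == 0:
        return 0.0
    acf = np.correlate(xc, xc, "full")[n - 1 :] / (n * var)
    tau = 0.5
    for m in range(1, n):
        tau += acf[m]
        if m >= c * max(tau, 0.5):
            break
    return float(max(tau - 0.5, 0.0))


def wham_solve(
    windows: list[UmbrellaWindow],
    config: WHAMConfig | None = None,
    estimate_g: bool = False,
) -> PMFProfile:
    """Self-consistent WHAM solution for the unbiased P(z) and PMF(z).

    With ``estimate_g=True`` each window's weight factor g_j = (1+2 tau_j)^-1
    is estimated from its integrated autocorrelation time; the default takes
    every g_j = 1.  Non-convergence returns ``converged=False`` rather than
    raising; a gap in histogram overlap between adjacent windows triggers a
    warning naming the gap.
    """
    if not windows or all(w.n == 0 for w in windows):
        raise ValueError("need at least one window with samples")
    config = config or WHAMConfig()
    edges = config.edges()
    centers = 0.5 * (edges[:-1] + edges[1:])
    dz = config.bin_width
    beta = config.beta

    nw = len(windows)
    hists = np.zeros((nw, centers.size))
    gs = np.ones(nw)
    for j, w in enumerate(windows):
        if w.samples.min() < edges[0] or w.samples.max() > edges[-1]:
            raise ValueError(
                f"window {j} samples outside the bin range (0, {config.lz})"
            )
        hists[j], _ = np.histogram(w.samples, bins=edges)
        if estimate_g:
            tau = integrated_autocorrelation_time(w.samples)
            w.tau = tau
            w.g = 1.0 / (1.0 + 2.0 * tau)
        gs[j] = w.g

    # adjacent-window overlap diagnostic
    for j in range(nw - 1):
        if not np.any((hists[j] > 0) & (hists[j + 1] > 0)):
            warnings.warn(
                f"no histogram overlap between windows {j} and {j + 1} "
                f"(k={windows[j].kspring:.4g} and {windows[j + 1].kspring:.4g})",
                stacklevel=2,
            )

    nj = hists.sum(axis=1)
    w_jz = np.array(
        [bias_energy(centers, w.kspring, w.lspring) for w in windows]
    )
    num = (hists / gs[:, None]).sum(axis=0)
    f = np.zeros(nw)
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        den = ((nj / gs)[:, None] * np.exp(-beta * (w_jz - f[:, None]))).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(den > 0, num / den, 0.0)
        norm = p.sum() * dz
        p /= norm
        fnew = -np.log(np.clip((np.exp(-beta * w_jz) * p[None, :]).sum(axis=1) * dz,
                               1e-300, None)) / beta
        fnew -= fnew[0]  # gauge: f_0 = 0 (PMF is invariant to a common shift)
        delta = np.max(np.abs(fnew - f))
        f = fnew
        if delta < config.tol:
            converged = True
            break

    den = ((nj / gs)[:, None] * np.exp(-beta * (w_jz - f[:, None]))).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(den > 0, num / den, 0.0)
    p /= p.sum() * dz

    with np.errstate(divide="ignore"):
        pmf = np.where(p > 0, -np.log(np.clip(p, 1e-300, None)) / beta, np.nan)
    if config.z0 is not None:
        i0 = int(np.argmin(np.abs(centers - config.z0)))
        if p[i0] <= 0:
            raise ValueError(f"reference z0={config.z0} lies in an unsampled bin")
    else:
        nz = np.nonzero(p > 0)[0]
        i0 = nz[-1]  # sampled bin farthest from the lower wall (bulk side)
    pmf -= pmf[i0]
    return PMFProfile(
        z=centers, pmf=pmf, p=p, f_windows=f, iterations=it,
        converged=converged, bin_width=dz,
    )


def sample_biased_windows(
    pmf_func,
    ks: np.ndarray,
    n_samples: int,
    config: WHAMConfig | None = None,
    lspring: float = 1.0,
    support: tuple[float, float] | None = None,
    seed: int = 0,
) -> list[UmbrellaWindow]:
    """Synthetic biased samples from a known PMF (validation aid).

    For each stiffness k the per-bin probability is exactly
    p(z) ~ exp(-beta [PMF(z) + w_k(z)]) on the bin centres within
    ``support``; samples are multinomial draws from it, so the generated
    windows follow the biased Boltzmann weights by construction.
    """
    config = config or WHAMConfig()
    rng = np.random.default_rng(seed)
    edges = config.edges()
    centers = 0.5 * (edges[:-1] + edges[1:])
    lo, hi = support if support else (edges[0], edges[-1])
    mask = (centers > lo) & (centers < hi)
    windows = []
    for k in np.asarray(ks, float):
        w = bias_energy(centers, k, lspring)
        logp = np.where(mask, -config.beta * (pmf_func(centers) + w), -np.inf)
        p = np.exp(logp - logp.max())
        p /= p.sum()
        counts = rng.multinomial(n_samples, p)
        # place samples at their bin centres (consistent with binned WHAM)
        samples = np.repeat(centers, counts)
        windows.append(UmbrellaWindow(kspring=float(k), lspring=lspring,
                                      samples=samples))
    return windows
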