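"""Run configuration: YAML parsing, interaction-name notation, validation.

Wall interactions are named ``<eps>W<zc>`` (e.g. ``3W2.5``) and pair
interactions ``<eps>LJ<rc>`` (e.g. ``1LJ1.5``); ``RW`` denotes the purely
repulsive wall (9-3 truncated at its minimum) and ``WCA`` the purely
repulsive pair.  An empty config gives the full-scale production preset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields

import yaml

from .potentials import PairSpec, WallSpec, WCA_CUTOFF, WALL_REPULSIVE_CUTOFF

__all__ = [
    "RunConfig",
    "SystemConfig",
    "IntegratorSection",
    "AnalysisSection",
    "UmbrellaSection",
    "parse_config",
    "parse_wall_name",
    "parse_pair_name",
    "wall_name",
    "pair_name",
    "ConfigError",
]

_WALL_RE = re.compile(r"^([0-9.]+)W([0-9.]+)$")
_PAIR_RE = re.compile(r"^([0-9.]+)LJ([0-9.]+)$")


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending key."""


def parse_wall_name(name: str, side: str = "lower") -> WallSpec:
    """``"3W2.5"`` -> WallSpec(eps=3, zc=2.5); ``"RW"`` -> repulsive wall."""
    name = name.strip()
    if name == "RW":
        return WallSpec(epsilon=1.0, zc=WALL_REPULSIVE_CUTOFF, side=side)
    m = _WALL_RE.match(name)
    if not m:
        raise ConfigError(f"invalid wall name {name!r} (expected e.g. '3W2.5' or 'RW')")
    return WallSpec(epsilon=float(m.group(1)), zc=float(m.group(2)), side=side)


def parse_pair_name(name: str) -> PairSpec:
    """``"1LJ1.5"`` -> PairSpec(eps=1, rc=1.5); ``"WCA"`` -> WCA."""
    name = name.strip()
    if name == "WCA":
        return PairSpec()
    m = _PAIR_RE.match(name)
    if not m:
        raise ConfigError(f"invalid pair name {name!r} (expected e.g. '1LJ1.5' or 'WCA')")
    return PairSpec(epsilon=float(m.group(1)), rc=float(m.group(2)))


def wall_name(spec: WallSpec) -> str:
    if spec.repulsive:
        return "RW"
    return f"{spec.epsilon:g}W{spec.zc:g}"


def pair_name(spec: PairSpec) -> str:
    if spec.epsilon == 1.0 and abs(spec.rc - WCA_CUTOFF) < 1e-12:
        return "WCA"
    return f"{spec.epsilon:g}LJ{spec.rc:g}"


@dataclass
class SystemConfig:
    """Box, coating, protein and doping parameters (full-scale defaults)."""

    lx: float = 54.29
    ly: float = 64.44
    h: float = 20.0
    n_chains: int = 81
    chain_length: int = 50
    np_beads: int = 40
    hp: float = 0.25
    gp: int = 24
    density: float = 0.65
    n_total: int = 45_510
    wall: str = "1W1"            # protein-wall attraction, eps-W-zc notation
    doping: str = "none"         # none | middle | random | terminal | ligand
    ap_pair: str = "1LJ1.5"      # A-bead to P-bead attraction
    hh_pair: str = "120LJ1.19"   # hydrophobic attraction (config-exposed)
    sigma_lig: float = 0.023
    z_lig: float = 3.0
    p_wall_style: str = "93"     # "93" | "lj" z-wall for polar beads


@dataclass
class IntegratorSection:
    dt: float = 0.005
    temperature: float = 1.0
    thermostat: str = "nose-hoover"
    damping: float = 1.0
    steps: int = 100_000
    skin: float = 0.3
    log_stride: int = 100
    traj_stride: int = 1000


@dataclass
class AnalysisSection:
    bin_width: float = 0.2
    trailing_fraction: float = 0.3


@dataclass
class UmbrellaSection:
    dk: float = 0.005
    k_max: float = 0.3
    lspring: float = 1.0
    t_window: float = 500.0
    stride: int = 10
    burn_in: float = 0.1
    wham_bin_width: float = 0.1


@dataclass
class RunConfig:
    system: SystemConfig = field(default_factory=SystemConfig)
    integrator: IntegratorSection = field(default_factory=IntegratorSection)
    analysis: AnalysisSection = field(default_factory=AnalysisSection)
    umbrella: UmbrellaSection = field(default_factory=UmbrellaSection)
    seed: int = 0

    def interaction_table(self):
        from .system import default_interaction_table

        s = self.system
        return default_interaction_table(
            protein_wall=parse_wall_name(s.wall),
            ap_pair=parse_pair_name(s.ap_pair),
            hh_epsilon=parse_pair_name(s.hh_pair).epsilon,
            hh_rc=parse_pair_name(s.hh_pair).rc,
            p_wall_style=s.p_wall_style,
        )


def _fill(cls, data: dict, section: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in [{section}]: {', '.join(sorted(unknown))}"
        )
    obj = cls(**data)
    return obj


def _validate(cfg: RunConfig) -> None:
    s = cfg.system
    for key in ("lx", "ly", "h"):
        if getattr(s, key) <= 0:
            raise ConfigError(f"system.{key} must be positive")
    if not 0.0 < s.hp < 1.0:
        raise ConfigError(f"system.hp must be in (0, 1), got {s.hp}")
    if s.doping not in ("none", "middle", "random", "terminal", "ligand"):
        raise ConfigError(f"system.doping invalid: {s.doping!r}")
    parse_wall_name(s.wall)
    parse_pair_name(s.ap_pair)
    parse_pair_name(s.hh_pair)
    if cfg.integrator.dt <= 0:
        raise ConfigError("integrator.dt must be positive")
    if cfg.umbrella.dk <= 0 or cfg.umbrella.k_max < 0:
        raise ConfigError("umbrella.dk must be positive and k_max >= 0")


def parse_config(text: str) -> RunConfig:
    """Parse a YAML run configuration; unknown keys are rejected.

    An empty document yields the all-defaults (full-scale) configuration.
    """
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping of sections")
    sections = {"system": SystemConfig, "integrator": IntegratorSection,
                "analysis": AnalysisSection, "umbrella": UmbrellaSection}
    unknown = set(data) - set(sections) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown section(s): {', '.join(sorted(unknown))}")
    kwargs = {
        name: _fill(cls, data.get(name, {}) or {}, name)
        for name, cls in sections.items()
    }
    cfg = RunConfig(seed=int(data.get("seed", 0)), **kwargs)
    _validate(cfg)
    return cfg
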