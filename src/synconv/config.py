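"""Network configurations for grouped and sequential dendritic computation.

A :class:`NetworkConfig` bundles the connectivity, activity, and geometry
parameters that govern every downstream stage: connection probability ``p``,
presynaptic population size ``T_pre``, background Poisson rate ``R`` (Hz),
ensemble time window ``D`` (s), group zone length ``Z`` (um), sequence
spacing ``S`` and window ``delta`` (um), total (collapsed single-cable)
dendritic length ``L`` (um), inter-synapse interval ``sigma`` (um), ensemble
size ``N``, number of ensembles ``M``, participation probability ``p_e``,
and the postsynaptic population size ``T_post``.

Six built-in configurations cover hippocampal and cortical statistics for
each of three dendritic integration mechanisms (chemical, CICR, electrical).
In all of them the dendrite discretization is consistent: p * T_pre =
L / sigma = 20,000 synapses per postsynaptic neuron.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "NetworkConfig",
    "BUILTIN_NAMES",
    "builtin_config",
    "load_config",
    "save_config",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised for unknown configuration names or invariant violations."""


@dataclass(frozen=True)
class NetworkConfig:
    name: str
    p: float            # connection probability
    T_pre: int          # presynaptic population size
    R: float            # background rate (Hz)
    D: float            # per-ensemble time window (s)
    Z: float            # group zone length (um)
    S: float            # minimum sequence spacing (um)
    delta: float        # sequence convergence window (um)
    L: float = 10_000.0     # total dendritic length (um)
    sigma: float = 0.5      # inter-synapse interval (um)
    N: int = 100            # ensemble size
    M: int = 4              # number of ensembles
    p_e: float = 0.8        # ensemble participation probability
    T_post: int = 400_000   # postsynaptic population size

    def __post_init__(self) -> None:
        errs = []
        for field, lo_open in (("p", False), ("p_e", False)):
            v = getattr(self, field)
            if not (0.0 <= v <= 1.0):
                errs.append(f"{field}={v} must lie in [0, 1]")
        for field in ("T_pre", "D", "Z", "S", "delta", "L", "sigma", "N", "M", "T_post"):
            v = getattr(self, field)
            if not v > 0:
                errs.append(f"{field}={v} must be strictly positive")
        if self.R < 0:
            errs.append(f"R={self.R} must be nonnegative")
        if self.Z > self.L:
            errs.append(f"Z={self.Z} exceeds L={self.L}")
        if self.S + self.delta > self.L:
            errs.append(f"S+delta={self.S + self.delta} exceeds L={self.L}")
        if errs:
            raise ConfigError("; ".join(errs))

    # -- derived quantities -------------------------------------------------

    @property
    def n_synapses(self) -> int:
        """Synapses per postsynaptic neuron, p * T_pre (= L / sigma)."""
        return int(round(self.p * self.T_pre))

    @property
    def p_bg(self) -> float:
        """Per-synapse probability of a background hit in window D, 1 - e^-RD."""
        return -math.expm1(-self.R * self.D)

    @property
    def zone_synapses(self) -> int:
        """Number of synapses in a zone of length Z."""
        w = self.Z / self.sigma
        if abs(w - round(w)) > 1e-9:
            raise ConfigError(f"Z/sigma = {w} is not an integer synapse count")
        return int(round(w))

    @property
    def spacing_offsets(self) -> tuple[int, int]:
        """Sequence spacing [S, S+delta) as a half-open synapse-offset range."""
        lo = self.S / self.sigma
        hi = (self.S + self.delta) / self.sigma
        if abs(lo - round(lo)) > 1e-9 or abs(hi - round(hi)) > 1e-9:
            raise ConfigError("S/sigma and (S+delta)/sigma must be integers")
        return int(round(lo)), int(round(hi))

    def replace(self, **kwargs) -> "NetworkConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# Table of example network configurations: (p, T_pre, R, D, Z, S, delta).
_BUILTINS: dict[str, tuple[float, int, float, float, float, float, float]] = {
    "hippo-chem":  (0.05, 400_000, 0.01, 2.0,   10.0, 2.0,  1.5),
    "hippo-CICR":  (0.05, 400_000, 0.01, 0.2,   10.0, 2.0,  1.5),
    "hippo-elec":  (0.05, 400_000, 0.1,  0.004, 50.0, 10.0, 5.0),
    "cortex-chem": (0.2,  100_000, 0.1,  2.0,   10.0, 2.0,  1.5),
    "cortex-CICR": (0.2,  100_000, 0.1,  0.2,   10.0, 2.0,  1.5),
    "cortex-elec": (0.2,  100_000, 1.0,  0.004, 50.0, 10.0, 5.0),
}

BUILTIN_NAMES = tuple(_BUILTINS)


def builtin_config(name: str, **overrides) -> NetworkConfig:
    """Return a built-in configuration by name, optionally overriding fields.

    Group analyses default to N=100 ensemble neurons; sequence analyses
    conventionally use N=1000 (pass ``N=1000``).
    """
    if name not in _BUILTINS:
        raise ConfigError(
            f"unknown configuration {name!r}; valid names: {', '.join(BUILTIN_NAMES)}"
        )
    p, T_pre, R, D, Z, S, delta = _BUILTINS[name]
    cfg = NetworkConfig(name=name, p=p, T_pre=T_pre, R=R, D=D, Z=Z, S=S, delta=delta)
    if overrides:
        cfg = cfg.replace(**overrides)
    return cfg


def load_config(path: str | Path) -> NetworkConfig:
    """Load a configuration from a flat key-value YAML file.

    The file may name a built-in via ``extends:`` (or ``name:`` of a
    built-in); any other keys override that base. Unknown keys and invariant
    violations raise :class:`ConfigError`.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} must contain a flat key-value mapping")

    base_name = raw.pop("extends", None) or raw.get("name")
    valid = {f.name for f in dataclasses.fields(NetworkConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    if base_name in _BUILTINS:
        raw.pop("name", None)
        try:
            return builtin_config(base_name, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
    try:
        return NetworkConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def save_config(config: NetworkConfig, path: str | Path) -> None:
    """Serialize a configuration to YAML; round-trips through load_config."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
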