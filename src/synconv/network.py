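"""Synthetic random feedforward connectivity and presynaptic activity.

Connectivity is sampled onto a single collapsed dendrite of length L,
discretized into p*T_pre uniformly spaced synapses (20,000 in the built-in
configurations); each synapse draws its presynaptic source independently
and uniformly from the T_pre-neuron input layer (with replacement — one
axon may form several synapses). The first M*N presynaptic identifiers
partition into M ensembles of N neurons; all remaining neurons only ever
participate in background activity.

Presynaptic activity for one trial is coded over {+1, -1, 0}: +1 for
ensemble-driven participation, -1 for a background (Poisson) hit with
probability p_bg = 1 - e^(-RD) per window, 0 for silence. Group rasters
have a single time step with every ensemble eligible at once; sequence
rasters have one eligible ensemble per step (at most MAX_M = 9 steps), and
ensemble neurons outside their step fall back to the background pool. An
ensemble neuron that fails its participation draw is silent for that step.

Seeding: within a batch, the connectivity seed changes per run while the
activity seed is shared, so every run sees identical presynaptic activity
on freshly sampled wiring.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np

from .config import NetworkConfig

__all__ = [
    "MAX_M",
    "Connectivity",
    "ActivityRaster",
    "TrialSet",
    "build_connectivity",
    "generate_activity",
    "run_batch",
    "connectivity_seed",
    "save_connectivity",
    "load_connectivity",
]

MAX_M = 9  # longest sequence raster supported

TRIAL_TYPES = ("connectivity", "stimulus", "background_only")


@dataclass(frozen=True)
class Connectivity:
    """Random wiring of one run: (neurons x synapse positions) source ids."""

    presyn_ids: np.ndarray  # int32, shape (n_neurons, n_synapses)
    config: NetworkConfig
    run_seed: int

    @property
    def n_neurons(self) -> int:
        return self.presyn_ids.shape[0]

    @property
    def n_synapses(self) -> int:
        return self.presyn_ids.shape[1]

    def positions_um(self) -> np.ndarray:
        """Physical synapse positions on the implicit uniform grid."""
        return np.arange(self.n_synapses) * self.config.sigma


@dataclass(frozen=True)
class ActivityRaster:
    """Presynaptic activity over time steps, coded {+1, -1, 0}."""

    values: np.ndarray  # int8, shape (T_pre, n_steps)
    trial_type: str
    ensemble_order: np.ndarray
    activity_seed: int

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class TrialSet:
    """Activity rasters of one run, grouped by trial type."""

    connectivity: list[ActivityRaster]
    stimulus: list[ActivityRaster]
    background_only: list[ActivityRaster]


def connectivity_seed(base_seed: int, run_index: int) -> int:
    """Derive a per-run connectivity seed (stable hash below 2^31)."""
    ss = np.random.SeedSequence([int(base_seed), int(run_index), 0x5EED])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def build_connectivity(config: NetworkConfig, n_neurons: int, run_seed: int) -> Connectivity:
    """Sample random feedforward connectivity for ``n_neurons`` target cells.

    Each of the p*T_pre synapses per neuron draws its source uniformly from
    [0, T_pre), so a fixed ensemble of N neurons contributes pN expected
    connections per target neuron. Same ``run_seed`` -> bit-identical wiring.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    rng = np.random.default_rng(run_seed)
    ids = rng.integers(0, config.T_pre, size=(n_neurons, config.n_synapses), dtype=np.int32)
    return Connectivity(presyn_ids=ids, config=config, run_seed=int(run_seed))


def generate_activity(
    config: NetworkConfig,
    trial_type: str,
    n_steps: int = 1,
    ensemble_order: np.ndarray | None = None,
    activity_seed: int = 0,
) -> ActivityRaster:
    """Sample one presynaptic activity raster.

    For sequence rasters (n_steps > 1), ``ensemble_order`` is a permutation
    of 0..M-1 giving which ensemble is +1-eligible at each of the first M
    steps; group rasters (n_steps == 1) make all M ensembles simultaneously
    eligible. Steps beyond M (up to MAX_M) carry background only.
    """
    if trial_type not in TRIAL_TYPES:
        raise ValueError(f"trial_type must be one of {TRIAL_TYPES}")
    if not (1 <= n_steps <= MAX_M):
        raise ValueError(f"n_steps must lie in [1, {MAX_M}]")
    M, N = config.M, config.N
    if ensemble_order is None:
        ensemble_order = np.arange(M)
    ensemble_order = np.asarray(ensemble_order, dtype=int)
    if sorted(ensemble_order.tolist()) != list(range(M)):
        raise ValueError("ensemble_order must be a permutation of 0..M-1")
    if n_steps > 1 and n_steps < M:
        raise ValueError("sequence rasters need n_steps >= M")

    rng = np.random.default_rng(activity_seed)
    values = np.zeros((config.T_pre, n_steps), dtype=np.int8)

    p_e = 1.0 if trial_type == "connectivity" else config.p_e
    p_bg = 0.0 if trial_type == "connectivity" else config.p_bg

    # ensemble eligibility mask: (M*N, n_steps) True where the neuron's
    # ensemble is scheduled in that step
    eligible = np.zeros((M * N, n_steps), dtype=bool)
    if trial_type != "background_only":
        if n_steps == 1:
            eligible[:, 0] = True
        else:
            for step in range(M):
                ens = ensemble_order[step]
                eligible[ens * N : (ens + 1) * N, step] = True

    if trial_type != "background_only":
        fires = rng.random((M * N, n_steps)) < p_e
        values[: M * N][eligible & fires] = 1

    if p_bg > 0.0:
        bg = rng.random((config.T_pre, n_steps)) < p_bg
        bg[: M * N][eligible] = False  # an ensemble neuron in its step is +1 or silent
        values[bg & (values == 0)] = -1

    return ActivityRaster(
        values=values,
        trial_type=trial_type,
        ensemble_order=ensemble_order,
        activity_seed=int(activity_seed),
    )


def run_batch(
    config: NetworkConfig,
    n_runs: int,
    neurons_per_run: int,
    base_seed: int,
    *,
    n_steps: int = 1,
    n_stimulus_trials: int = 95,
    n_background_trials: int = 4,
    ensemble_order: np.ndarray | None = None,
) -> Iterator[tuple[Connectivity, TrialSet]]:
    """Yield (connectivity, trials) for each run of a batch.

    The connectivity seed is a deterministic function of ``base_seed`` and
    the run index, while activity seeds depend on ``base_seed`` and the
    trial index only, so all runs share identical presynaptic activity.
    The default trial split (1 connectivity + 95 stimulus + 4 background)
    totals the conventional 100 trials; both counts are free parameters.
    """
    if n_runs < 1 or neurons_per_run < 1:
        raise ValueError("n_runs and neurons_per_run must be >= 1")
    for run in range(n_runs):
        conn = build_connectivity(config, neurons_per_run, connectivity_seed(base_seed, run))
        trials = TrialSet(
            connectivity=[
                generate_activity(config, "connectivity", n_steps, ensemble_order, base_seed)
            ],
            stimulus=[
                generate_activity(
                    config, "stimulus", n_steps, ensemble_order, _activity_seed(base_seed, 1, t)
                )
                for t in range(n_stimulus_trials)
            ],
            background_only=[
                generate_activity(
                    config, "background_only", n_steps, ensemble_order,
                    _activity_seed(base_seed, 2, t),
                )
                for t in range(n_background_trials)
            ],
        )
        yield conn, trials


def _activity_seed(base_seed: int, trial_class: int, trial_index: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(trial_class), int(trial_index), 0xAC71])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


# -- HDF5 persistence -------------------------------------------------------

def save_connectivity(conn: Connectivity, path: str | Path, raster: ActivityRaster | None = None) -> None:
    """Write connectivity (and optionally one activity raster) to HDF5."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("presyn_ids", data=conn.presyn_ids, compression="gzip")
        ds.attrs["run_seed"] = conn.run_seed
        for key, val in conn.config.to_dict().items():
            fh.attrs[f"config_{key}"] = val
        if raster is not None:
            act = fh.create_dataset("activity", data=raster.values, compression="gzip")
            act.attrs["trial_type"] = raster.trial_type
            act.attrs["activity_seed"] = raster.activity_seed
            act.attrs["ensemble_order"] = raster.ensemble_order


def load_connectivity(path: str | Path) -> Connectivity:
    from .config import NetworkConfig

    with h5py.File(path, "r") as fh:
        ids = fh["presyn_ids"][...]
        run_seed = int(fh["presyn_ids"].attrs["run_seed"])
        cfg_kwargs = {
            key[len("config_"):]: val for key, val in fh.attrs.items() if key.startswith("config_")
        }
        cfg_kwargs["name"] = str(cfg_kwargs["name"])
        for int_field in ("T_pre", "N", "M", "T_post"):
            cfg_kwargs[int_field] = int(cfg_kwargs[int_field])
        config = NetworkConfig(**cfg_kwargs)
    return Connectivity(presyn_ids=ids, config=config, run_seed=run_seed)
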