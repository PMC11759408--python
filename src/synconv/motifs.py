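"""Census of synaptic groups and dendritic sequences on simulated neurons.

Groups are counted by sliding a window of Z/sigma synapses along each
neuron's input array one synapse at a time (windows running off the distal
end are not evaluated, mirroring the branch-point end-effect treatment):

* fully mixed      — at least one input from each of the M ensembles,
* stimulus-driven  — >= M ensemble inputs of any identity,
* noise            — >= M background inputs,
* any              — >= M active inputs of any kind.

Sequences are counted through pairwise step-adjacency structures: entry
(i, j) of X_t->t+1 is 1 iff synapse i is active at step t, synapse j at
step t+1, and position(j) - position(i) lies in [S, S+delta) (half-open, so
the per-step window measure is exactly delta). The number of M-input
sequences equals the grand sum of the product of the M-1 adjacency
matrices; :func:`census_sequences` evaluates the same product by vector
propagation, which is what makes the 4000 x 20,000 scale tractable.

Input arrays label each synapse with the ensemble identity (1..M) of an
ensemble-driven input, -1 for a background input, and 0 for silence; they
are derived jointly from a :class:`~synconv.network.Connectivity` and an
:class:`~synconv.network.ActivityRaster`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .config import NetworkConfig
from .network import ActivityRaster, Connectivity

__all__ = [
    "input_labels",
    "GroupCensus",
    "scan_groups",
    "classify_group_mixing",
    "build_step_adjacency",
    "count_sequences",
    "SequenceCensus",
    "census_sequences",
    "population_probability",
]


def input_labels(conn: Connectivity, raster: ActivityRaster, step: int = 0) -> np.ndarray:
    """Per-synapse input labels for one time step.

    Returns an int8 array (n_neurons, n_synapses): ensemble id 1..M where an
    ensemble-driven (+1) input arrives, -1 for background, 0 for silence.
    """
    act = raster.values[:, step]
    per_neuron = act[conn.presyn_ids]  # (n_neurons, n_synapses) in {+1,-1,0}
    labels = per_neuron.astype(np.int8, copy=True)
    drove = per_neuron == 1
    if np.any(drove):
        ens_id = (conn.presyn_ids[drove] // conn.config.N + 1).astype(np.int8)
        labels[drove] = ens_id
    return labels


def _window_sum(x: np.ndarray, w: int) -> np.ndarray:
    """Sliding-window sums of width w along the last axis (full windows only)."""
    c = np.cumsum(x, axis=-1, dtype=np.float32)
    out = c[..., w - 1 :].copy()
    out[..., 1:] -= c[..., :-w]
    return out


def _scan_groups_chunk(labels: np.ndarray, w: int, M: int, n_ens: int) -> dict[str, np.ndarray]:
    """Group census for one chunk of neurons; minimizes large temporaries."""
    ens_count = _window_sum(labels >= 1, w)
    bg_count = _window_sum(labels == -1, w)
    sd_win = ens_count >= M
    noise = (bg_count >= M).sum(axis=-1)
    bg_count += ens_count
    any_ = (bg_count >= M).sum(axis=-1)
    del bg_count

    # presence of each ensemble per window, accumulated in-place
    unique = np.zeros(ens_count.shape, dtype=np.int8)
    fm = None
    for m in range(1, n_ens + 1):
        pres = _window_sum(labels == m, w) > 0
        unique += pres
        if m <= M:
            fm = pres if fm is None else (fm & pres)
    fully_mixed = fm.sum(axis=-1) if M <= n_ens else np.zeros(labels.shape[0], dtype=np.int64)
    hist = np.stack(
        [((unique == k) & sd_win).sum(axis=-1) for k in range(1, M + 1)], axis=-1
    )
    return {
        "fully_mixed": np.asarray(fully_mixed, dtype=np.int64),
        "stimulus_driven": sd_win.sum(axis=-1).astype(np.int64),
        "noise": noise.astype(np.int64),
        "any": any_.astype(np.int64),
        "hist": hist.astype(np.int64),
    }


@dataclass(frozen=True)
class GroupCensus:
    """Per-neuron window counts for each group type at one group size M."""

    M: int
    fully_mixed: np.ndarray
    stimulus_driven: np.ndarray
    noise: np.ndarray
    any: np.ndarray
    # histogram over windows passing the stimulus-driven criterion, indexed
    # by the number of distinct ensembles present (1..M); shape (n_neurons, M)
    unique_ensemble_hist: np.ndarray


def scan_groups(
    labels: np.ndarray, config: NetworkConfig, M: int | None = None, batch: int = 512
) -> GroupCensus:
    """Count group motifs of size M in each neuron's input array.

    ``labels`` is (n_neurons, n_synapses) as produced by
    :func:`input_labels` (a single neuron may be passed as a 1-D array).
    All overlapping windows are counted; population probabilities use only
    the >= 1 indicator, so double counting is harmless.
    """
    M = config.M if M is None else M
    if M < 1:
        raise ValueError("M must be >= 1")
    labels = np.atleast_2d(np.asarray(labels))
    w = config.zone_synapses
    if labels.shape[1] < w:
        raise ValueError(f"input array shorter than one zone ({labels.shape[1]} < {w})")

    n_ens = config.M  # ensembles present in the raster
    chunks = [
        _scan_groups_chunk(labels[s : s + batch], w, M, n_ens)
        for s in range(0, labels.shape[0], batch)
    ]
    cat = {k: np.concatenate([c[k] for c in chunks]) for k in chunks[0]}
    return GroupCensus(
        M=M,
        fully_mixed=cat["fully_mixed"],
        stimulus_driven=cat["stimulus_driven"],
        noise=cat["noise"],
        any=cat["any"],
        unique_ensemble_hist=cat["hist"],
    )


def classify_group_mixing(group_labels) -> int:
    """Number of distinct ensembles represented in a stimulus-driven group.

    M distinct -> fully mixed; 1 -> homogeneous; in between -> partially
    mixed. ``group_labels`` holds the ensemble identities of the group's
    inputs (background/silent entries are ignored).
    """
    arr = np.asarray(group_labels)
    return int(np.unique(arr[arr >= 1]).size)


def build_step_adjacency(
    active_t: np.ndarray, active_t1: np.ndarray, config: NetworkConfig
) -> sparse.csr_matrix:
    """Pairwise spacing structure between consecutive time steps.

    Entry (i, j) is 1 iff synapse i is active at step t, synapse j at step
    t+1, and the positional offset j - i (in synapses) lies in the half-open
    spacing window [S/sigma, (S+delta)/sigma).
    """
    active_t = np.asarray(active_t, dtype=bool)
    active_t1 = np.asarray(active_t1, dtype=bool)
    if active_t.shape != active_t1.shape or active_t.ndim != 1:
        raise ValueError("step activity arrays must be 1-D and of equal length")
    lo, hi = config.spacing_offsets
    ii = np.flatnonzero(active_t)
    jj = np.flatnonzero(active_t1)
    rows, cols = [], []
    for i in ii:
        sel = jj[(jj >= i + lo) & (jj < i + hi)]
        rows.extend([i] * sel.size)
        cols.extend(sel.tolist())
    n = active_t.size
    data = np.ones(len(rows), dtype=np.int64)
    return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


def count_sequences(adjacencies: list[sparse.spmatrix]) -> int:
    """Total M-input sequences: grand sum of the adjacency chain product."""
    if len(adjacencies) < 1:
        raise ValueError("need at least one adjacency structure (M >= 2)")
    n = adjacencies[0].shape[0]
    for adj in adjacencies:
        if adj.shape != (n, n):
            raise ValueError("adjacency structures must share one synapse dimension")
    prod = adjacencies[0].tocsr(copy=True)
    for adj in adjacencies[1:]:
        prod = prod @ adj
    return int(prod.sum())


def _propagate(actives: list[np.ndarray], lo: int, hi: int) -> np.ndarray:
    """Chain-product sequence counts via vector propagation.

    ``actives`` is a list of (n_neurons, n_synapses) 0/1 arrays, one per
    step. Returns per-neuron sequence counts. Equivalent to summing the
    product of the step-adjacency matrices.
    """
    v = actives[0].astype(np.float32)
    n = v.shape[1]
    for a in actives[1:]:
        # predecessors of j are offsets d = j - i in [lo, hi); the window is
        # narrow (delta/sigma offsets), so shifted slice-adds beat a cumsum
        win = np.zeros_like(v)
        for d in range(lo, hi):
            if d < n:
                win[:, d:] += v[:, : n - d]
        v = win
        v *= a
    return v.sum(axis=-1).astype(np.int64)


@dataclass(frozen=True)
class SequenceCensus:
    """Per-neuron sequence counts for each class at one sequence length M."""

    M: int
    poss: np.ndarray
    noise: np.ndarray
    any: np.ndarray

    @property
    def gapfill(self) -> np.ndarray:
        return self.any - self.poss - self.noise


def census_sequences(
    conn: Connectivity,
    raster: ActivityRaster,
    M: int | None = None,
) -> SequenceCensus:
    """Count POSS / noise / any sequences of length M for every neuron.

    A POSS step requires an ensemble-driven input whose identity matches the
    ensemble scheduled at that step of the raster's stimulus order; noise
    steps require background inputs; "any" accepts either. Gap-fill counts
    follow by subtraction (any - POSS - noise). Only the first M raster
    steps are used.
    """
    M = conn.config.M if M is None else M
    if M < 2:
        raise ValueError("sequence length M must be >= 2")
    if raster.n_steps < M:
        raise ValueError(f"raster has {raster.n_steps} steps; need >= {M}")
    lo, hi = conn.config.spacing_offsets

    # With one eligible ensemble per step, a +1 at step t always carries the
    # identity scheduled at t, so the POSS class is exactly the +1 entries.
    poss, noise, any_ = [], [], []
    for t in range(M):
        g = raster.values[:, t][conn.presyn_ids]  # {+1,-1,0} per synapse
        poss.append(g == 1)
        noise.append(g == -1)
        any_.append(g != 0)
    return SequenceCensus(
        M=M,
        poss=_propagate(poss, lo, hi),
        noise=_propagate(noise, lo, hi),
        any=_propagate(any_, lo, hi),
    )


def population_probability(counts: np.ndarray) -> tuple[float, float]:
    """Fraction of neurons carrying >= 1 motif, with binomial standard error."""
    counts = np.asarray(counts)
    if counts.size < 1:
        raise ValueError("need counts for at least one neuron")
    q = float(np.mean(counts >= 1))
    se = float(np.sqrt(q * (1.0 - q) / counts.size))
    return q, se
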