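"""Closed-form probabilities of synaptic groups and dendritic sequences.

In a randomly connected feedforward network, the expected number of
connections from an ensemble of N presynaptic neurons onto one postsynaptic
neuron is pN, and the expected number landing inside a dendritic zone of
length Z is nu = pNZ/L. The probability that one zone receives at least one
connection from each of M co-active ensembles (a connectivity-based fully
mixed group) is approximately

    P_zone = (1 - e^-nu)^M,            P_neuron = 1 - (1 - P_zone)^kappa,

where kappa, the effective number of independent zones per neuron, lies
between L/Z (non-overlapping zones) and L/sigma (every synapse starts a
zone). The active variants replace pN by p_e * pN. For spatiotemporal
sequences, successive inputs must land within [S, S+delta) of the previous
one, giving an expected count of M-length perfect sequences

    E = pN * (pN * delta / L)^(M-1),    P_neuron = 1 - e^-E.

Stimulus-driven, noise, any, and gap-fill motifs follow from Poisson /
binomial tails and expectation chains over the same geometry; all of them
are validated against the Monte Carlo census in :mod:`synconv.motifs`.

The default ``kappa_mode`` is ``"zones"`` (kappa = L/Z), matching the
piriform-cortex worked example. Sequences are unidirectional by default;
``symmetric=True`` doubles the expectation (distal-to-proximal ordering is
then also accepted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .config import NetworkConfig

__all__ = [
    "ProbabilityResult",
    "p_background",
    "prob_fully_mixed_group",
    "prob_stimulus_driven_group",
    "prob_noise_group",
    "prob_any_group",
    "prob_ordered_sequence",
    "prob_noise_sequence",
    "prob_any_sequence",
    "prob_gapfill_sequence",
    "expected_interrupted_zones",
    "fit_kappa",
    "resolve_kappa",
    "motif_probability",
    "GROUP_MOTIFS",
    "SEQUENCE_MOTIFS",
]

GROUP_MOTIFS = ("cFMG", "aFMG", "cSDG", "aSDG", "noise_group", "any_group")
SEQUENCE_MOTIFS = ("cPOSS", "aPOSS", "noise_seq", "gapfill_seq", "any_seq")


@dataclass(frozen=True)
class ProbabilityResult:
    """Per-zone probability, per-neuron probability, and expected count."""

    per_zone: float | None
    per_neuron: float
    expectation: float | None = None


def p_background(R: float, D: float) -> float:
    """Probability of a synapse receiving a background hit in window D.

    Poisson background at rate R gives 1 - e^(-R*D); depends on R and D only
    through their product.
    """
    if R < 0 or D < 0:
        raise ValueError(f"R and D must be nonnegative, got R={R}, D={D}")
    return -math.expm1(-R * D)


def resolve_kappa(config: NetworkConfig, kappa_mode: str | float = "zones") -> float:
    """Translate a kappa mode into a numeric effective zone count.

    ``"zones"`` -> L/Z, ``"synapses"`` -> L/sigma, a number -> used as a
    fitted kappa (must lie within [L/Z, L/sigma]).
    """
    lo, hi = config.L / config.Z, config.L / config.sigma
    if kappa_mode == "zones":
        return lo
    if kappa_mode == "synapses":
        return hi
    try:
        kappa = float(kappa_mode)
    except (TypeError, ValueError):
        raise ValueError(f"kappa_mode must be 'zones', 'synapses', or numeric, got {kappa_mode!r}")
    if not (lo - 1e-9 <= kappa <= hi + 1e-9):
        raise ValueError(f"fitted kappa={kappa} outside [L/Z, L/sigma] = [{lo}, {hi}]")
    return kappa


def _per_neuron_from_zone(p_zone: float, kappa: float) -> float:
    # 1 - (1 - p)^kappa, computed stably for tiny p
    return -math.expm1(kappa * math.log1p(-min(p_zone, 1.0)))


def prob_fully_mixed_group(
    config: NetworkConfig,
    M: int | None = None,
    *,
    active: bool = False,
    kappa_mode: str | float = "zones",
) -> ProbabilityResult:
    """Probability of a (connectivity-based or active) fully mixed group.

    At least one input from each of the M ensembles within one zone of
    length Z; the active variant requires the inputs to fire (p_e).
    """
    M = config.M if M is None else M
    if M < 1:
        raise ValueError("M must be >= 1")
    pe = config.p_e if active else 1.0
    nu = config.p * pe * config.N * config.Z / config.L
    p_zone = (-math.expm1(-nu)) ** M
    kappa = resolve_kappa(config, kappa_mode)
    return ProbabilityResult(p_zone, _per_neuron_from_zone(p_zone, kappa))


def prob_stimulus_driven_group(
    config: NetworkConfig,
    M: int | None = None,
    *,
    active: bool = False,
    kappa_mode: str | float = "zones",
) -> ProbabilityResult:
    """Probability of a stimulus-driven group: >= M ensemble inputs in a zone.

    The M*N ensemble neurons contribute a Poisson-distributed number of
    connections to a zone with rate lambda = M*p*N*Z/L (times p_e for the
    active variant); the zone probability is the upper tail P(X >= M).
    """
    M = config.M if M is None else M
    if M < 1:
        raise ValueError("M must be >= 1")
    pe = config.p_e if active else 1.0
    lam = M * config.p * pe * config.N * config.Z / config.L
    p_zone = float(stats.poisson.sf(M - 1, lam))
    kappa = resolve_kappa(config, kappa_mode)
    return ProbabilityResult(p_zone, _per_neuron_from_zone(p_zone, kappa))


def prob_noise_group(
    config: NetworkConfig,
    M: int | None = None,
    *,
    kappa_mode: str | float = "zones",
    poisson_approx: bool = False,
) -> ProbabilityResult:
    """Probability of a noise group: >= M background hits within one zone.

    The zone holds n = Z/sigma synapses, each hit independently with
    probability q = 1 - e^(-RD); the zone probability is the binomial tail
    P(X >= M). ``poisson_approx=True`` substitutes the Poisson tail with
    rate n*q (documented approximation; the binomial form is the default
    because Z/sigma is a small finite synapse count).
    """
    M = config.M if M is None else M
    if M < 1:
        raise ValueError("M must be >= 1")
    n = config.zone_synapses
    q = config.p_bg
    if poisson_approx:
        p_zone = float(stats.poisson.sf(M - 1, n * q))
    else:
        p_zone = float(stats.binom.sf(M - 1, n, q))
    kappa = resolve_kappa(config, kappa_mode)
    return ProbabilityResult(p_zone, _per_neuron_from_zone(p_zone, kappa))


def prob_any_group(
    config: NetworkConfig,
    M: int | None = None,
    *,
    kappa_mode: str | float = "zones",
) -> ProbabilityResult:
    """Probability of any group: >= M active inputs of any kind in a zone.

    Combines the ensemble-driven expectation M*p*p_e*N*Z/L with the
    background expectation (Z/sigma)*(1 - e^(-RD)) and takes the Poisson
    upper tail at M. Active inputs are implied: background is active by
    definition and ensemble inputs fire with p_e.
    """
    M = config.M if M is None else M
    if M < 1:
        raise ValueError("M must be >= 1")
    lam = (
        M * config.p * config.p_e * config.N * config.Z / config.L
        + config.zone_synapses * config.p_bg
    )
    p_zone = float(stats.poisson.sf(M - 1, lam))
    kappa = resolve_kappa(config, kappa_mode)
    return ProbabilityResult(p_zone, _per_neuron_from_zone(p_zone, kappa))


def _seq_result(expectation: float) -> ProbabilityResult:
    return ProbabilityResult(None, -math.expm1(-expectation), expectation)


def prob_ordered_sequence(
    config: NetworkConfig,
    M: int | None = None,
    *,
    active: bool = False,
    symmetric: bool = False,
) -> ProbabilityResult:
    """Expected count and probability of a perfectly ordered stimulus sequence.

    E = pN * (pN * delta / L)^(M-1), with pN replaced by p_e*pN for the
    active variant; ``symmetric=True`` doubles E (both spatial orderings
    accepted). P_neuron = 1 - e^-E by the Poisson approximation.
    """
    M = config.M if M is None else M
    if M < 1:
        raise ValueError("M must be >= 1")
    pe = config.p_e if active else 1.0
    pN = config.p * pe * config.N
    E = pN * (pN * config.delta / config.L) ** (M - 1)
    if symmetric:
        E *= 2.0
    return _seq_result(E)


def prob_noise_sequence(config: NetworkConfig, M: int | None = None) -> ProbabilityResult:
    """Expected count/probability of a sequence made of background hits alone.

    The chain starts at any of L/sigma synapses with per-step success
    probability q = 1 - e^(-RD), and each subsequent step must land on one of
    the delta/sigma synapses of the spacing window:
    E = (L/sigma)*q * ((delta/sigma)*q)^(M-1).
    """
    M = config.M if M is None else M
    if M < 1:
        raise ValueError("M must be >= 1")
    q = config.p_bg
    start = (config.L / config.sigma) * q
    step = (config.delta / config.sigma) * q
    return _seq_result(start * step ** (M - 1))


def prob_any_sequence(
    config: NetworkConfig, M: int | None = None, *, active: bool = True
) -> ProbabilityResult:
    """Expected count/probability of a sequence of ensemble and/or noise inputs.

    Per step, the spacing window may be satisfied either by the correct
    ensemble (expectation p*p_e*N*delta/L) or by background
    ((delta/sigma)*q); the first step may start from the first ensemble
    (p*p_e*N anywhere) or from background ((L/sigma)*q).
    """
    M = config.M if M is None else M
    if M < 1:
        raise ValueError("M must be >= 1")
    pe = config.p_e if active else 1.0
    q = config.p_bg
    start = config.p * pe * config.N + (config.L / config.sigma) * q
    step = config.p * pe * config.N * config.delta / config.L + (config.delta / config.sigma) * q
    return _seq_result(start * step ** (M - 1))


def prob_gapfill_sequence(
    config: NetworkConfig, M: int | None = None, *, active: bool = True
) -> ProbabilityResult:
    """Expected count/probability of gap-fill sequences (mixed provenance).

    Gap-fills are sequences with at least one ensemble and at least one
    background input: E_gapfill = E_any - E_POSS - E_noise.
    """
    M = config.M if M is None else M
    e_any = prob_any_sequence(config, M, active=active).expectation
    e_poss = prob_ordered_sequence(config, M, active=active).expectation
    e_noise = prob_noise_sequence(config, M).expectation
    return _seq_result(max(e_any - e_poss - e_noise, 0.0))


def expected_interrupted_zones(Z: float, B: float, L: float) -> float:
    """Expected number of zones that begin too close to a branch point.

    A neuron with B branches loses a region of length Z per branch out of
    total length L: E_end = Z*B/L.
    """
    if Z <= 0 or B <= 0 or L <= 0:
        raise ValueError("Z, B, and L must be positive")
    return Z * B / L


_GROUP_FUNCS = {
    "cFMG": lambda cfg, M, km: prob_fully_mixed_group(cfg, M, active=False, kappa_mode=km),
    "aFMG": lambda cfg, M, km: prob_fully_mixed_group(cfg, M, active=True, kappa_mode=km),
    "cSDG": lambda cfg, M, km: prob_stimulus_driven_group(cfg, M, active=False, kappa_mode=km),
    "aSDG": lambda cfg, M, km: prob_stimulus_driven_group(cfg, M, active=True, kappa_mode=km),
    "noise_group": lambda cfg, M, km: prob_noise_group(cfg, M, kappa_mode=km),
    "any_group": lambda cfg, M, km: prob_any_group(cfg, M, kappa_mode=km),
}

_SEQ_FUNCS = {
    "cPOSS": lambda cfg, M, sym: prob_ordered_sequence(cfg, M, active=False, symmetric=sym),
    "aPOSS": lambda cfg, M, sym: prob_ordered_sequence(cfg, M, active=True, symmetric=sym),
    "noise_seq": lambda cfg, M, sym: prob_noise_sequence(cfg, M),
    "gapfill_seq": lambda cfg, M, sym: prob_gapfill_sequence(cfg, M),
    "any_seq": lambda cfg, M, sym: prob_any_sequence(cfg, M),
}


def motif_probability(
    config: NetworkConfig,
    motif: str,
    M: int | None = None,
    *,
    kappa_mode: str | float = "zones",
    symmetric: bool = False,
) -> ProbabilityResult:
    """Dispatch on motif name (one of GROUP_MOTIFS or SEQUENCE_MOTIFS)."""
    if motif in _GROUP_FUNCS:
        return _GROUP_FUNCS[motif](config, M, kappa_mode)
    if motif in _SEQ_FUNCS:
        return _SEQ_FUNCS[motif](config, M, symmetric)
    raise ValueError(f"unknown motif {motif!r}; valid: {GROUP_MOTIFS + SEQUENCE_MOTIFS}")


def fit_kappa(
    m_values: np.ndarray,
    probabilities: np.ndarray,
    config: NetworkConfig,
    motif: str = "cFMG",
) -> float:
    """Least-squares fit of the effective zone count kappa to simulation data.

    Given Monte Carlo per-neuron probabilities at several group sizes M,
    finds the kappa in [L/Z, L/sigma] minimizing the squared deviation of
    1 - (1 - P_zone(M))^kappa from the estimates. Requires at least two
    points with probabilities strictly inside (0, 1).
    """
    m_values = np.asarray(m_values, dtype=int)
    probabilities = np.asarray(probabilities, dtype=float)
    usable = (probabilities > 0.0) & (probabilities < 1.0)
    if usable.sum() < 2:
        raise ValueError(
            "kappa fit needs >= 2 (M, probability) points strictly inside (0, 1); "
            f"got {int(usable.sum())}"
        )
    ms, qs = m_values[usable], probabilities[usable]
    p_zone = np.array(
        [motif_probability(config, motif, int(m), kappa_mode="zones").per_zone for m in ms]
    )
    lo, hi = config.L / config.Z, config.L / config.sigma

    def loss(kappa: float) -> float:
        pred = -np.expm1(kappa * np.log1p(-p_zone))
        return float(np.sum((pred - qs) ** 2))

    res = optimize.minimize_scalar(loss, bounds=(lo, hi), method="bounded")
    return float(res.x)
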