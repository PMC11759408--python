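# Methods

## Model and scope

The package analyses a two-layer feedforward network. A presynaptic
population of `T_pre` neurons contains `M` ensembles of `N` co-active
neurons (occupying the first `M·N` identifiers); every other neuron only
ever participates in Poisson background activity at rate `R` (Hz). Each
postsynaptic neuron collapses its dendritic arbor into a single notional
cable of length `L` (µm) discretized at the inter-synapse interval `σ`
(µm); every synapse draws its presynaptic source independently and
uniformly, with replacement, so one axon may form several synapses and
the expected number of connections from one ensemble is `pN`. All
synapses are electrotonically equivalent — there is no distance- or
activity-dependent wiring, because pure randomness is the hypothesis
under test. Branched morphologies enter only through the end-effect
expectation `E_end = Z·B/L` for a neuron with `B` branches.

Six built-in configurations pair hippocampal (`p = 0.05`,
`T_pre = 400,000`) and cortical (`p = 0.2`, `T_pre = 100,000`)
connectivity statistics with the spatiotemporal scales of three dendritic
mechanisms: chemical (`Z = 10` µm, `D = 2` s), CICR (`Z = 10` µm,
`D = 0.2` s), and electrical (`Z = 50` µm, `D = 4` ms). In all of them
`L = 10,000` µm and `σ = 0.5` µm, so `p·T_pre = L/σ = 20,000` synapses
per neuron; `L` and `σ` are fixed at these values precisely because they
make the discretization identity hold for every configuration. Ensemble
sizes default to `N = 100` for group analyses and `N = 1000` for sequence
analyses; the participation probability is `p_e = 0.8`; the postsynaptic
population size `T_post` (used only for interpreting per-neuron
probabilities as population counts) is a free parameter defaulting to
400,000.

## Probability theory

Group motifs are governed by the per-zone expectation `ν = pNZ/L`
(`ν = p·p_e·N·Z/L` for the active variants):

* fully mixed:  `P_zone = (1 − e^(−ν))^M`;
* stimulus-driven: Poisson upper tail `P(X ≥ M)` with rate `M·p·N·Z/L`;
* noise: binomial tail over the `Z/σ` synapses of a zone with per-synapse
  probability `p_bg = 1 − e^(−RD)` (a Poisson-tail approximation is
  available behind a flag but the binomial form is the default, because
  `Z/σ` is a small finite count);
* any: Poisson tail with the combined rate
  `M·p·p_e·N·Z/L + (Z/σ)·p_bg`.

Per-neuron probabilities follow as `1 − (1 − P_zone)^κ`, where the
effective number of independent zones κ is bounded by `L/Z`
(non-overlapping zones) and `L/σ` (every synapse starts a zone). The
default reporting mode uses κ = L/Z, matching the piriform worked
example; `fit_kappa` recovers a configuration's effective κ from
simulation estimates by bounded least squares. The overlap dependence
between zones is deliberately not modelled exactly — the κ band plus the
fit stand in for it.

Sequence motifs use expectation chains with the per-step window measure
Δ: `E_POSS = pN·(pNΔ/L)^(M−1)`,
`E_noise = (L/σ)·p_bg·((Δ/σ)·p_bg)^(M−1)`, and the "any" chain combines
the ensemble and background contributions per step. Gap-fill sequences
(partly ensemble, partly background) are obtained by subtraction
`E_any − E_POSS − E_noise`. Per-neuron probabilities are `1 − e^(−E)`.
Sequences are unidirectional by default; a symmetric variant doubles the
expectation. The stimulus-driven/noise/any/gap-fill forms are validated
against the Monte Carlo census rather than against any printed formula,
and the census is the arbiter wherever the two could disagree.

## Synthetic data and the census

Activity rasters code each presynaptic neuron and time step as `+1`
(ensemble-driven), `−1` (background hit, probability `p_bg` per window),
or `0`. Group rasters have one step with all ensembles eligible; sequence
rasters have one eligible ensemble per step (at most 9 steps), with
neurons of inactive ensembles falling back to the background pool. An
ensemble neuron that fails its `p_e` draw is silent for that step rather
than reverting to background — the cleaner reading of "participates in
ensemble activity". Within a batch of runs the connectivity seed changes
per run while the activity seed is shared, so runs differ only in wiring.

The group census slides a `Z/σ`-synapse window one synapse at a time;
windows that would run off the distal end are not evaluated (mirroring
the end-effect treatment). All overlapping windows are counted, but
population probabilities use only the ≥1-occurrence indicator, so double
counting is harmless. The sequence census builds step-adjacency
structures whose (i, j) entry marks an active synapse j lying a spacing
`[S, S+Δ)` *downstream* of an active synapse i in the previous step; the
spacing interval is half-open so that the per-step window measure is
exactly Δ, consistent with `ν = pNΔ/L`. Sequence counts are the grand
sum of the adjacency chain product, evaluated by vector propagation
(mathematically identical, and exact — path counts are small integers);
both routes, plus naive depth-first enumeration, are cross-checked on
random toy instances.

What the generator does *not* emulate: correlated background activity,
synaptic weights, electrotonic attenuation, structured (distance-biased)
wiring, and trial-to-trial ensemble identity drift. Passing tests
therefore speak to the statistics of random convergence, not to any
particular biological circuit's deviations from randomness.

## Activation models

Grouped computation applies `ω(g) = 1 − 10^(−(g/M_ref)^ρ)` to the number
of active inputs in each sliding zone and reports the zone-normalized sum
`(σ/Z)·Σ ω` as a somatic proxy. The base of 10 pins `ω(M_ref) = 0.9`
for every exponent ρ, so ρ only controls how strongly sub-group counts
are suppressed. ρ = 2 is the weak regime; the strong value is not pinned
by theory and defaults to ρ = 8, with the meaningful claim being
CSD/CSD^C separability rather than the specific exponent.

Sequential computation uses the recurrence

    Q(t,x) = γ·Q(t−1,x) + δ(t,x) + ψ(δ(t,x) · Σ_{x′} ((1 + γ·Q(t−1,x′))^η − 1))

with the sum over synapses a spacing `[S, S+Δ)` upstream of x and
`ψ(y) = 2·Vmax·(sigmoid(c·y) − ½)`. This placement of δ(t,x) — gating
the sequential term multiplicatively — is the reading that satisfies
both structural constraints (no input at x ⇒ no sequential boost;
no prior activation ⇒ ψ(0) = 0). The four parameters (γ, η, c, Vmax) are
not hard-coded: a deterministic grid search tunes them so that an
isolated perfect sequence on a bare dendrite reaches a local selectivity
of ~0.8 over the standard pattern set, rejecting degenerate solutions in
which the ordered response fails to beat the reversal.

Pattern sets: all 6 permutations for M = 3; for M ≥ 4, 24 permutations
sampled at uniform stride `M!/24` from lexicographic order, so the first
pattern is always the identity and, at M = 4, the last is the full
reversal. Selectivity is `(A_seq − A_mean)/A_max`, undefined (NaN) when
`A_max ≤ 0`. Background subtraction — a proxy for precise EI balance —
subtracts each neuron's background-only trial-average from its stimulus
trial-averages before recomputing selectivity.

Cohort separability is operationalized as the existence of a single
threshold on trial-averaged activation reaching a balanced accuracy of
0.95, reported alongside the AUC and a one-sided Mann-Whitney U test.
The CSD comparison uses a random subsample of the complement (the
complement distribution is exchangeable, so subsampling is unbiased).
The CFM comparison is made against the partially-mixed/homogeneous group
carriers in its complement: these neurons have activation statistics
identical to CFM neurons and are the reason fully mixed convergence
cannot be identified from somatic responses; testing against the full
complement would instead measure an arbitrary mixture weight between
confusable and trivially different neurons.

## Reaction-diffusion models

Both chemistry models live on a 100 µm cable with 0.5 µm voxels,
zero-flux boundaries, and operator splitting: a Heun reaction substep
followed by a Crank–Nicolson diffusion/advection substep (batched
tridiagonal solves across stimulus patterns). Stimuli deposit Ca over a
fixed 2 µm footprint with a fixed total amount, making the delivered
input independent of grid resolution; halving the voxel size changes the
response integral by under 2%.

The Ca–calmodulin chain binds four Ca ions in sequential mass-action
steps formulated as fluxes, so total calmodulin is conserved exactly.
Because the fully loaded state is effectively fourth-order in local Ca,
clustered inputs (2 µm spacing) outproduce the same total Ca delivered
at 10 µm spacing.

The bistable switch couples three species: Ca (input, fast clearance),
the switch molecule A (D = 5 µm²/s), and the inhibitor B (D = 2 µm²/s).
A is produced at Ca input sites with a gain `1 + G·A²/(K_g² + A²)` in the
resident A concentration — an input landing inside the still-warm halo of
a previous input is amplified, which is what compounds ordered inputs —
and self-activates through a steep Hill term whose threshold sits well
above normal sequence operation (the bistable core: a broad
supra-threshold Ca pulse latches A high until B accumulates and resets
it). A small directional advection of A (1.5 µm/s, matching the 3 µm /
2 s stimulus progression) represents directional intracellular transport
and breaks the mirror symmetry of pure diffusion; without it the ordered
pattern and its spatial reversal would be dynamically indistinguishable
and the response could not increase monotonically with the pattern's
directionality (Q-score = slope × R² of the pattern regressed on perfect
ordering). All rate constants are synthetic — chosen by the tuning sweeps
documented in the parameter dataclasses to satisfy the property suite
(ordered > scrambled, monotone response-vs-Q trend, far-ectopic
robustness beyond two diffusion lengths `λ = √(D_A/k_deg) ≈ 4 µm`, deeper
in-zone ectopic dips for M = 4 than M = 7) — and are labelled as such.

## Scales, seeds, and numerical choices

Monte Carlo probability comparisons run at 4000 postsynaptic neurons per
configuration (one conventional run); agreement is assessed against the
analytic κ band or within 3 binomial standard errors of the κ-fitted or
Poisson prediction. The cohort analyses screen 12,000–24,000 neurons for
group cohorts and 8,000 neurons (at M = 3, where perfect sequential
connectivity has probability ~3×10⁻³) for PSCSD cohorts; the package
scales to the full 400,000-neuron screening by raising `n_runs`, and the
M = 4 cohort (probability ~2×10⁻⁵) simply needs that larger screen.
Sequence-selectivity trials share per-trial randomness across stimulus
patterns so that pattern comparisons are paired. All randomness derives
from user-supplied integer seeds through `numpy` `SeedSequence` spawning;
identical seeds give bit-identical outputs. Reaction-diffusion
integrations use dt = 10–20 ms against reaction timescales of ≥ 50 ms.

## Known limitations

* The analytic "any group" tail treats the mixed ensemble/background
  count as Poisson; for very small zones the binomial correction to the
  background part is visible, which is why the census is the arbiter.
* κ is descriptive, not derived: it absorbs zone-overlap dependence into
  one fitted number.
* The abstract activation models have arbitrary units; only ordinal
  statements (separability, rank tests, selectivity changes) are
  meaningful across parameter sets.
* The bistable-switch parameters are a synthetic set satisfying the
  documented properties, not a transcription of any published model; the
  directional-transport term is a modelling choice with a biophysical
  rationale, not a fitted mechanism.
* Electrical-compartment modelling (channel kinetics, EPSP propagation)
  is out of scope; the electrical configurations enter only through
  their spatiotemporal scales.
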