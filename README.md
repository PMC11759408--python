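# synconv

Theory and simulation of **synaptic convergence in randomly connected
feedforward networks**: how likely is it that axonal projections from
co-active neural ensembles land together — as *groups* within a short
dendritic zone, or as spatiotemporally ordered *sequences* — on a single
postsynaptic neuron, and what does a dendrite's nonlinear machinery make
of such convergence?

The package is aimed at computational neuroscientists studying dendritic
computation, synaptic clustering, and network connectivity statistics. It
combines:

1. **Closed-form probability theory.** With connection probability `p`,
   ensembles of `N` neurons, and a collapsed dendrite of length `L`
   discretized at the inter-synapse interval `σ`, the expected number of
   inputs from one ensemble in a zone of length `Z` is `ν = pNZ/L`, and
   the probability that a neuron carries a *fully mixed group* — at least
   one input from each of `M` co-active ensembles somewhere on its
   arbor — is

       P_cFMG ≈ 1 − (1 − (1 − e^(−ν))^M)^κ,   κ ∈ [L/Z, L/σ],

   where κ is the effective number of independent zones. For ordered
   sequences with spacing window `[S, S+Δ)`, the expected number of
   perfect `M`-length sequences is `E = pN·(pNΔ/L)^(M−1)` and
   `P_cPOSS ≈ 1 − e^(−E)`. Stimulus-driven, noise, any, and gap-fill
   motifs follow from Poisson/binomial tails and expectation chains, and
   background activity enters through `p_bg = 1 − e^(−RD)`.
2. **Monte Carlo connectivity simulation.** Random wiring of
   presynaptic axons onto 20,000-synapse dendrites, `{+1, −1, 0}`
   activity rasters with ensemble and Poisson-background structure, a
   sliding-window group census, and matrix-product sequence counting —
   the independent check on every formula above.
3. **Dendritic activation models.** A saturating group nonlinearity
   `ω(g) = 1 − 10^(−(g/M)^ρ)` and a spatiotemporal recurrence for
   sequence selectivity, with neuron-level selectivity
   `(A_seq − A_mean)/A_max` over a standard permutation set.
4. **Reaction-diffusion chemistry.** A Ca–calmodulin binding chain
   (grouped selectivity) and a bistable-switch system with inhibitory
   feedback (sequence selectivity, ectopic-input robustness) on a 1-D
   dendritic cable.

Six built-in network configurations cover hippocampal and cortical
statistics for chemical, CICR, and electrical dendritic mechanisms.

## Worked example

The mitral-cell projection from the olfactory bulb to piriform cortex is
approximately random, with `pN ≈ 1.28` expected connections per
glomerular ensemble onto a 2000 µm apical arbor:

```python
from synconv import NetworkConfig, analytic

pir = NetworkConfig(name="piriform", p=0.0064, T_pre=1_000_000, R=0.0,
                    D=1.0, Z=50.0, S=10.0, delta=5.0, L=2000.0, N=200, M=4)
print(f"P_cFMG(Z=50) = {analytic.prob_fully_mixed_group(pir).per_neuron:.3g}")
print(f"P_cSDG(Z=50) = {analytic.prob_stimulus_driven_group(pir).per_neuron:.3g}")
print(f"P_cPOSS      = {analytic.prob_ordered_sequence(pir.replace(Z=10.0)).per_neuron:.3g}")
```

prints

```
P_cFMG(Z=50) = 3.93e-05
P_cSDG(Z=50) = 0.000404
P_cPOSS      = 4.19e-08
```

i.e. in a population of ~500,000 piriform neurons, about 20 neurons
receive grouped projections from four specific glomerular ensembles
within a 50 µm zone (and relaxing ensemble uniqueness raises that
tenfold), while a perfectly ordered four-step sequence is expected in
only ~0.02 neurons per hemisphere — grouped convergence is plausible
under pure randomness, sequential convergence needs larger ensembles.

The same quantities can be estimated by brute-force simulation and
compared against the κ-band:

```bash
synconv figure2 --config hippo-elec --m-range 3:5 --n-neurons 4000 --seed 1 --out out/
synconv figure7 --m 3 --n-runs 2 --seed 1 --out out/
```

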