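import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synconv import analytic
from synconv.config import builtin_config


class TestBackgroundProbability:
    def test_zero_rate(self):
        assert analytic.p_background(0.0, 2.0) == 0.0

    def test_closed_form(self):
        assert analytic.p_background(0.01, 2.0) == pytest.approx(1 - math.exp(-0.02), rel=1e-12)

    def test_depends_only_on_rate_window_product(self):
        assert analytic.p_background(0.01, 2.0) == pytest.approx(
            analytic.p_background(0.1, 0.2), rel=1e-12
        )

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            analytic.p_background(-0.1, 1.0)


class TestPiriformWorkedExamples:
    """Olfactory-bulb projections to piriform cortex: pN=1.28, L=2000, M=4."""

    def test_fully_mixed(self, piriform_config):
        assert analytic.prob_fully_mixed_group(piriform_config).per_neuron == pytest.approx(
            3.93e-5, rel=5e-3
        )
        z10 = piriform_config.replace(Z=10.0)
        assert analytic.prob_fully_mixed_group(z10).per_neuron == pytest.approx(3.31e-7, rel=5e-3)

    def test_stimulus_driven(self, piriform_config):
        assert analytic.prob_stimulus_driven_group(piriform_config).per_neuron == pytest.approx(
            4.04e-4, rel=5e-3
        )
        z10 = piriform_config.replace(Z=10.0)
        assert analytic.prob_stimulus_driven_group(z10).per_neuron == pytest.approx(
            3.51e-6, rel=5e-3
        )

    def test_ordered_sequence(self, piriform_config):
        assert analytic.prob_ordered_sequence(piriform_config).per_neuron == pytest.approx(
            4.19e-8, rel=5e-3
        )


class TestGroupIdentities:
    def test_active_equals_connectivity_at_full_participation(self):
        cfg = builtin_config("cortex-chem", p_e=1.0)
        for M in (2, 4):
            a = analytic.prob_fully_mixed_group(cfg, M, active=True)
            c = analytic.prob_fully_mixed_group(cfg, M, active=False)
            assert a.per_neuron == pytest.approx(c.per_neuron, rel=1e-12)

    def test_single_ensemble_group_definitions_coincide(self):
        cfg = builtin_config("hippo-elec")
        fmg = analytic.prob_fully_mixed_group(cfg, 1).per_neuron
        sdg = analytic.prob_stimulus_driven_group(cfg, 1).per_neuron
        assert fmg == pytest.approx(sdg, rel=1e-6)

    def test_no_ensemble_axons(self):
        cfg = builtin_config("hippo-elec").replace(N=1, p=0.0)
        assert analytic.prob_fully_mixed_group(cfg, 4).per_neuron == 0.0

    def test_cicr_and_chem_share_group_probabilities(self):
        """Same zone length -> identical connectivity-based group curves."""
        for pair in (("hippo-chem", "hippo-CICR"), ("cortex-chem", "cortex-CICR")):
            a, b = (builtin_config(n) for n in pair)
            for M in range(2, 6):
                assert analytic.prob_fully_mixed_group(a, M).per_neuron == pytest.approx(
                    analytic.prob_fully_mixed_group(b, M).per_neuron, rel=1e-12
                )

    def test_same_rate_window_product_noise_curves(self):
        """hippo-chem and cortex-CICR have equal R*D, hence equal noise groups."""
        a, b = builtin_config("hippo-chem"), builtin_config("cortex-CICR")
        for M in range(2, 7):
            assert analytic.prob_noise_group(a, M).per_neuron == pytest.approx(
                analytic.prob_noise_group(b, M).per_neuron, rel=1e-12
            )


class TestSequenceFamilies:
    def test_single_input_sequence(self):
        cfg = builtin_config("hippo-CICR", N=1000)
        res = analytic.prob_ordered_sequence(cfg, 1)
        assert res.per_neuron == pytest.approx(1 - math.exp(-cfg.p * cfg.N), rel=1e-12)

    def test_symmetric_doubles_expectation(self):
        cfg = builtin_config("hippo-CICR", N=1000)
        for M in (2, 4):
            uni = analytic.prob_ordered_sequence(cfg, M).expectation
            sym = analytic.prob_ordered_sequence(cfg, M, symmetric=True).expectation
            assert sym == pytest.approx(2 * uni, rel=1e-12)

    def test_no_background_collapses_families(self):
        cfg = builtin_config("hippo-CICR", N=1000, R=0.0)
        for M in (2, 4):
            assert analytic.prob_noise_sequence(cfg, M).per_neuron == 0.0
            assert analytic.prob_gapfill_sequence(cfg, M).per_neuron == 0.0
            any_ = analytic.prob_any_sequence(cfg, M).per_neuron
            poss = analytic.prob_ordered_sequence(cfg, M, active=True).per_neuron
            assert any_ == pytest.approx(poss, rel=1e-9)

    def test_gapfill_bounded_by_any(self):
        for name in ("hippo-CICR", "cortex-chem", "cortex-elec"):
            cfg = builtin_config(name, N=1000)
            for M in range(2, 6):
                gap = analytic.prob_gapfill_sequence(cfg, M).per_neuron
                any_ = analytic.prob_any_sequence(cfg, M).per_neuron
                assert 0.0 <= gap <= any_ + 1e-15

    def test_noise_group_zero_without_background(self):
        cfg = builtin_config("hippo-elec", R=0.0)
        for M in range(1, 6):
            assert analytic.prob_noise_group(cfg, M).per_neuron == 0.0


class TestEndEffects:
    def test_pyramidal_and_purkinje(self):
        assert analytic.expected_interrupted_zones(10, 50, 10_000) == pytest.approx(0.05)
        assert analytic.expected_interrupted_zones(10, 900, 7_800) == pytest.approx(1.1538, rel=1e-3)

    def test_single_branch(self):
        assert analytic.expected_interrupted_zones(10, 1, 2000) == pytest.approx(10 / 2000)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            analytic.expected_interrupted_zones(0, 50, 1000)


class TestMonotonicity:
    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        M=st.integers(2, 7),
        scale=st.floats(1.05, 2.0),
        motif=st.sampled_from(["cFMG", "cSDG", "aFMG", "cPOSS", "any_group"]),
    )
    def test_increasing_in_ensemble_size(self, M, scale, motif):
        cfg = builtin_config("hippo-CICR", N=500)
        bigger = cfg.replace(N=int(cfg.N * scale))
        p_small = analytic.motif_probability(cfg, motif, M).per_neuron
        p_big = analytic.motif_probability(bigger, motif, M).per_neuron
        assert p_big >= p_small - 1e-15

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(M=st.integers(1, 7), motif=st.sampled_from(["cFMG", "cSDG", "noise_group", "cPOSS"]))
    def test_decreasing_in_motif_size(self, M, motif):
        cfg = builtin_config("cortex-CICR", N=100)
        p_m = analytic.motif_probability(cfg, motif, M).per_neuron
        p_m1 = analytic.motif_probability(cfg, motif, M + 1).per_neuron
        assert p_m1 <= p_m + 1e-15

    def test_kappa_upper_bound_dominates(self):
        for name in ("hippo-elec", "cortex-chem"):
            cfg = builtin_config(name)
            for M in range(2, 6):
                lo = analytic.prob_fully_mixed_group(cfg, M, kappa_mode="zones").per_neuron
                hi = analytic.prob_fully_mixed_group(cfg, M, kappa_mode="synapses").per_neuron
                assert hi >= lo


class TestKappaFit:
    def test_recovers_generating_kappa(self):
        cfg = builtin_config("hippo-elec")
        for kappa_true in (cfg.L / cfg.Z, 5 * cfg.L / cfg.Z):
            ms = np.arange(2, 7)
            qs = np.array([
                analytic.prob_fully_mixed_group(cfg, int(m), kappa_mode=kappa_true).per_neuron
                for m in ms
            ])
            fitted = analytic.fit_kappa(ms, qs, cfg)
            assert fitted == pytest.approx(kappa_true, rel=1e-3)

    def test_fit_respects_bounds(self):
        cfg = builtin_config("hippo-elec")
        ms = np.array([2, 3, 4])
        qs = np.array([0.9, 0.5, 0.1])  # arbitrary but in (0,1)
        fitted = analytic.fit_kappa(ms, qs, cfg)
        assert cfg.L / cfg.Z <= fitted <= cfg.L / cfg.sigma

    def test_degenerate_data_rejected(self):
        cfg = builtin_config("hippo-elec")
        with pytest.raises(ValueError):
            analytic.fit_kappa(np.array([2, 3]), np.array([0.0, 0.0]), cfg)
        with pytest.raises(ValueError):
            analytic.fit_kappa(np.array([3]), np.array([0.5]), cfg)

    def test_fitted_kappa_mode_validation(self):
        cfg = builtin_config("hippo-elec")
        with pytest.raises(ValueError):
            analytic.resolve_kappa(cfg, cfg.L / cfg.sigma * 10)
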