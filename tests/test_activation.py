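import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synconv import activation as act
from synconv.config import builtin_config


class TestOmega:
    @pytest.mark.parametrize("rho", [1.0, 2.0, 4.0, 8.0])
    def test_complete_group_always_yields_09(self, rho):
        nl = act.GroupNonlinearity(rho=rho, M_ref=4)
        assert act.omega(4, nl) == pytest.approx(0.9, abs=1e-12)

    def test_zero_and_saturation(self):
        nl = act.GroupNonlinearity(rho=8.0, M_ref=4)
        assert act.omega(0, nl) == 0.0
        assert act.omega(8, nl) > 0.999

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(rho=st.floats(0.5, 10), g=st.integers(0, 20))
    def test_monotone_and_bounded(self, rho, g):
        nl = act.GroupNonlinearity(rho=rho, M_ref=5)
        assert 0.0 <= act.omega(g, nl) <= act.omega(g + 1, nl) <= 1.0

    def test_invalid_rho(self):
        with pytest.raises(ValueError):
            act.GroupNonlinearity(rho=0.0, M_ref=4)


class TestGroupActivation:
    def test_silent_dendrite(self):
        cfg = builtin_config("hippo-elec", M=4)
        nl = act.GroupNonlinearity(rho=2.0, M_ref=4)
        out = act.neuron_group_activation(np.zeros((2, 1000), dtype=np.int8), cfg, nl)
        assert (out == 0).all()

    def test_saturated_dendrite_reaches_zone_count_bound(self):
        cfg = builtin_config("hippo-elec", M=4)
        nl = act.GroupNonlinearity(rho=8.0, M_ref=4)
        labels = np.ones((1, cfg.n_synapses), dtype=np.int8)
        out = act.neuron_group_activation(labels, cfg, nl)
        assert out[0] <= cfg.L / cfg.Z
        assert out[0] == pytest.approx(cfg.L / cfg.Z, rel=0.02)  # near-saturation

    def test_invariant_to_ensemble_relabeling(self, rng):
        """Activation depends only on which synapses are active."""
        cfg = builtin_config("hippo-CICR", M=4)
        nl = act.GroupNonlinearity(rho=4.0, M_ref=4)
        labels = rng.integers(0, 5, size=(3, 2000)).astype(np.int8)
        shuffled = labels.copy()
        shuffled[shuffled > 0] = 5 - shuffled[shuffled > 0]  # permute identities
        np.testing.assert_allclose(
            act.neuron_group_activation(labels, cfg, nl),
            act.neuron_group_activation(shuffled, cfg, nl),
        )


class TestSequenceActivation:
    def test_no_input_no_activation(self, hippo_cicr_seq, tuned_sequence_params):
        params, _ = tuned_sequence_params
        assert act.sequence_activation(np.zeros((4, 200)), hippo_cicr_seq, params) == 0.0

    def test_isolated_input_decays_geometrically(self, hippo_cicr_seq, tuned_sequence_params):
        params, _ = tuned_sequence_params
        d = np.zeros((4, 200))
        d[0, 100] = 1.0
        _, field = act.sequence_activation(d, hippo_cicr_seq, params, return_field=True)
        q = field[:, 100]
        assert q[0] == pytest.approx(1.0)
        for t in range(1, 4):
            assert q[t] == pytest.approx(params.gamma ** t, rel=1e-9)

    def test_ordered_exceeds_reversed(self, hippo_cicr_seq, tuned_sequence_params):
        params, _ = tuned_sequence_params
        ordered = act._local_sequence_inputs(4, (0, 1, 2, 3), hippo_cicr_seq)
        rev = act._local_sequence_inputs(4, (3, 2, 1, 0), hippo_cicr_seq)
        a_ord = act.sequence_activation(ordered, hippo_cicr_seq, params)
        a_rev = act.sequence_activation(rev, hippo_cicr_seq, params)
        assert a_ord > a_rev

    def test_space_reversal_equals_pattern_reversal(self, hippo_cicr_seq, tuned_sequence_params):
        """Directionality is purely geometric."""
        params, _ = tuned_sequence_params
        d = act._local_sequence_inputs(4, (0, 1, 2, 3), hippo_cicr_seq)
        a_rev_pattern = act.sequence_activation(
            act._local_sequence_inputs(4, (3, 2, 1, 0), hippo_cicr_seq), hippo_cicr_seq, params
        )
        a_rev_space = act.sequence_activation(d[:, ::-1].copy(), hippo_cicr_seq, params)
        assert a_rev_space == pytest.approx(a_rev_pattern, rel=1e-9)

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            act.SequenceActivationParams(gamma=1.0, eta=2.0, c=1.0, Vmax=5.0)


class TestPatternSet:
    def test_sizes(self):
        assert len(act.pattern_set(3)) == 6
        assert len(act.pattern_set(4)) == 24
        assert len(act.pattern_set(5)) == 24

    def test_endpoints_for_m4(self):
        ps = act.pattern_set(4)
        assert ps[0] == (0, 1, 2, 3)
        assert ps[-1] == (3, 2, 1, 0)

    def test_first_is_identity_for_all_m(self):
        for M in (3, 4, 5, 6):
            assert act.pattern_set(M)[0] == tuple(range(M))

    def test_small_m_rejected(self):
        with pytest.raises(ValueError):
            act.pattern_set(2)


class TestSelectivity:
    def test_uniform_responses(self):
        assert act.selectivity(np.array([1.0, 1.0, 1.0])) == 0.0

    def test_direct_arithmetic(self):
        assert act.selectivity(np.array([2.0, 1.0, 1.0, 1.0])) == pytest.approx(0.375)

    def test_upper_bound(self, rng):
        a = rng.random((50, 24))
        sel = act.selectivity(a)
        bound = 1 - a.mean(axis=-1) / a.max(axis=-1)
        assert (sel <= bound + 1e-12).all()

    def test_nonpositive_max_flagged(self):
        assert np.isnan(act.selectivity(np.array([0.0, 0.0])))


class TestBackgroundSubtract:
    def test_equal_stimulus_and_background(self):
        stim = np.full((3, 4), 2.0)
        out = act.background_subtract(stim, np.full(3, 2.0))
        assert (out == 0).all()

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError):
            act.background_subtract(np.zeros((3, 4)), np.zeros(2))

    def test_subtraction_raises_selectivity_for_positive_baseline(self, rng):
        acts = rng.random((20, 6)) + 1.0
        acts[:, 0] += 1.5  # ordered pattern strictly dominant for every neuron
        bg = np.full(20, 0.8)
        raw = act.selectivity(acts)
        sub = act.selectivity(act.background_subtract(acts, bg))
        assert (sub >= raw - 1e-12).all()


class TestTuning:
    def test_target_achieved_and_deterministic(self, hippo_cicr_seq, tuned_sequence_params):
        params, sel = tuned_sequence_params
        assert 0.75 <= sel <= 0.85
        again = act.tune_sequence_params(hippo_cicr_seq, 0.8, M=4)
        assert again[0] == params and again[1] == sel

    def test_invalid_target(self, hippo_cicr_seq):
        with pytest.raises(ValueError):
            act.tune_sequence_params(hippo_cicr_seq, 0.0)


class TestDiscriminateCohorts:
    def test_identical_distributions_not_separable(self, rng):
        x = rng.normal(size=200)
        rep = act.discriminate_cohorts(x[:100], x[100:])
        assert not rep.threshold_separable

    def test_disjoint_distributions_separable(self, rng):
        a = rng.normal(loc=10.0, size=50)
        b = rng.normal(loc=0.0, size=50)
        rep = act.discriminate_cohorts(a, b)
        assert rep.threshold_separable
        assert rep.p_value < 1e-6
        assert rep.auc > 0.99

    def test_degenerate_cohort_flagged(self):
        rep = act.discriminate_cohorts(np.array([1.0]), np.array([0.0, 0.1]))
        assert rep.inconclusive
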