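import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trustdyn as td
from trustdyn.errors import ConfigurationError, ParameterError
from trustdyn.trust import AO_ALPHABET, NOT_REWARDED, REWARDED


def seq_from_symbols(symbols):
    return td.ObservationSequence(
        actions=tuple("a" for _ in symbols),
        rewarded=tuple(s == REWARDED for s in symbols),
    )


class TestTransitionEstimation:
    def test_add_one_bigram_counts(self):
        model = td.estimate_transitions(seq_from_symbols("rrrn"), smoothing=1.0)
        # transitions from r: r->r twice, r->n once
        assert model.prob("r", "r") == pytest.approx(3 / 5)
        assert model.prob("r", "n") == pytest.approx(2 / 5)

    def test_empty_sequence_uniform(self):
        model = td.estimate_transitions(seq_from_symbols(""), smoothing=1.0)
        assert np.allclose(model.matrix, 0.5)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        bits=st.lists(st.booleans(), max_size=30),
        smoothing=st.floats(0.1, 5.0),
    )
    def test_rows_always_normalized(self, bits, smoothing):
        seq = td.ObservationSequence(tuple("a" for _ in bits), tuple(bits))
        model = td.estimate_transitions(seq, smoothing=smoothing)
        assert np.allclose(model.matrix.sum(axis=1), 1.0, atol=1e-12)
        assert (model.matrix >= 0).all() and (model.matrix <= 1).all()

    def test_zero_smoothing_unseen_context_uniform(self):
        model = td.estimate_transitions(seq_from_symbols("rr"), smoothing=0.0)
        assert model.prob("r", "r") == 1.0
        assert model.prob("n", "r") == 0.5  # context never observed
        with pytest.raises(ParameterError):
            td.estimate_transitions(seq_from_symbols("rr"), smoothing=-1.0)


@pytest.fixture(scope="module")
def model():
    return td.TransitionModel(matrix=np.array([[0.8, 0.2], [0.4, 0.6]]))


class TestChainedProbability:
    def test_single_and_double_transitions(self, model):
        assert td.dbp_chain(seq_from_symbols("rn"), model) == pytest.approx(0.2)
        assert td.dbp_chain(seq_from_symbols("rrr"), model) == pytest.approx(0.64)

    def test_deterministic_chain(self):
        model = td.TransitionModel(matrix=np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert td.dbp_chain(seq_from_symbols("rrrrr"), model) == 1.0

    def test_exhaustive_enumeration_oracle(self, model):
        # independent oracle: explicit factor-by-factor product over every
        # 2-symbol sequence up to length 5
        for length in range(6):
            for symbols in itertools.product(AO_ALPHABET, repeat=length):
                expected = 1.0
                for a, b in zip(symbols[:-1], symbols[1:]):
                    expected *= model.prob(a, b)
                assert td.dbp_chain(seq_from_symbols(symbols), model) == pytest.approx(
                    expected, rel=1e-12
                )

    def test_unknown_symbol_rejected(self, model):
        with pytest.raises(ConfigurationError):
            model.prob("x", "r")


class TestNextRewardProbability:
    def test_lookup_from_current_symbol(self):
        model = td.TransitionModel(matrix=np.array([[0.8, 0.2], [0.4, 0.6]]))
        assert td.dbp_next_reward(seq_from_symbols("nr"), model) == pytest.approx(0.8)
        assert td.dbp_next_reward(seq_from_symbols("rn"), model) == pytest.approx(0.4)

    def test_fully_rewarded_history_without_smoothing(self):
        seq = seq_from_symbols("rrrrr")
        model = td.estimate_transitions(seq, smoothing=0.0)
        assert td.dbp_next_reward(seq, model) == 1.0

    def test_hand_counted_example(self):
        seq = seq_from_symbols("rrnr")
        model = td.estimate_transitions(seq, smoothing=1.0)
        # transitions from r: r->r once, r->n once -> P(r|r) = 2/4
        assert td.dbp_next_reward(seq, model) == pytest.approx(0.5)

    def test_empty_sequence_marginal(self):
        model = td.estimate_transitions(seq_from_symbols(""), smoothing=1.0)
        assert td.dbp_next_reward(seq_from_symbols(""), model) == pytest.approx(0.5)


class TestTrustUpdate:
    def test_fixed_point_and_frozen_trust(self):
        state = td.TrustState(beta=0.6, eta=0.3)
        assert td.update_trust(state, 0.6).beta == pytest.approx(0.6)
        frozen = td.TrustState(beta=0.6, eta=0.0)
        assert td.update_trust(frozen, 1.0).beta == 0.6

    def test_smoothing_example(self):
        state = td.TrustState(beta=0.7, eta=0.1)
        assert td.update_trust(state, 1.0).beta == pytest.approx(0.73)

    def test_history_appended(self):
        state = td.TrustState(beta=0.5, eta=0.5)
        state = td.update_trust(td.update_trust(state, 1.0), 0.0)
        assert [h[0] for h in state.history] == [1, 2]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        beta=st.floats(0, 1), eta=st.floats(0, 1), dbp=st.floats(0, 1)
    )
    def test_beta_stays_in_unit_interval(self, beta, eta, dbp):
        out = td.update_trust(td.TrustState(beta=beta, eta=eta), dbp)
        assert 0.0 <= out.beta <= 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            td.TrustState(beta=1.2)
        with pytest.raises(ParameterError):
            td.update_trust(td.TrustState(beta=0.5), 1.5)


def beta_after_observation(consistency, competence, n_trials, seed, eta=0.2):
    """Macro trust loop driven by a simulated expert (no network needed)."""
    seq = td.generate_expert_sequence(consistency, competence, n_trials, seed)
    state = td.TrustState(beta=0.7, eta=eta)
    for t in range(n_trials):
        prefix = seq.prefix(t + 1)
        model = td.estimate_transitions(prefix, smoothing=1.0)
        state = td.update_trust(state, td.dbp_next_reward(prefix, model))
    return state.beta


class TestTrustRecoversExpertStatistics:
    def test_beta_converges_to_reward_probability(self):
        finals = [beta_after_observation(0.9, 0.8, 100, seed) for seed in range(120)]
        assert abs(np.median(finals) - 0.8) < 0.05

    def test_competence_monotonicity(self):
        longrun = [
            np.median([beta_after_observation(0.9, comp, 100, seed) for seed in range(15)])
            for comp in (0.2, 0.5, 0.8, 0.95)
        ]
        assert all(a <= b + 1e-9 for a, b in zip(longrun[:-1], longrun[1:]))


class TestGainMappingAndSignalValue:
    def test_affine_endpoints(self):
        assert td.trust_to_gain(0.0, 4.0, 12.0) == 4.0
        assert td.trust_to_gain(1.0, 4.0, 12.0) == 12.0
        assert td.trust_to_gain(0.5, 4.0, 12.0) == pytest.approx(8.0)

    def test_invalid_map(self):
        with pytest.raises(ConfigurationError):
            td.trust_to_gain(0.5, 10.0, 4.0)

    def test_signal_value_product(self):
        assert td.signal_value(0.0, 6.0, 0.0) == 0.0
        assert td.signal_value(1.0, 1.0, 0.37) == pytest.approx(0.37)
        assert td.signal_value(2.0, 6.0, 0.64) == pytest.approx(7.68)

    def test_signal_value_validation(self):
        with pytest.raises(ParameterError):
            td.signal_value(-1.0, 6.0, 0.5)
        with pytest.raises(ParameterError):
            td.signal_value(1.0, 6.0, 1.5)


class TestObservationSerialization:
    def test_frame_round_trip(self):
        seq = td.generate_expert_sequence(0.8, 0.6, 25, seed=5)
        back = td.ObservationSequence.from_frame(seq.to_frame())
        assert back == seq
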