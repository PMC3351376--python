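"""Penalized transitions, Viterbi decoding, event extraction, and training."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vertpsm import (
    DecoderState,
    EmissionSequence,
    ParameterError,
    PSMParameters,
    StateSequence,
    TrainingError,
    ValidationError,
    decode,
    decode_brute_force,
    effective_transitions,
    extract_events,
    train_from_sequences,
    train_supervised,
    update_counters,
)
from vertpsm.synthetic import simulate_annotated_history

from oracles import random_emissions, trace_decode


def emissions(symbols, label="s1"):
    return EmissionSequence(symbols=tuple(symbols), alpha=0.10, subpopulation=label)


class TestParameters:
    def test_default_values(self, default_params):
        assert default_params.p_AN0 == pytest.approx(0.154)
        assert default_params.p_NA0 == pytest.approx(0.079)
        assert default_params.e_A == pytest.approx({"N": 0.102, "Z": 0.150, "P": 0.748})
        assert default_params.e_N == pytest.approx({"N": 0.434, "Z": 0.337, "P": 0.229})

    def test_yaml_roundtrip(self, tmp_path, default_params):
        path = tmp_path / "params.yaml"
        default_params.save(path)
        assert PSMParameters.load(path) == default_params

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(p_AN0=0.0),
            dict(p_AN0=1.0),
            dict(e_A={"N": 0.5, "Z": 0.5, "P": 0.5}),
            dict(e_N={"N": 0.5, "Z": 0.5}),
        ],
    )
    def test_invalid_parameters_rejected(self, default_params, kwargs):
        base = default_params.to_dict()
        base.update(kwargs)
        with pytest.raises(ParameterError):
            PSMParameters(**base)


class TestPenalty:
    def test_nominal_values_at_zero_counters(self, default_params):
        p_an, p_na, p_aa, p_nn = effective_transitions(default_params, DecoderState())
        assert p_an == pytest.approx(0.154)
        assert p_na == pytest.approx(0.079)
        assert p_aa == pytest.approx(0.846)
        assert p_nn == pytest.approx(0.921)

    def test_exponential_decay(self, default_params):
        p_an, *_ = effective_transitions(default_params, DecoderState(c_p=2))
        assert p_an == pytest.approx(0.154 * math.exp(-2), rel=1e-12)

    @pytest.mark.parametrize("c", range(11))
    def test_matches_direct_evaluation(self, default_params, c):
        p_an, p_na, p_aa, p_nn = effective_transitions(
            default_params, DecoderState(c_p=c)
        )
        assert p_an == pytest.approx(0.154 * math.exp(-c), abs=1e-15)
        _, p_na, _, p_nn = effective_transitions(default_params, DecoderState(c_notp=c))
        assert p_na == pytest.approx(0.079 * math.exp(-c), abs=1e-15)
        assert p_nn == pytest.approx(1 - 0.079 * math.exp(-c), abs=1e-15)

    def test_large_counter_limit(self, default_params):
        _, p_na, _, p_nn = effective_transitions(
            default_params, DecoderState(c_notp=10_000)
        )
        assert p_na == pytest.approx(0.0, abs=1e-20)
        assert p_nn == pytest.approx(1.0)


class TestCounters:
    def test_z_resets_positive_run(self):
        ds = update_counters(DecoderState(c_p=3), "Z")
        assert (ds.c_p, ds.c_notp) == (0, 1)

    def test_n_extends_nonpositive_run(self):
        ds = update_counters(DecoderState(c_notp=2), "N")
        assert (ds.c_p, ds.c_notp) == (0, 3)

    def test_p_starts_positive_run(self):
        ds = update_counters(DecoderState(), "P")
        assert (ds.c_p, ds.c_notp) == (1, 0)

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValidationError):
            update_counters(DecoderState(), "Q")

    def test_both_counters_positive_rejected(self):
        with pytest.raises(ValidationError):
            DecoderState(c_p=1, c_notp=1)


class TestDecode:
    def test_all_z_stays_nonadaptive(self, default_params):
        seq = decode(emissions("Z" * 12), default_params)
        assert seq.states == ("N",) * 12

    @pytest.mark.parametrize("symbol", ["P", "N", "Z"])
    def test_single_symbol_from_initial_state(self, default_params, symbol):
        """One interval: argmax between staying in N and entering A, and the
        back-shift is the identity on a length-1 sequence."""
        seq = decode(emissions(symbol), default_params)
        p = default_params
        stay = (1 - p.p_NA0) * p.e_N[symbol]
        enter = p.p_NA0 * p.e_A[symbol]
        expected = "A" if enter > stay else "N"
        assert seq.states == (expected,)

    def test_sustained_positive_run_becomes_adaptive(self, default_params):
        seq = decode(emissions("PPPPP"), default_params)
        assert "A" in seq.states
        assert seq.states[-1] == "A"
        # once entered, the penalized p_AN keeps the path in A for the run
        first_a = seq.states.index("A")
        assert set(seq.states[first_a:]) == {"A"}

    def test_empty_sequence_rejected(self, default_params):
        with pytest.raises(ValidationError):
            decode(emissions(""), default_params)

    def test_decode_is_pure(self, default_params):
        e = emissions("ZPPNZPPPZN")
        assert decode(e, default_params).states == decode(e, default_params).states

    def test_back_shift_translates_one_point(self, default_params):
        e = emissions("ZZPPPPZZZZ")
        raw = decode(e, default_params, apply_back_shift=False).states
        shifted = decode(e, default_params).states
        assert shifted == raw[1:] + (raw[-1],)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_trace(self, default_params, seed):
        rng = np.random.default_rng(seed)
        p = default_params
        for _ in range(60):
            syms = random_emissions(rng)
            expected = trace_decode(syms, p.p_AN0, p.p_NA0, p.e_A, p.e_N)
            assert decode(emissions(syms), p).states == expected

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_enumeration(self, seed):
        """Three-way agreement on short sequences, including random parameters."""
        rng = np.random.default_rng(100 + seed)
        e_a = rng.dirichlet(np.ones(3))
        e_n = rng.dirichlet(np.ones(3))
        params = PSMParameters(
            p_AN0=rng.uniform(0.05, 0.5),
            p_NA0=rng.uniform(0.05, 0.5),
            e_A=dict(zip("NZP", e_a)),
            e_N=dict(zip("NZP", e_n)),
        )
        for _ in range(40):
            syms = random_emissions(rng, max_length=9)
            e = emissions(syms)
            viterbi = decode(e, params).states
            brute = decode_brute_force(e, params).states
            trace = trace_decode(syms, params.p_AN0, params.p_NA0, params.e_A, params.e_N)
            assert viterbi == brute == trace

    def test_brute_force_length_guard(self, default_params):
        with pytest.raises(ParameterError):
            decode_brute_force(emissions("P" * 20), default_params)

    @given(st.integers(0, 2**32 - 1))
    def test_appending_p_never_flips_trailing_a(self, seed):
        """If the raw decode ends in A, appending another positive symbol
        keeps that position adaptive (inertia of the penalized model)."""
        params = PSMParameters.default()
        rng = np.random.default_rng(seed)
        syms = random_emissions(rng, max_length=25)
        raw = decode(emissions(syms), params, apply_back_shift=False).states
        if raw[-1] == "A":
            extended = decode(
                emissions(syms + ("P",)), params, apply_back_shift=False
            ).states
            assert extended[len(syms) - 1] == "A"


class TestEvents:
    GENS = tuple(range(0, 90, 10))  # 9 measurements -> 8 intervals

    def test_single_run(self):
        events = extract_events(StateSequence(tuple("NNAAANNN"), "s1"), self.GENS)
        assert [(e.start_index, e.end_index) for e in events] == [(2, 4)]
        event = events[0]
        assert event.duration_points == 3
        assert event.start_gen == 30.0 and event.end_gen == 50.0
        assert event.duration_gens == 20.0

    def test_no_events(self):
        assert extract_events(StateSequence(tuple("NNNNNNNN"), "s1"), self.GENS) == []

    def test_two_singleton_runs(self):
        events = extract_events(
            StateSequence(tuple("ANANNNNN"), "s1"), self.GENS
        )
        assert [(e.start_index, e.end_index) for e in events] == [(0, 0), (2, 2)]

    def test_run_to_the_end(self):
        events = extract_events(StateSequence(tuple("NNNNNAAA"), "s1"), self.GENS)
        assert [(e.start_index, e.end_index) for e in events] == [(5, 7)]
        assert events[0].end_gen == 80.0

    def test_axis_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            extract_events(StateSequence(tuple("NNA"), "s1"), [0.0, 10.0, 20.0])


class TestTraining:
    def test_degenerate_all_n_without_pseudocount(self):
        with pytest.raises(TrainingError):
            train_from_sequences([("NNNN", "ZZZZ")], pseudocount=0.0)

    def test_degenerate_all_n_with_pseudocount(self):
        params = train_from_sequences([("NNNN", "ZZZZ")], pseudocount=0.5)
        assert 0 < params.p_NA0 < 0.5
        assert params.e_N["Z"] > params.e_N["P"]

    def test_counts_match_hand_tally(self):
        params = train_from_sequences(
            [("NNAAN", "ZPPPN")], pseudocount=0.0
        )
        # transitions: N->N, N->A, A->A, A->N ; emissions N:{Z,P,N} A:{P,P}
        assert params.p_NA0 == pytest.approx(1 / 2)
        assert params.p_AN0 == pytest.approx(1 / 2)
        assert params.e_A == pytest.approx({"N": 0.0, "Z": 0.0, "P": 1.0})
        assert params.e_N == pytest.approx({"N": 1 / 3, "Z": 1 / 3, "P": 1 / 3})

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            train_from_sequences([("NN", "ZZZ")])

    def test_empty_training_set_rejected(self, reference_cal):
        with pytest.raises(TrainingError):
            train_from_sequences([])
        with pytest.raises(TrainingError):
            train_supervised([], reference_cal)

    def test_recovery_from_simulated_annotations(self, default_params, reference_cal):
        """Training on data generated from known parameters recovers them
        within sampling error (moderate size; the full-size recovery is
        exercised by the acceptance suite)."""
        histories = [
            simulate_annotated_history(
                60, default_params, reference_cal, seed=1000 + i
            )[0]
            for i in range(40)
        ]
        fitted = train_supervised(
            histories, reference_cal, pseudocount=0.5, subpopulations=("s1",)
        )
        n_points = sum(h.history.n_points - 1 for h in histories)
        assert n_points == 2400
        for estimate, truth in [
            (fitted.p_AN0, default_params.p_AN0),
            (fitted.p_NA0, default_params.p_NA0),
            (fitted.e_A["P"], default_params.e_A["P"]),
            (fitted.e_N["Z"], default_params.e_N["Z"]),
        ]:
            se = math.sqrt(truth * (1 - truth) / (n_points / 3))
            assert abs(estimate - truth) < 4 * se
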