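"""Two-state history-penalized hidden Markov model for adaptive-event calling.

Hidden states are ``N`` (not expanding) and ``A`` (adaptive expansion).  The
nominal transition probabilities are damped by an exponential penalty driven
by the length of the current run of positive (``C_P``) or non-positive
(``C_!P``) emission symbols:

    p_AN = p_AN0 * exp(-C_P),   p_NA = p_NA0 * exp(-C_!P)

Both counters are functions of the *observed* emission sequence alone (a run
of ``P`` symbols increments ``C_P`` and resets ``C_!P``; ``N``/``Z`` do the
opposite), so the transition matrix at every step is known in advance and the
most likely state path can be decoded exactly with a time-inhomogeneous
forward Viterbi pass.  After decoding, the state sequence is translated back
one position (the published back-shift) to better align calls with per-sample
annotations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .classifier import (
    EMISSION_ALPHABET,
    EmissionSequence,
    NeutralCalibration,
    classify_rates,
    compute_expansion_rates,
    compute_proportions,
)
from .errors import ParameterError, TrainingError, ValidationError
from .io import AnnotatedHistory

HIDDEN_STATES = ("N", "A")

#: Counter values are capped before exponentiation; exp(-50) ~ 2e-22 is zero
#: for every decision purpose and the cap avoids needless underflow.
COUNTER_CAP = 50

#: Relative tolerance below which two path scores are considered tied.
#: Ties resolve to staying in the current state (and to ``N`` at the end of
#: the sequence), giving the decoder a deterministic, inertia-consistent rule
#: that is robust to floating-point ordering effects.
TIE_REL = 1e-12


def _strictly_greater(a: float, b: float) -> bool:
    """True when ``a`` beats ``b`` by more than the tie tolerance."""
    return a > b and (a - b) > TIE_REL * max(abs(a), abs(b))


@dataclass(frozen=True)
class PSMParameters:
    """Nominal transition probabilities and per-state emission distributions."""

    p_AN0: float
    p_NA0: float
    e_A: Mapping[str, float]
    e_N: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "e_A", dict(self.e_A))
        object.__setattr__(self, "e_N", dict(self.e_N))
        for name, p in (("p_AN0", self.p_AN0), ("p_NA0", self.p_NA0)):
            if not (0.0 < p < 1.0):
                raise ParameterError(f"{name} must lie strictly in (0, 1), got {p}")
        for name, dist in (("e_A", self.e_A), ("e_N", self.e_N)):
            if set(dist) != set(EMISSION_ALPHABET):
                raise ParameterError(f"{name} must assign a probability to each of N, Z, P")
            if any(not (0.0 <= v <= 1.0) for v in dist.values()):
                raise ParameterError(f"{name} probabilities must lie in [0, 1]")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ParameterError(f"{name} must sum to 1 (got {sum(dist.values())})")

    def emission(self, state: str, symbol: str) -> float:
        dist = self.e_A if state == "A" else self.e_N
        return dist[symbol]

    @classmethod
    def default(cls) -> "PSMParameters":
        """Parameters trained on the annotated yeast chemostat dataset."""
        text = resources.files("vertpsm.data").joinpath("default_params.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_dict(cls, payload: Mapping) -> "PSMParameters":
        try:
            return cls(
                p_AN0=float(payload["p_AN0"]),
                p_NA0=float(payload["p_NA0"]),
                e_A={s: float(payload["e_A"][s]) for s in EMISSION_ALPHABET},
                e_N={s: float(payload["e_N"][s]) for s in EMISSION_ALPHABET},
            )
        except (KeyError, TypeError) as exc:
            raise ParameterError(f"malformed parameter payload: {exc}") from exc

    def to_dict(self) -> dict:
        return {
            "p_AN0": float(self.p_AN0),
            "p_NA0": float(self.p_NA0),
            "e_A": {s: float(self.e_A[s]) for s in EMISSION_ALPHABET},
            "e_N": {s: float(self.e_N[s]) for s in EMISSION_ALPHABET},
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PSMParameters":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class DecoderState:
    """Current hidden state plus the contiguous-symbol penalty counters."""

    state: str = "N"
    c_p: int = 0
    c_notp: int = 0

    def __post_init__(self) -> None:
        if self.state not in HIDDEN_STATES:
            raise ValidationError(f"unknown hidden state {self.state!r}")
        if self.c_p < 0 or self.c_notp < 0:
            raise ValidationError("penalty counters must be non-negative")
        if self.c_p > 0 and self.c_notp > 0:
            raise ValidationError("at most one penalty counter may be positive")


@dataclass(frozen=True)
class StateSequence:
    """Decoded hidden states, one per emission interval (post back-shift)."""

    states: tuple[str, ...]
    subpopulation: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        bad = set(self.states) - set(HIDDEN_STATES)
        if bad:
            raise ValidationError(f"hidden-state symbols outside {{A, N}}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class AdaptiveEvent:
    """A maximal run of decoded A states for one subpopulation.

    Indices live on the emission-interval axis (inclusive on both ends);
    interval ``k`` is attributed to the measurement at ``generations[k + 1]``.
    """

    subpopulation: str
    start_index: int
    end_index: int
    start_gen: float
    end_gen: float
    duration_points: int
    duration_gens: float


def effective_transitions(
    params: PSMParameters, ds: DecoderState
) -> tuple[float, float, float, float]:
    """Penalized transition probabilities ``(p_AN, p_NA, p_AA, p_NN)``."""
    p_an = params.p_AN0 * math.exp(-min(ds.c_p, COUNTER_CAP))
    p_na = params.p_NA0 * math.exp(-min(ds.c_notp, COUNTER_CAP))
    return p_an, p_na, 1.0 - p_an, 1.0 - p_na


def update_counters(ds: DecoderState, symbol: str) -> DecoderState:
    """Advance the contiguous-run counters with one emission symbol."""
    if symbol not in EMISSION_ALPHABET:
        raise ValidationError(f"unknown emission symbol {symbol!r}")
    if symbol == "P":
        return replace(ds, c_p=ds.c_p + 1, c_notp=0)
    return replace(ds, c_p=0, c_notp=ds.c_notp + 1)


def transition_schedule(
    params: PSMParameters, symbols: Sequence[str]
) -> list[tuple[float, float, float, float]]:
    """Per-step ``(p_AN, p_NA, p_AA, p_NN)`` for a whole emission sequence.

    The penalty at step ``k`` uses the run length accumulated over symbols
    strictly before ``k``; the symbol at ``k`` then updates the counters.
    """
    ds = DecoderState()
    schedule = []
    for symbol in symbols:
        schedule.append(effective_transitions(params, ds))
        ds = update_counters(ds, symbol)
    return schedule


def back_shift(states: Sequence[str]) -> tuple[str, ...]:
    """Translate decoded states one position earlier; the last state repeats."""
    states = tuple(states)
    if len(states) <= 1:
        return states
    return states[1:] + (states[-1],)


def decode(
    emissions: EmissionSequence, params: PSMParameters, apply_back_shift: bool = True
) -> StateSequence:
    """Decode an emission sequence into the most likely A/N state path.

    Exact forward Viterbi over the two hidden states with the emission-driven
    penalized transition schedule; all subpopulations start in state ``N``
    before the first interval.  The back-shift is applied by default.
    """
    symbols = tuple(emissions.symbols)
    if not symbols:
        raise ValidationError("cannot decode an empty emission sequence")
    schedule = transition_schedule(params, symbols)

    # scores[s] is the best path probability ending in state s, renormalized
    # each step by the running maximum (argmax-invariant).
    p_an, p_na, p_aa, p_nn = schedule[0]
    scores = {
        "N": p_nn * params.emission("N", symbols[0]),
        "A": p_na * params.emission("A", symbols[0]),
    }
    backptr: list[dict[str, str]] = [{"N": "N", "A": "N"}]
    for k in range(1, len(symbols)):
        p_an, p_na, p_aa, p_nn = schedule[k]
        stay = {"N": p_nn, "A": p_aa}
        enter = {"N": p_an, "A": p_na}  # probability of switching *into* state
        new_scores: dict[str, float] = {}
        pointers: dict[str, str] = {}
        for state in HIDDEN_STATES:
            other = "A" if state == "N" else "N"
            e = params.emission(state, symbols[k])
            stay_score = scores[state] * stay[state] * e
            switch_score = scores[other] * enter[state] * e
            if _strictly_greater(switch_score, stay_score):
                new_scores[state] = switch_score
                pointers[state] = other
            else:
                new_scores[state] = stay_score
                pointers[state] = state
        top = max(new_scores.values())
        if top > 0:
            new_scores = {s: v / top for s, v in new_scores.items()}
        scores = new_scores
        backptr.append(pointers)

    last = "A" if _strictly_greater(scores["A"], scores["N"]) else "N"
    raw = [last]
    for pointers in reversed(backptr[1:]):
        raw.append(pointers[raw[-1]])
    raw.reverse()

    states = back_shift(raw) if apply_back_shift else tuple(raw)
    return StateSequence(states=states, subpopulation=emissions.subpopulation)


def decode_brute_force(
    emissions: EmissionSequence,
    params: PSMParameters,
    apply_back_shift: bool = True,
    max_length: int = 16,
) -> StateSequence:
    """Exact decoder by exhaustive path enumeration (comparison utility).

    Scores every one of the ``2**L`` state paths directly and applies the same
    tie rule as :func:`decode` (prefer ``N`` at the end, prefer staying when
    walking backwards).  Only practical for short sequences; used to study
    the decoder, not to run it.
    """
    symbols = tuple(emissions.symbols)
    if not symbols:
        raise ValidationError("cannot decode an empty emission sequence")
    if len(symbols) > max_length:
        raise ParameterError(
            f"brute-force enumeration limited to {max_length} symbols, got {len(symbols)}"
        )
    schedule = transition_schedule(params, symbols)

    def path_score(path: Sequence[str]) -> float:
        score = 1.0
        prev = "N"
        for k, state in enumerate(path):
            p_an, p_na, p_aa, p_nn = schedule[k]
            trans = {
                ("N", "N"): p_nn,
                ("N", "A"): p_na,
                ("A", "A"): p_aa,
                ("A", "N"): p_an,
            }[(prev, state)]
            score *= trans * params.emission(state, symbols[k])
            prev = state
        return score

    def tie_key(path: Sequence[str]) -> tuple:
        # Mirror the Viterbi traceback preference: N at the final position,
        # then "stay" (match the successor) at each earlier position.
        key = [0 if path[-1] == "N" else 1]
        for k in range(len(path) - 2, -1, -1):
            key.append(0 if path[k] == path[k + 1] else 1)
        return tuple(key)

    best_path: tuple[str, ...] | None = None
    best_score = -1.0
    for path in itertools.product(HIDDEN_STATES, repeat=len(symbols)):
        score = path_score(path)
        if best_path is None or _strictly_greater(score, best_score):
            best_path, best_score = path, score
        elif not _strictly_greater(best_score, score) and tie_key(path) < tie_key(best_path):
            best_path, best_score = path, max(best_score, score)
    assert best_path is not None
    states = back_shift(best_path) if apply_back_shift else best_path
    return StateSequence(states=states, subpopulation=emissions.subpopulation)


def extract_events(states: StateSequence, generations: Sequence[float]) -> list[AdaptiveEvent]:
    """Collapse maximal runs of A states into adaptive events.

    ``generations`` is the full measurement axis (one longer than the state
    sequence); event indices are inclusive interval indices and the generation
    span maps interval ``k`` to the measurement at ``generations[k + 1]``.
    """
    gens = np.asarray(generations, dtype=float)
    if gens.size != len(states) + 1:
        raise ValidationError(
            f"generation axis of length {gens.size} does not match "
            f"{len(states)} state intervals"
        )
    events: list[AdaptiveEvent] = []
    run_start: int | None = None
    seq = states.states
    for k, state in enumerate(seq + ("N",)):  # sentinel closes a trailing run
        if state == "A" and run_start is None:
            run_start = k
        elif state != "A" and run_start is not None:
            a, b = run_start, k - 1
            events.append(
                AdaptiveEvent(
                    subpopulation=states.subpopulation,
                    start_index=a,
                    end_index=b,
                    start_gen=float(gens[a + 1]),
                    end_gen=float(gens[b + 1]),
                    duration_points=b - a + 1,
                    duration_gens=float(gens[b + 1] - gens[a + 1]),
                )
            )
            run_start = None
    return events


def train_from_sequences(
    pairs: Iterable[tuple[Sequence[str], Sequence[str]]],
    pseudocount: float = 0.5,
) -> PSMParameters:
    """Estimate PSM parameters from aligned (state, emission) sequence pairs.

    Nominal transition probabilities are the observed frequencies of leaving
    each state; emission distributions are the per-state symbol frequencies.
    The pseudocount (Laplace-style, default 0.5) is added to every count so
    that small annotated sets cannot produce zero or undefined probabilities.
    """
    if pseudocount < 0:
        raise ParameterError("pseudocount must be non-negative")
    trans = {("A", "N"): 0.0, ("A", "A"): 0.0, ("N", "A"): 0.0, ("N", "N"): 0.0}
    emit = {s: {o: 0.0 for o in EMISSION_ALPHABET} for s in HIDDEN_STATES}
    n_pairs = 0
    for states, symbols in pairs:
        states = tuple(states)
        symbols = tuple(symbols)
        if len(states) != len(symbols):
            raise ValidationError("state and emission sequences must have equal length")
        bad = (set(states) - set(HIDDEN_STATES)) | (set(symbols) - set(EMISSION_ALPHABET))
        if bad:
            raise ValidationError(f"unknown symbols in training sequences: {sorted(bad)}")
        for state, symbol in zip(states, symbols):
            emit[state][symbol] += 1.0
        for a, b in zip(states, states[1:]):
            trans[(a, b)] += 1.0
        n_pairs += 1
    if n_pairs == 0:
        raise TrainingError("empty training set")

    def leave_prob(state: str) -> float:
        other = "A" if state == "N" else "N"
        num = trans[(state, other)] + pseudocount
        den = trans[(state, other)] + trans[(state, state)] + 2.0 * pseudocount
        if den == 0.0:
            raise TrainingError(
                f"state {state} has no observed successor; use a positive pseudocount"
            )
        p = num / den
        if not (0.0 < p < 1.0):
            raise TrainingError(
                f"degenerate transition estimate for state {state} "
                f"(p = {p}); use a positive pseudocount"
            )
        return p

    def emission_dist(state: str) -> dict[str, float]:
        total = sum(emit[state].values()) + 3.0 * pseudocount
        if total == 0.0:
            raise TrainingError(
                f"state {state} never visited in training data; use a positive pseudocount"
            )
        return {o: (emit[state][o] + pseudocount) / total for o in EMISSION_ALPHABET}

    return PSMParameters(
        p_AN0=leave_prob("A"),
        p_NA0=leave_prob("N"),
        e_A=emission_dist("A"),
        e_N=emission_dist("N"),
    )


def train_supervised(
    training: Sequence[AnnotatedHistory],
    cal: NeutralCalibration,
    alpha: float = 0.10,
    tails: int = 1,
    distribution: str = "t",
    pseudocount: float = 0.5,
    subpopulations: Sequence[str] | None = None,
) -> PSMParameters:
    """Train PSM parameters from annotated histories.

    Each history is pushed through the statistical classifier to obtain its
    emission symbols; annotation row ``k + 1`` supplies the hidden state for
    interval ``k`` (the slope ending at that measurement).  ``subpopulations``
    optionally restricts training to a subset of labels; by default every
    annotated subpopulation contributes.
    """
    if not training:
        raise TrainingError("empty training set")
    wanted = set(subpopulations) if subpopulations is not None else None
    pairs: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
    for annotated in training:
        history = annotated.history
        rates = compute_expansion_rates(compute_proportions(history))
        emissions = classify_rates(
            rates, cal, alpha=alpha, tails=tails, distribution=distribution
        )
        for j, label in enumerate(history.subpopulation_labels):
            if wanted is not None and label not in wanted:
                continue
            pairs.append((tuple(annotated.states[1:, j]), emissions[j].symbols))
    if not pairs:
        raise TrainingError("no subpopulations left after filtering")
    return train_from_sequences(pairs, pseudocount=pseudocount)


__all__ = [
    "HIDDEN_STATES",
    "COUNTER_CAP",
    "PSMParameters",
    "DecoderState",
    "StateSequence",
    "AdaptiveEvent",
    "effective_transitions",
    "update_counters",
    "transition_schedule",
    "back_shift",
    "decode",
    "decode_brute_force",
    "extract_events",
    "train_from_sequences",
    "train_supervised",
]
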