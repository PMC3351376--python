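"""Synthetic FACS population histories with known ground-truth adaptive events.

The generator emulates a multi-labeled chemostat: each labeled subpopulation
is a set of lineages with exponential relative-fitness weights, so a mutant
lineage with selection coefficient ``s`` grows logistically within its host
subpopulation after it arises.  Observation emulates a FACS reading: a
multinomial draw of the configured total count over the true proportions,
followed by optional Gaussian jitter on the proportions (renormalized so each
sample still sums to the configured total).

Ground truth marks a subpopulation ``A`` at a measurement while one of its
mutant lineages is above a detectability threshold, below within-host
saturation, and the subpopulation's true share is still rising — i.e. while
the expansion is observable in principle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .classifier import NeutralCalibration, critical_value
from .errors import ValidationError
from .hmm import PSMParameters
from .io import AnnotatedHistory, PopulationHistory


@dataclass(frozen=True)
class SweepEvent:
    """A planned adaptive mutation: lineage seeded in ``subpopulation`` at
    ``start_gen`` with selection coefficient ``s`` (1/generation) and initial
    within-host frequency ``init_freq``."""

    subpopulation: int
    start_gen: float
    s: float
    init_freq: float = 1e-3

    def __post_init__(self) -> None:
        if self.start_gen < 0:
            raise ValidationError("sweep cannot start before generation 0")
        if self.s < 0:
            raise ValidationError("selection coefficient must be non-negative")
        if not (0.0 < self.init_freq < 1.0):
            raise ValidationError("init_freq must lie in (0, 1)")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated chemostat experiment.

    Defaults emulate a three-color chemostat sampled every ~10 generations
    (roughly daily sampling) with FACS totals of 1e5 cells and mild
    proportion-scale measurement noise.
    """

    J: int = 3
    n_points: int = 25
    gens_per_point: float = 10.0
    events: tuple[SweepEvent, ...] = ()
    noise_sd: float = 0.005
    total_counts: int = 100_000
    seed: int = 0
    detect_threshold: float = 0.05
    saturation: float = 0.95
    initial_proportions: tuple[float, ...] | None = None
    experiment_id: str = "simulated"

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        if self.J < 2:
            raise ValidationError("need at least two labeled subpopulations")
        if self.n_points < 2:
            raise ValidationError("need at least two measurements")
        if self.gens_per_point <= 0:
            raise ValidationError("gens_per_point must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.total_counts <= 0:
            raise ValidationError("total_counts must be positive")
        if not (0 < self.detect_threshold < self.saturation <= 1):
            raise ValidationError("need 0 < detect_threshold < saturation <= 1")
        for event in self.events:
            if not (0 <= event.subpopulation < self.J):
                raise ValidationError(
                    f"sweep targets subpopulation {event.subpopulation}, "
                    f"but J = {self.J}"
                )
        if self.initial_proportions is not None:
            p = tuple(float(x) for x in self.initial_proportions)
            if len(p) != self.J or any(x <= 0 for x in p):
                raise ValidationError("initial_proportions must be J positive values")
            object.__setattr__(self, "initial_proportions", p)


def _true_dynamics(config: SimConfig, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """True subpopulation shares and per-mutant within-host frequencies.

    Returns ``(shares, mutant_freqs)`` with shapes ``(len(times), J)`` and
    ``(len(times), n_events)``.
    """
    if config.initial_proportions is not None:
        base = np.asarray(config.initial_proportions, dtype=float)
        base = base / base.sum()
    else:
        base = np.full(config.J, 1.0 / config.J)

    events = sorted(config.events, key=lambda e: e.start_gen)
    wt = base.copy()  # constant exponential weight of each wild-type lineage
    seeds: list[tuple[SweepEvent, float]] = []  # (event, weight at start_gen)
    for event in events:
        j = event.subpopulation
        host = wt[j] + sum(
            w0 * math.exp(e.s * (event.start_gen - e.start_gen))
            for e, w0 in seeds
            if e.subpopulation == j and e.start_gen <= event.start_gen
        )
        seeds.append((event, event.init_freq / (1.0 - event.init_freq) * host))

    shares = np.empty((times.size, config.J))
    freqs = np.empty((times.size, len(seeds)))
    for i, t in enumerate(times):
        weights = wt.copy()
        m = np.zeros(len(seeds))
        for idx, (event, w0) in enumerate(seeds):
            if t >= event.start_gen:
                m[idx] = w0 * math.exp(event.s * (t - event.start_gen))
                weights[event.subpopulation] += m[idx]
        shares[i] = weights / weights.sum()
        for idx, (event, _) in enumerate(seeds):
            freqs[i, idx] = m[idx] / weights[event.subpopulation]
    return shares, freqs


def _observe(
    shares: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """FACS observation: multinomial sampling plus Gaussian proportion jitter."""
    n, J = shares.shape
    counts = np.empty((n, J))
    for i in range(n):
        drawn = rng.multinomial(config.total_counts, shares[i])
        p = drawn / config.total_counts
        if config.noise_sd > 0:
            p = p + rng.normal(0.0, config.noise_sd, size=J)
        p = np.maximum(p, 1e-9)
        counts[i] = p / p.sum() * config.total_counts
    return counts


def simulate_experiment(config: SimConfig) -> tuple[PopulationHistory, AnnotatedHistory]:
    """Simulate one experiment; deterministic for a fixed config (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    times = np.arange(config.n_points, dtype=float) * config.gens_per_point
    # one extra grid point so "still expanding" is defined at the last sample
    extended = np.append(times, times[-1] + config.gens_per_point)
    shares, freqs = _true_dynamics(config, extended)

    states = np.full((config.n_points, config.J), "N", dtype="<U1")
    for idx, event in enumerate(sorted(config.events, key=lambda e: e.start_gen)):
        j = event.subpopulation
        for i in range(config.n_points):
            detectable = config.detect_threshold <= freqs[i, idx] < config.saturation
            expanding = shares[i + 1, j] > shares[i, j]
            if detectable and expanding:
                states[i, j] = "A"

    counts = _observe(shares[:-1], config, rng)
    history = PopulationHistory(
        experiment_id=config.experiment_id,
        subpopulation_labels=tuple(f"s{j + 1}" for j in range(config.J)),
        generations=times,
        counts=counts,
    )
    return history, AnnotatedHistory(history=history, states=states)


def simulate_neutral(config: SimConfig) -> PopulationHistory:
    """Neutrality experiment: the same conditions with no adaptive events."""
    history, _ = simulate_experiment(replace(config, events=()))
    return history


def simulate_annotated_history(
    n_intervals: int,
    params: PSMParameters,
    cal: NeutralCalibration,
    seed: int = 0,
    alpha: float = 0.10,
    tails: int = 1,
    delta_gen: float = 1.0,
    experiment_id: str = "annotated-sim",
) -> tuple[AnnotatedHistory, tuple[str, ...]]:
    """Sample a hidden-state/emission chain from ``params`` and realize it as
    an annotated two-subpopulation history whose classified slopes reproduce
    the sampled symbols exactly.

    The driven subpopulation carries slopes chosen well clear of the
    significance threshold (2-6x the critical slope) for ``P``/``N`` symbols
    and exactly ``mu_r`` for ``Z``; a buffer subpopulation absorbs the
    complementary counts so totals are constant.  Because proportions close to
    one, the buffer's slopes mirror the driven ones; its annotation is the
    honest all-``N``.  Returns the annotated history and the sampled symbol
    sequence (useful for verifying classifier exactness).

    Intended for supervised-training recovery studies: train on the driven
    subpopulation (label ``"s1"``) to compare against the generating
    parameters.
    """
    if n_intervals < 1:
        raise ValidationError("need at least one interval")
    rng = np.random.default_rng(seed)
    crit_slope = critical_value(cal, alpha, tails=tails) * cal.sigma_r / math.sqrt(
        cal.n_neutral
    )
    trans_from = {
        "N": (1.0 - params.p_NA0, params.p_NA0),  # -> (N, A)
        "A": (params.p_AN0, 1.0 - params.p_AN0),
    }
    states: list[str] = []
    symbols: list[str] = []
    prev = "N"
    for _ in range(n_intervals):
        p_n, p_a = trans_from[prev]
        state = "N" if rng.random() < p_n else "A"
        dist = params.e_A if state == "A" else params.e_N
        u = rng.random()
        if u < dist["N"]:
            symbol = "N"
        elif u < dist["N"] + dist["Z"]:
            symbol = "Z"
        else:
            symbol = "P"
        states.append(state)
        symbols.append(symbol)
        prev = state

    g = np.empty(n_intervals + 1)
    g[0] = 1.0
    for k, symbol in enumerate(symbols):
        if symbol == "Z":
            slope = cal.mu_r
        else:
            magnitude = crit_slope * rng.uniform(2.0, 6.0)
            slope = cal.mu_r + (magnitude if symbol == "P" else -magnitude)
        step = slope * delta_gen
        if not (0.1 < g[k] + step < 1.9):  # safety valve; essentially never fires
            step = -step
        g[k + 1] = g[k] + step

    history = PopulationHistory(
        experiment_id=experiment_id,
        subpopulation_labels=("s1", "buffer"),
        generations=np.arange(n_intervals + 1, dtype=float) * delta_gen,
        counts=np.column_stack([g, 2.0 - g]),
    )
    ann = np.full((n_intervals + 1, 2), "N", dtype="<U1")
    ann[1:, 0] = states
    annotated = AnnotatedHistory(history=history, states=ann)
    return annotated, tuple(symbols)


__all__ = [
    "SweepEvent",
    "SimConfig",
    "simulate_experiment",
    "simulate_neutral",
    "simulate_annotated_history",
]
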