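"""Scoring against annotations and population-dynamics summary statistics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .classifier import RateSeries
from .errors import DegenerateInputError, ValidationError
from .hmm import AdaptiveEvent, StateSequence
from .io import AnnotatedHistory, PopulationHistory


@dataclass(frozen=True)
class ErrorRates:
    """Confusion fractions over all pooled classified points.

    tp: model A and annotated A; tn: model N and annotated N;
    fp: model A but annotated N; fn: model N but annotated A.
    Fractions sum to one.
    """

    tp: float
    tn: float
    fp: float
    fn: float
    n_points: int = 0

    @property
    def accuracy(self) -> float:
        return self.tp + self.tn


@dataclass(frozen=True)
class DynamicsSummary:
    """Adaptive-event summary statistics for one experiment."""

    ae_per_gen_color: float
    rate_of_pex_mean: float
    rate_of_pex_sd: float
    ae_length_mean: float
    ae_length_sd: float
    n_events: int = 0


def compare_annotations(
    predicted: Sequence[StateSequence], annotated: AnnotatedHistory
) -> ErrorRates:
    """Pool predicted vs annotated states into confusion fractions.

    ``predicted`` holds one post-shift state sequence per subpopulation in
    label order; sequence slot ``k`` is scored against annotation row
    ``k + 1`` (the measurement the interval is attributed to).  The
    inoculation measurement (row 0) is not scored — the model fixes it at N.
    """
    history = annotated.history
    if len(predicted) != history.n_subpopulations:
        raise ValidationError(
            f"{len(predicted)} predicted sequences for "
            f"{history.n_subpopulations} subpopulations"
        )
    counts = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for j, seq in enumerate(predicted):
        if len(seq) != history.n_points - 1:
            raise ValidationError(
                f"sequence for {history.subpopulation_labels[j]!r} has length "
                f"{len(seq)}, expected {history.n_points - 1}"
            )
        for k, model_state in enumerate(seq.states):
            ann_state = annotated.states[k + 1, j]
            if model_state == "A":
                counts["tp" if ann_state == "A" else "fp"] += 1
            else:
                counts["fn" if ann_state == "A" else "tn"] += 1
    total = sum(counts.values())
    return ErrorRates(
        tp=counts["tp"] / total,
        tn=counts["tn"] / total,
        fp=counts["fp"] / total,
        fn=counts["fn"] / total,
        n_points=total,
    )


def summarize_dynamics(
    events: Sequence[AdaptiveEvent],
    rates: RateSeries,
    history: PopulationHistory,
    length_unit: str = "points",
) -> DynamicsSummary:
    """Summarize adaptive events of one experiment.

    ``ae_per_gen_color`` is the event count per elapsed generation per
    subpopulation; the expansion rate (rate of PEX) is the mean and sample sd
    of the per-interval expansion rates inside events; the event length is
    reported in measurement points by default (``length_unit="generations"``
    switches to generation spans).
    """
    if length_unit not in ("points", "generations"):
        raise ValidationError(f"length_unit must be 'points' or 'generations'")
    span = float(history.generations[-1] - history.generations[0])
    J = history.n_subpopulations
    if not events:
        warnings.warn("no adaptive events; dynamics summary is all zero", stacklevel=2)
        return DynamicsSummary(0.0, 0.0, 0.0, 0.0, 0.0, n_events=0)

    label_index = {label: j for j, label in enumerate(history.subpopulation_labels)}
    internal_rates: list[float] = []
    lengths: list[float] = []
    for event in events:
        j = label_index[event.subpopulation]
        internal_rates.extend(
            float(rates.r[k, j]) for k in range(event.start_index, event.end_index + 1)
        )
        lengths.append(
            float(event.duration_points)
            if length_unit == "points"
            else float(event.duration_gens)
        )

    def _sd(values: Sequence[float]) -> float:
        return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0

    return DynamicsSummary(
        ae_per_gen_color=len(events) / (span * J),
        rate_of_pex_mean=float(np.mean(internal_rates)),
        rate_of_pex_sd=_sd(internal_rates),
        ae_length_mean=float(np.mean(lengths)),
        ae_length_sd=_sd(lengths),
        n_events=len(events),
    )


def event_distribution(
    events_by_subpopulation: Mapping[str, Sequence[AdaptiveEvent]],
) -> dict[str, float]:
    """Length-weighted share of adaptive-event mass per subpopulation.

    ``share_j = sum of j's event durations / sum of all event durations``
    (durations in measurement points); shares sum to one per experiment.
    """
    durations = {
        label: float(sum(e.duration_points for e in events))
        for label, events in events_by_subpopulation.items()
    }
    total = sum(durations.values())
    if total <= 0:
        raise DegenerateInputError("no adaptive events; event distribution undefined")
    return {label: d / total for label, d in durations.items()}


__all__ = [
    "ErrorRates",
    "DynamicsSummary",
    "compare_annotations",
    "summarize_dynamics",
    "event_distribution",
]
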