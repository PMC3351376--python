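"""End-to-end analysis pipeline: calibrate -> classify -> decode -> events ->
sampling points, assembled into a serializable prediction report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .classifier import (
    EmissionSequence,
    NeutralCalibration,
    RateSeries,
    calibrate_neutral,
    classify_rates,
    compute_expansion_rates,
    compute_proportions,
)
from .errors import CalibrationError
from .hmm import AdaptiveEvent, PSMParameters, StateSequence, decode, extract_events
from .io import PopulationHistory
from .sampling import SamplingSuggestion, suggest_sampling_points

logger = logging.getLogger("vertpsm")


@dataclass(frozen=True)
class PredictionReport:
    """Per-subpopulation emissions, decoded states, events and sampling points."""

    history: PopulationHistory
    rates: RateSeries = field(repr=False)
    emissions: tuple[EmissionSequence, ...]
    states: tuple[StateSequence, ...]
    events: dict[str, list[AdaptiveEvent]]
    suggestions: dict[str, list[SamplingSuggestion]]
    calibration: NeutralCalibration | None = None


def run_pipeline(
    history: PopulationHistory,
    params: PSMParameters | None = None,
    calibration: NeutralCalibration | None = None,
    neutral_histories: Sequence[PopulationHistory] = (),
    alpha: float = 0.10,
    tails: int = 1,
    distribution: str = "t",
) -> PredictionReport:
    """Run the full analysis on one population history.

    A calibration may be supplied directly or derived from neutrality
    histories; providing neither is a configuration error.
    """
    if calibration is None:
        if not neutral_histories:
            raise CalibrationError(
                "no calibration supplied and no neutrality histories to derive one"
            )
        logger.info("calibrating from %d neutrality histories", len(neutral_histories))
        calibration = calibrate_neutral(
            [compute_expansion_rates(compute_proportions(h)) for h in neutral_histories]
        )
    logger.info(
        "calibration: mu_r=%.5g sigma_r=%.5g n=%d",
        calibration.mu_r,
        calibration.sigma_r,
        calibration.n_neutral,
    )
    params = params or PSMParameters.default()

    rates = compute_expansion_rates(compute_proportions(history))
    emissions = classify_rates(
        rates, calibration, alpha=alpha, tails=tails, distribution=distribution
    )
    logger.info("classified %d intervals x %d subpopulations", rates.n_intervals,
                history.n_subpopulations)

    states = tuple(decode(e, params) for e in emissions)
    events: dict[str, list[AdaptiveEvent]] = {}
    suggestions: dict[str, list[SamplingSuggestion]] = {}
    for seq, emis in zip(states, emissions):
        label = seq.subpopulation
        events[label] = extract_events(seq, history.generations)
        suggestions[label] = suggest_sampling_points(seq, emis, history.generations)
        logger.info("%s: %d adaptive events", label, len(events[label]))
    return PredictionReport(
        history=history,
        rates=rates,
        emissions=tuple(emissions),
        states=states,
        events=events,
        suggestions=suggestions,
        calibration=calibration,
    )


def report_frame(report: PredictionReport) -> pd.DataFrame:
    """Long-format view of a report: one row per measurement per subpopulation.

    Interval quantities (emission, state, event, sampling flag) are attributed
    to the measurement at the interval index plus one; the inoculation row
    carries the assumed initial state N and no emission.
    """
    history = report.history
    rows = []
    for j, label in enumerate(history.subpopulation_labels):
        emis = report.emissions[j].symbols
        states = report.states[j].states
        event_of = {}
        for eid, event in enumerate(report.events[label]):
            for k in range(event.start_index, event.end_index + 1):
                event_of[k] = eid
        sampling = {s.suggested_index for s in report.suggestions[label]}
        for m in range(history.n_points):
            k = m - 1
            rows.append(
                {
                    "time_index": m,
                    "generation": float(history.generations[m]),
                    "subpopulation": label,
                    "count": float(history.counts[m, j]),
                    "emission": emis[k] if m > 0 else "",
                    "state": states[k] if m > 0 else "N",
                    "event_id": event_of.get(k, -1) if m > 0 else -1,
                    "is_sampling_point": bool(m > 0 and k in sampling),
                }
            )
    return pd.DataFrame(rows)


def report_payload(report: PredictionReport) -> dict:
    """JSON-ready summary of events and sampling suggestions."""
    payload: dict = {
        "experiment_id": report.history.experiment_id,
        "subpopulations": {},
    }
    if report.calibration is not None:
        payload["calibration"] = {
            "mu_r": report.calibration.mu_r,
            "sigma_r": report.calibration.sigma_r,
            "n_neutral": report.calibration.n_neutral,
        }
    for j, label in enumerate(report.history.subpopulation_labels):
        payload["subpopulations"][label] = {
            "emissions": "".join(report.emissions[j].symbols),
            "states": "".join(report.states[j].states),
            "events": [
                {
                    "start_index": e.start_index,
                    "end_index": e.end_index,
                    "start_gen": e.start_gen,
                    "end_gen": e.end_gen,
                    "duration_points": e.duration_points,
                    "duration_gens": e.duration_gens,
                }
                for e in report.events[label]
            ],
            "sampling_points": [
                {
                    "suggested_index": s.suggested_index,
                    "suggested_generation": s.suggested_generation,
                    "event_start_index": s.event.start_index,
                    "event_end_index": s.event.end_index,
                }
                for s in report.suggestions[label]
            ],
        }
    return payload


def write_prediction_report(
    report: PredictionReport,
    csv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> None:
    if csv_path is not None:
        report_frame(report).to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(report_payload(report), indent=2) + "\n")


__all__ = [
    "PredictionReport",
    "run_pipeline",
    "report_frame",
    "report_payload",
    "write_prediction_report",
]
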