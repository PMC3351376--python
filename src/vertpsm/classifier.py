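"""Statistical classification of lineage-frequency slopes.

Raw FACS counts are converted to normalized proportion trajectories
(P_j0 = 1 for every subpopulation), differenced into per-generation expansion
rates, and each rate is tested against a neutral reference distribution
estimated from neutrality experiments.  Each inter-sample slope becomes one
emission symbol:

``P``  significantly positive slope (subpopulation expanding),
``N``  significantly negative slope (contracting),
``Z``  not significantly different from the neutral mean.

The test statistic is ``T = (r - mu_r) / (sigma_r / sqrt(n_neutral))`` with
``n_neutral - 1`` degrees of freedom, compared single-tailed (default) or
two-tailed against a Student-t (or optionally Gaussian) critical value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy import stats as sps

from .errors import (
    CalibrationError,
    DegenerateInputError,
    ParameterError,
    ValidationError,
)
from .io import PopulationHistory

EMISSION_ALPHABET = ("N", "Z", "P")


@dataclass(frozen=True)
class NormalizedTrajectories:
    """Per-subpopulation proportion trajectories normalized to start at 1.0."""

    P: np.ndarray = field(repr=False)
    generations: np.ndarray = field(repr=False)
    subpopulation_labels: tuple[str, ...] = ()


@dataclass(frozen=True)
class RateSeries:
    """Expansion rates r_pe (1/generation) for each inter-sample interval.

    ``r[k, j]`` is the slope of subpopulation ``j`` over the interval
    ``(t_k, t_{k+1})``.
    """

    r: np.ndarray = field(repr=False)
    generations: np.ndarray = field(repr=False)
    subpopulation_labels: tuple[str, ...] = ()

    @property
    def n_intervals(self) -> int:
        return self.r.shape[0]


@dataclass(frozen=True)
class NeutralCalibration:
    """Neutral slope statistics (mu_r, sigma_r) pooled from neutrality runs."""

    mu_r: float
    sigma_r: float
    n_neutral: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu_r):
            raise CalibrationError("mu_r must be finite")
        if not (self.sigma_r > 0):
            raise CalibrationError("sigma_r must be positive (zero-variance calibration)")
        if self.n_neutral < 2:
            raise CalibrationError("calibration needs at least two pooled slope measurements")

    def save(self, path: str | Path) -> None:
        payload = {
            "mu_r": float(self.mu_r),
            "sigma_r": float(self.sigma_r),
            "n_neutral": int(self.n_neutral),
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "NeutralCalibration":
        payload = yaml.safe_load(Path(path).read_text())
        try:
            return cls(
                mu_r=float(payload["mu_r"]),
                sigma_r=float(payload["sigma_r"]),
                n_neutral=int(payload["n_neutral"]),
            )
        except (KeyError, TypeError) as exc:
            raise CalibrationError(f"malformed calibration file {path}: {exc}") from exc


@dataclass(frozen=True)
class EmissionSequence:
    """Classified slope symbols for one subpopulation, one per interval."""

    symbols: tuple[str, ...]
    alpha: float
    subpopulation: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", tuple(self.symbols))
        bad = set(self.symbols) - set(EMISSION_ALPHABET)
        if bad:
            raise ValidationError(f"emission symbols outside {{P, N, Z}}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.symbols)


def compute_proportions(history: PopulationHistory) -> NormalizedTrajectories:
    """Normalize FACS counts to proportion trajectories with P_j0 = 1.

    ``P_ji = (x_ji / sum_j x_ji) / (x_j0 / sum_j x_j0)``: the subpopulation's
    proportion of the total reading at time i, divided by its initial
    proportion, so that every trajectory starts at exactly 1.0.
    """
    counts = history.counts
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise DegenerateInputError("zero total FACS count at a time point")
    proportions = counts / totals
    initial = proportions[0]
    if np.any(initial <= 0):
        zeros = [
            label
            for label, p0 in zip(history.subpopulation_labels, initial)
            if p0 <= 0
        ]
        raise CalibrationError(
            f"zero initial count for subpopulation(s) {zeros}; cannot normalize to P_j0 = 1"
        )
    P = proportions / initial
    P[0, :] = 1.0  # exact by construction
    return NormalizedTrajectories(
        P=P,
        generations=history.generations.copy(),
        subpopulation_labels=history.subpopulation_labels,
    )


def compute_expansion_rates(traj: NormalizedTrajectories) -> RateSeries:
    """Difference normalized trajectories into per-generation expansion rates."""
    gens = np.asarray(traj.generations, dtype=float)
    dt = np.diff(gens)
    if np.any(dt == 0):
        raise DegenerateInputError("duplicate generation values (zero-length interval)")
    rates = np.diff(traj.P, axis=0) / dt[:, None]
    return RateSeries(r=rates, generations=gens, subpopulation_labels=traj.subpopulation_labels)


def pooled_slopes(neutral_rates: Iterable[RateSeries]) -> np.ndarray:
    """Flatten all slopes from a collection of rate series into one pool."""
    chunks = [np.asarray(rs.r, dtype=float).ravel() for rs in neutral_rates]
    if not chunks:
        return np.empty(0)
    return np.concatenate(chunks)


def calibrate_neutral(neutral_rates: Sequence[RateSeries]) -> NeutralCalibration:
    """Estimate (mu_r, sigma_r, n) from pooled neutrality-experiment slopes."""
    slopes = pooled_slopes(neutral_rates)
    if slopes.size < 2:
        raise CalibrationError("calibration needs at least two pooled neutral slopes")
    sigma = float(np.std(slopes, ddof=1))
    if sigma == 0.0:
        raise CalibrationError("neutral slopes have zero variance (sigma_r = 0)")
    return NeutralCalibration(
        mu_r=float(np.mean(slopes)), sigma_r=sigma, n_neutral=int(slopes.size)
    )


def calibrate_neutral_per_label(
    neutral_rates: Sequence[RateSeries],
) -> dict[str, NeutralCalibration]:
    """Per-fluorophore variant of :func:`calibrate_neutral` (labels must match)."""
    by_label: dict[str, list[np.ndarray]] = {}
    for rs in neutral_rates:
        for j, label in enumerate(rs.subpopulation_labels):
            by_label.setdefault(label, []).append(np.asarray(rs.r[:, j], dtype=float))
    out: dict[str, NeutralCalibration] = {}
    for label, chunks in by_label.items():
        slopes = np.concatenate(chunks)
        if slopes.size < 2:
            raise CalibrationError(f"label {label!r}: fewer than two neutral slopes")
        sigma = float(np.std(slopes, ddof=1))
        if sigma == 0.0:
            raise CalibrationError(f"label {label!r}: zero-variance neutral slopes")
        out[label] = NeutralCalibration(
            mu_r=float(np.mean(slopes)), sigma_r=sigma, n_neutral=int(slopes.size)
        )
    return out


def critical_value(
    cal: NeutralCalibration, alpha: float, tails: int = 1, distribution: str = "t"
) -> float:
    """Critical |T| above which a slope is called significant."""
    if not (0.0 < alpha < 1.0):
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha}")
    if tails not in (1, 2):
        raise ParameterError(f"tails must be 1 or 2, got {tails}")
    level = alpha if tails == 1 else alpha / 2.0
    if distribution == "t":
        return float(sps.t.ppf(1.0 - level, df=cal.n_neutral - 1))
    if distribution == "normal":
        return float(sps.norm.ppf(1.0 - level))
    raise ParameterError(f"unknown distribution {distribution!r} (use 't' or 'normal')")


def classify_rates(
    rates: RateSeries,
    cal: NeutralCalibration,
    alpha: float = 0.10,
    tails: int = 1,
    distribution: str = "t",
) -> list[EmissionSequence]:
    """Classify every slope of every subpopulation into P/N/Z emission symbols.

    ``T = (r - mu_r) / (sigma_r / sqrt(n_neutral))`` is compared against the
    Student-t critical value with ``n_neutral - 1`` degrees of freedom;
    slopes exactly at the critical value are *not* rejected.  Significant
    slopes emit ``P`` when ``r > mu_r`` and ``N`` otherwise; everything else
    emits ``Z``.
    """
    crit = critical_value(cal, alpha, tails=tails, distribution=distribution)
    se = cal.sigma_r / math.sqrt(cal.n_neutral)
    T = (np.asarray(rates.r, dtype=float) - cal.mu_r) / se
    symbols = np.where(np.abs(T) > crit, np.where(T > 0, "P", "N"), "Z")
    labels = rates.subpopulation_labels or tuple(
        f"s{j + 1}" for j in range(rates.r.shape[1])
    )
    return [
        EmissionSequence(symbols=tuple(symbols[:, j]), alpha=alpha, subpopulation=label)
        for j, label in enumerate(labels)
    ]


__all__ = [
    "EMISSION_ALPHABET",
    "NormalizedTrajectories",
    "RateSeries",
    "NeutralCalibration",
    "EmissionSequence",
    "compute_proportions",
    "compute_expansion_rates",
    "calibrate_neutral",
    "calibrate_neutral_per_label",
    "pooled_slopes",
    "critical_value",
    "classify_rates",
]
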