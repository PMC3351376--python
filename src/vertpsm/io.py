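"""Reading and writing FACS population histories and annotations.

The CSV dialect is self-describing: the first column is ``generation``,
followed by one count column per labeled subpopulation.  Annotated files add
one ``<label>_state`` column per subpopulation holding ``A``/``N`` symbols,
one row per FACS measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

GENERATION_COLUMN = "generation"
STATE_SUFFIX = "_state"
STATE_ALPHABET = ("A", "N")


@dataclass(frozen=True)
class PopulationHistory:
    """A chemostat population history: FACS counts per subpopulation over time.

    Parameters
    ----------
    experiment_id
        Free-text identifier of the experiment.
    subpopulation_labels
        Ordered labels of the fluorescently marked subpopulations (J >= 2).
    generations
        Strictly increasing elapsed generations t_i at each measurement
        (n >= 2).
    counts
        ``(n, J)`` array of non-negative FACS counts x_ji.
    """

    experiment_id: str
    subpopulation_labels: tuple[str, ...]
    generations: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "subpopulation_labels", tuple(self.subpopulation_labels))
        gens = np.asarray(self.generations, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "generations", gens)
        object.__setattr__(self, "counts", counts)
        if gens.ndim != 1:
            raise ValidationError("generations must be one-dimensional")
        if counts.ndim != 2 or counts.shape != (gens.size, len(self.subpopulation_labels)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{gens.size} time points x {len(self.subpopulation_labels)} subpopulations"
            )
        if gens.size < 2:
            raise ValidationError("a population history needs at least two time points")
        if len(self.subpopulation_labels) < 2:
            raise ValidationError("a population history needs at least two subpopulations")
        if len(set(self.subpopulation_labels)) != len(self.subpopulation_labels):
            raise ValidationError("subpopulation labels must be unique")
        if not np.all(np.isfinite(gens)) or np.any(gens < 0):
            raise ValidationError("generations must be finite and non-negative")
        if np.any(np.diff(gens) <= 0):
            raise ValidationError("generations must be strictly increasing")
        if not np.all(np.isfinite(counts)) or np.any(counts < 0):
            raise ValidationError("counts must be finite and non-negative")
        if np.any(counts.sum(axis=1) <= 0):
            raise ValidationError("every time point needs at least one positive count")

    @property
    def n_points(self) -> int:
        return self.generations.size

    @property
    def n_subpopulations(self) -> int:
        return len(self.subpopulation_labels)


@dataclass(frozen=True)
class AnnotatedHistory:
    """A population history plus a human A/N state annotation per measurement."""

    history: PopulationHistory
    states: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype="<U1")
        object.__setattr__(self, "states", states)
        expected = (self.history.n_points, self.history.n_subpopulations)
        if states.shape != expected:
            raise ValidationError(
                f"annotation shape {states.shape} does not match history shape {expected}"
            )
        bad = set(np.unique(states)) - set(STATE_ALPHABET)
        if bad:
            raise ValidationError(f"annotation symbols outside {{A, N}}: {sorted(bad)}")


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if GENERATION_COLUMN not in frame.columns:
        raise FormatError(f"{path} is missing the '{GENERATION_COLUMN}' column")
    return frame


def read_population_history(path: str | Path, experiment_id: str | None = None) -> PopulationHistory:
    """Read a FACS population history CSV.

    Column order in the file defines subpopulation order.  Missing cells are
    an error; no imputation is attempted.
    """
    frame = _read_csv(path)
    labels = [c for c in frame.columns if c != GENERATION_COLUMN and not c.endswith(STATE_SUFFIX)]
    if len(labels) < 2:
        raise FormatError(f"{path} has fewer than two subpopulation count columns")
    if frame[labels + [GENERATION_COLUMN]].isna().any().any():
        raise ValidationError(f"{path} contains missing cells")
    return PopulationHistory(
        experiment_id=experiment_id or Path(path).stem,
        subpopulation_labels=tuple(labels),
        generations=frame[GENERATION_COLUMN].to_numpy(dtype=float),
        counts=frame[labels].to_numpy(dtype=float),
    )


def read_annotated_history(path: str | Path, experiment_id: str | None = None) -> AnnotatedHistory:
    """Read a history CSV that also carries ``<label>_state`` annotation columns."""
    history = read_population_history(path, experiment_id=experiment_id)
    frame = _read_csv(path)
    state_cols = [label + STATE_SUFFIX for label in history.subpopulation_labels]
    missing = [c for c in state_cols if c not in frame.columns]
    if missing:
        raise FormatError(f"{path} is missing annotation columns: {missing}")
    states = frame[state_cols]
    if states.isna().any().any():
        raise ValidationError(f"{path}: annotation columns are shorter than the history")
    return AnnotatedHistory(history=history, states=states.to_numpy(dtype="<U1"))


def write_population_history(history: PopulationHistory, path: str | Path) -> None:
    """Write a history in the package CSV dialect (round-trips with the reader)."""
    frame = pd.DataFrame({GENERATION_COLUMN: history.generations})
    for j, label in enumerate(history.subpopulation_labels):
        frame[label] = history.counts[:, j]
    frame.to_csv(path, index=False)


def write_annotated_history(annotated: AnnotatedHistory, path: str | Path) -> None:
    history = annotated.history
    frame = pd.DataFrame({GENERATION_COLUMN: history.generations})
    for j, label in enumerate(history.subpopulation_labels):
        frame[label] = history.counts[:, j]
    for j, label in enumerate(history.subpopulation_labels):
        frame[label + STATE_SUFFIX] = annotated.states[:, j]
    frame.to_csv(path, index=False)


def write_prediction_report(report, csv_path=None, json_path=None):
    """Serialize a :class:`~vertpsm.pipeline.PredictionReport` (thin wrapper)."""
    from .pipeline import write_prediction_report as _write

    return _write(report, csv_path=csv_path, json_path=json_path)


__all__ = [
    "PopulationHistory",
    "AnnotatedHistory",
    "read_population_history",
    "read_annotated_history",
    "write_population_history",
    "write_annotated_history",
    "write_prediction_report",
]
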