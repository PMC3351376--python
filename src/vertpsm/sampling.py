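"""Sampling-point suggestions for adaptive-mutant isolation.

For each adaptive event the emission sequence is scanned forward from the
event's end until the first significant contraction (``N`` symbol) at
position ``i``; the sample at ``i - 1`` is suggested as the one expected to
hold the mutant at its highest frequency.  If no contraction follows before
the series ends, the final measurement is suggested (the expanding lineage
has overrun the vessel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .classifier import EmissionSequence
from .errors import ValidationError
from .hmm import AdaptiveEvent, StateSequence, extract_events


@dataclass(frozen=True)
class SamplingSuggestion:
    """Recommended sampling point for one adaptive event."""

    subpopulation: str
    event: AdaptiveEvent
    suggested_index: int
    suggested_generation: float


def suggest_sampling_points(
    states: StateSequence,
    emissions: EmissionSequence,
    generations: Sequence[float],
) -> list[SamplingSuggestion]:
    """Suggest one sampling point per adaptive event of one subpopulation.

    ``states`` and ``emissions`` share the interval axis; ``generations`` is
    the full measurement axis (one element longer).  A suggestion that would
    precede the event's start (an immediate contraction) is clamped to the
    event's end, since a sample taken before the expansion cannot contain the
    mutant at its maximum frequency.
    """
    if len(states) != len(emissions):
        raise ValidationError(
            f"state sequence ({len(states)}) and emission sequence "
            f"({len(emissions)}) must have equal length"
        )
    events = extract_events(states, generations)
    symbols = emissions.symbols
    last = len(symbols) - 1

    suggestions: list[SamplingSuggestion] = []
    for event in events:
        found = next(
            (i for i in range(event.end_index, len(symbols)) if symbols[i] == "N"),
            None,
        )
        if found is None:
            index = last
        else:
            index = found - 1
            if index < event.start_index:
                index = event.end_index
        suggestions.append(
            SamplingSuggestion(
                subpopulation=states.subpopulation,
                event=event,
                suggested_index=index,
                suggested_generation=float(generations[index + 1]),
            )
        )

    for suggestion, event in zip(suggestions, events):
        for later in events:
            if later.start_index <= suggestion.suggested_index <= later.end_index and (
                later.start_index > event.end_index
            ):
                warnings.warn(
                    f"sampling suggestion {suggestion.suggested_index} for event "
                    f"[{event.start_index}, {event.end_index}] falls inside the later "
                    f"event [{later.start_index}, {later.end_index}] "
                    f"({states.subpopulation})",
                    stacklevel=2,
                )
    return suggestions


__all__ = ["SamplingSuggestion", "suggest_sampling_points"]
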