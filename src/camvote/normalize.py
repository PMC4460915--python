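"""Canonicalization of classification events before aggregation.

Volunteers sometimes listed the same species twice within one answer to
record two behaviours ('1 zebra, standing' and '1 zebra, moving'). Before
the consensus algorithm runs, such duplicates are merged into a single
annotation per species: counts are summed on the ordinal bin scale
('2 zebras') and behaviour/young flags are OR-ed ('standing and moving').
Merging happens strictly within one ClassificationID — never across
volunteers.
"""

from __future__ import annotations

from typing import Iterable, Iterator

from .counts import CountBin, combine_counts
from .tables_io import ClassificationEvent, SpeciesAnnotation

__all__ = ["combine_counts", "merge_duplicate_species", "normalize_stream"]


def merge_duplicate_species(event: ClassificationEvent) -> ClassificationEvent:
    """Merge repeated species annotations within one classification.

    Idempotent; annotation order follows first appearance of each species.
    """
    merged: dict[str, SpeciesAnnotation] = {}
    for ann in event.annotations:
        prev = merged.get(ann.species)
        if prev is None:
            merged[ann.species] = ann
        else:
            merged[ann.species] = SpeciesAnnotation(
                species=ann.species,
                count=combine_counts(prev.count, ann.count),
                standing=prev.standing or ann.standing,
                resting=prev.resting or ann.resting,
                moving=prev.moving or ann.moving,
                eating=prev.eating or ann.eating,
                interacting=prev.interacting or ann.interacting,
                babies=prev.babies or ann.babies,
            )
    if len(merged) == len(event.annotations):
        return event
    return ClassificationEvent(
        capture_event_id=event.capture_event_id,
        classification_id=event.classification_id,
        user_id=event.user_id,
        annotations=tuple(merged.values()),
    )


def normalize_stream(
    events: Iterable[ClassificationEvent],
) -> Iterator[ClassificationEvent]:
    """Apply :func:`merge_duplicate_species` to every event in a stream."""
    for event in events:
        yield merge_duplicate_species(event)
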