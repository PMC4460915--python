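"""Plurality consensus: one aggregated answer per capture event.

The algorithm turns the pile of per-volunteer classifications for an image
set into a single record per species present:

1. Species richness ``S*`` is the median, over non-blank classifications,
   of the number of distinct species each volunteer named (half-integer
   medians round *down*, floored at 1).
2. The ``S*`` species with the most votes become the aggregated answer;
   ties at the cut are broken by vote count then alphabetical label and
   flagged.
3. Per winning species: the count is the ordinal median of reported count
   bins, and each behaviour (and 'young present') becomes the proportion of
   classifications naming that species which flagged it.
4. Certainty metrics: Pielou's evenness of the vote distribution,
   −(Σ pᵢ ln pᵢ)/ln S over non-blank species votes, defined as 0 when all
   classifications agree; and per-species percent support,
   NumVotes/NumClassifications.

Capture events whose classifications are all blank produce no output: the
consensus table covers animal-containing image sets only.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

from .counts import CountBin, ordinal_median
from .tables_io import (
    BEHAVIOURS,
    CaptureMetadata,
    ClassificationEvent,
    ConsensusRecord,
)

__all__ = [
    "VoteTally",
    "NoNonBlankError",
    "median_species_richness",
    "plurality_species",
    "median_count",
    "behaviour_proportions",
    "pielou_evenness",
    "percent_support",
    "aggregate_capture_event",
    "aggregate_stream",
]


class NoNonBlankError(ValueError):
    """Every classification for the event was 'nothing here'."""


@dataclasses.dataclass(frozen=True)
class VoteTally:
    """Vote counts for one capture event.

    ``votes[s]`` is the number of volunteers whose classification included
    species ``s``; ``n_classifications`` counts all volunteers including
    those answering blank; ``n_blanks`` counts the blanks.
    """

    votes: Mapping[str, int]
    n_classifications: int
    n_blanks: int

    def __post_init__(self) -> None:
        if self.n_blanks > self.n_classifications:
            raise ValueError("more blanks than classifications")
        for s, v in self.votes.items():
            if not 0 < v <= self.n_classifications:
                raise ValueError(f"vote count for {s!r} out of range: {v}")

    @classmethod
    def from_events(cls, events: Sequence[ClassificationEvent]) -> "VoteTally":
        votes: dict[str, int] = {}
        n_blanks = 0
        for ev in events:
            if ev.is_blank:
                n_blanks += 1
                continue
            for species in ev.species_set:
                votes[species] = votes.get(species, 0) + 1
        return cls(votes=votes, n_classifications=len(events), n_blanks=n_blanks)


def median_species_richness(events: Sequence[ClassificationEvent]) -> int:
    """Median number of distinct species named per non-blank classification.

    Half-integer medians round down; the result is never below 1.
    """
    sizes = sorted(len(ev.species_set) for ev in events if not ev.is_blank)
    if not sizes:
        raise NoNonBlankError("species richness undefined without non-blank answers")
    n = len(sizes)
    if n % 2:
        med = sizes[n // 2]
    else:
        med = (sizes[n // 2 - 1] + sizes[n // 2]) // 2  # floor of half-integer
    return max(1, med)


def plurality_species(tally: VoteTally, s_star: int) -> tuple[list[str], bool]:
    """The ``s_star`` most-voted species, plus a tie flag.

    Ordering is by vote count descending then label ascending, which makes
    the selection deterministic. The tie flag is set when a species just
    outside the cut has the same vote count as the last species inside it —
    i.e. when the plurality answer is not unique.
    """
    if not tally.votes:
        raise NoNonBlankError("no species votes to rank")
    ranked = sorted(tally.votes.items(), key=lambda kv: (-kv[1], kv[0]))
    k = min(s_star, len(ranked))
    tie = len(ranked) > k and ranked[k][1] == ranked[k - 1][1]
    return [species for species, _ in ranked[:k]], tie


def _events_with(
    events: Sequence[ClassificationEvent], species: str
) -> list[ClassificationEvent]:
    hits = [ev for ev in events if species in ev.species_set]
    if not hits:
        raise ValueError(f"no classification names species {species!r}")
    return hits


def median_count(
    events: Sequence[ClassificationEvent], species: str
) -> CountBin:
    """Ordinal median of the count bins reported for ``species``; the lower
    middle bin is taken for even-length inputs."""
    bins = [
        ann.count
        for ev in _events_with(events, species)
        for ann in ev.annotations
        if ann.species == species
    ]
    return ordinal_median(bins)


def behaviour_proportions(
    events: Sequence[ClassificationEvent], species: str
) -> dict[str, float]:
    """Proportion of classifications naming ``species`` that flagged each
    behaviour (and young), keys ``standing`` ... ``interacting``, ``babies``."""
    hits = _events_with(events, species)
    props: dict[str, float] = {}
    for flag in BEHAVIOURS + ("babies",):
        n_true = sum(
            1
            for ev in hits
            if any(a.species == species and getattr(a, flag) for a in ev.annotations)
        )
        props[flag] = n_true / len(hits)
    return props


def pielou_evenness(tally: VoteTally) -> float:
    """Pielou's evenness of the species-vote distribution.

    With ``S`` distinct species voted and ``p_i`` each species' share of all
    species votes: 0 when all classifications agree (S = 1), otherwise
    −(Σ pᵢ ln pᵢ)/ln S. Ranges over [0, 1]; 0 signals high certainty, 1 a
    maximally split vote. Blank answers never enter the tally.
    """
    if not tally.votes:
        raise NoNonBlankError("evenness undefined without non-blank votes")
    counts = list(tally.votes.values())
    s = len(counts)
    if s == 1:
        return 0.0
    total = sum(counts)
    h = -sum((c / total) * math.log(c / total) for c in counts)
    return h / math.log(s)


def percent_support(tally: VoteTally, species: str) -> float:
    """NumVotes/NumClassifications for ``species``; the denominator includes
    blank answers."""
    if species not in tally.votes:
        raise ValueError(f"species {species!r} not in tally")
    return tally.votes[species] / tally.n_classifications


def aggregate_capture_event(
    events: Sequence[ClassificationEvent],
    metadata: CaptureMetadata | None = None,
) -> list[ConsensusRecord]:
    """Aggregate all classifications of one capture event.

    Returns one record per plurality species; an all-blank event yields an
    empty list. ``events`` should already be normalized (duplicate species
    merged within each classification).
    """
    if not events:
        return []
    ids = {ev.capture_event_id for ev in events}
    if len(ids) != 1:
        raise ValueError(f"events span multiple capture events: {sorted(ids)}")
    if all(ev.is_blank for ev in events):
        return []
    if metadata is None:
        metadata = CaptureMetadata(capture_event_id=next(iter(ids)))

    tally = VoteTally.from_events(events)
    s_star = median_species_richness(events)
    winners, tie = plurality_species(tally, s_star)
    evenness = pielou_evenness(tally)

    records = []
    for species in winners:
        props = behaviour_proportions(events, species)
        records.append(
            ConsensusRecord(
                metadata=metadata,
                num_species=len(winners),
                species=species,
                count=median_count(events, species),
                standing=props["standing"],
                resting=props["resting"],
                moving=props["moving"],
                eating=props["eating"],
                interacting=props["interacting"],
                babies=props["babies"],
                num_classifications=tally.n_classifications,
                num_votes=tally.votes[species],
                num_blanks=tally.n_blanks,
                evenness=evenness,
                tie=tie,
                percent_support=percent_support(tally, species),
            )
        )
    return records


def aggregate_stream(
    events: Iterable[ClassificationEvent],
    metadata: Mapping[str, CaptureMetadata] | None = None,
) -> list[ConsensusRecord]:
    """Group a classification stream by capture event and aggregate each.

    Events for one capture event need not be contiguous; output follows
    first appearance order of capture events.
    """
    grouped: dict[str, list[ClassificationEvent]] = {}
    for ev in events:
        grouped.setdefault(ev.capture_event_id, []).append(ev)
    records: list[ConsensusRecord] = []
    for cid, evs in grouped.items():
        meta = metadata.get(cid) if metadata else None
        records.extend(aggregate_capture_event(evs, meta))
    return records
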