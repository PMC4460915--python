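"""Validation of consensus output against expert gold-standard labels.

An expert panel classified a subset of capture events; comparing the
plurality consensus to those labels yields an overall accuracy, a
per-species accuracy table, a mismatch taxonomy, count-bin agreement and
the separation in evenness between correct and incorrect answers. Events
the experts marked ``impossible`` count as incorrect by definition, since
volunteers are never offered that option.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .tables_io import ConsensusRecord, GoldRecord
from .vocabulary import IMPOSSIBLE

__all__ = [
    "CORRECT",
    "IMPOSSIBLE_CATEGORY",
    "MISSED_SPECIES",
    "EXTRA_SPECIES",
    "WRONG_SPECIES",
    "MatchOutcome",
    "match_event",
    "match_all",
    "overall_accuracy",
    "mismatch_breakdown",
    "accuracy_by_species",
    "count_agreement",
    "evenness_separation",
]

CORRECT = "correct"
IMPOSSIBLE_CATEGORY = "impossible"
MISSED_SPECIES = "missed_species"
EXTRA_SPECIES = "extra_species"
WRONG_SPECIES = "wrong_species"

CATEGORIES = (
    CORRECT,
    IMPOSSIBLE_CATEGORY,
    MISSED_SPECIES,
    EXTRA_SPECIES,
    WRONG_SPECIES,
)


@dataclasses.dataclass(frozen=True)
class MatchOutcome:
    """Agreement category for one gold-covered capture event."""

    capture_event_id: str
    category: str
    evenness: float

    @property
    def is_correct(self) -> bool:
        return self.category == CORRECT


def _gold_species_set(gold: Sequence[GoldRecord]) -> frozenset[str]:
    return frozenset(g.species for g in gold if not g.is_impossible)


def match_event(
    consensus: Sequence[ConsensusRecord], gold: Sequence[GoldRecord]
) -> MatchOutcome:
    """Categorise the consensus answer for one event against its gold rows.

    ``correct`` when the species sets agree exactly; ``impossible`` when
    experts declared the image unidentifiable (incorrect by definition);
    ``missed_species`` / ``extra_species`` for strict subset/superset;
    ``wrong_species`` otherwise.
    """
    if not gold:
        raise ValueError("event is not covered by the gold standard")
    ids = {g.capture_event_id for g in gold} | {c.capture_event_id for c in consensus}
    if len(ids) != 1:
        raise ValueError(f"records span multiple capture events: {sorted(ids)}")
    evenness = consensus[0].evenness if consensus else math.nan

    if any(g.is_impossible for g in gold):
        return MatchOutcome(ids.pop(), IMPOSSIBLE_CATEGORY, evenness)

    got = frozenset(c.species for c in consensus)
    want = _gold_species_set(gold)
    if got == want:
        category = CORRECT
    elif got < want:
        category = MISSED_SPECIES
    elif got > want:
        category = EXTRA_SPECIES
    else:
        category = WRONG_SPECIES
    return MatchOutcome(ids.pop(), category, evenness)


def _group_by_event(records: Iterable) -> dict[str, list]:
    out: dict[str, list] = {}
    for r in records:
        out.setdefault(r.capture_event_id, []).append(r)
    return out


def match_all(
    consensus: Iterable[ConsensusRecord], gold: Iterable[GoldRecord]
) -> list[MatchOutcome]:
    """Match every gold-covered capture event; consensus records without
    gold coverage are ignored."""
    by_gold = _group_by_event(gold)
    by_cons = _group_by_event(consensus)
    return [
        match_event(by_cons.get(cid, []), gold_rows)
        for cid, gold_rows in by_gold.items()
    ]


def overall_accuracy(outcomes: Sequence[MatchOutcome]) -> float:
    """Share of gold-covered events whose consensus species set is exactly
    right (impossible events count against)."""
    if not outcomes:
        raise ValueError("no outcomes")
    return sum(o.is_correct for o in outcomes) / len(outcomes)


def mismatch_breakdown(outcomes: Sequence[MatchOutcome]) -> pd.Series:
    """Counts of the non-correct categories among mismatched events."""
    mism = [o.category for o in outcomes if not o.is_correct]
    return pd.Series(mism, dtype="object").value_counts().reindex(
        [IMPOSSIBLE_CATEGORY, MISSED_SPECIES, EXTRA_SPECIES, WRONG_SPECIES],
        fill_value=0,
    )


def accuracy_by_species(
    outcomes: Sequence[MatchOutcome], gold: Iterable[GoldRecord]
) -> pd.DataFrame:
    """Per-species accuracy over gold-covered events.

    For each species the experts reported: the number of events containing
    it, how many of those the consensus got entirely right, and the ratio.
    Impossible events are excluded. Columns: ``species``, ``n_correct``,
    ``n_total``, ``proportion``; sorted by ``n_total`` descending.
    """
    correct_ids = {o.capture_event_id for o in outcomes if o.is_correct}
    counted_ids = {
        o.capture_event_id
        for o in outcomes
        if o.category != IMPOSSIBLE_CATEGORY
    }
    totals: dict[str, int] = {}
    corrects: dict[str, int] = {}
    for g in gold:
        if g.is_impossible or g.capture_event_id not in counted_ids:
            continue
        totals[g.species] = totals.get(g.species, 0) + 1
        if g.capture_event_id in correct_ids:
            corrects[g.species] = corrects.get(g.species, 0) + 1
    rows = [
        (s, corrects.get(s, 0), n, corrects.get(s, 0) / n)
        for s, n in totals.items()
    ]
    df = pd.DataFrame(rows, columns=["species", "n_correct", "n_total", "proportion"])
    return df.sort_values(
        ["n_total", "species"], ascending=[False, True], ignore_index=True
    )


def count_agreement(
    consensus: Iterable[ConsensusRecord],
    gold: Iterable[GoldRecord],
    *,
    single_species_only: bool = False,
) -> pd.DataFrame:
    """Per-bin agreement between consensus and expert counts.

    Restricted to events where the consensus species set is exact or a
    subset of the gold set (elsewhere there is no species to compare), and
    within those to species the consensus actually reported. With
    ``single_species_only`` the comparison further keeps only events whose
    gold answer is a single species. Returns one row per gold count bin:
    ``bin``, ``n``, ``prop_exact``, ``prop_within_1`` ("within one bin" is
    ordinal adjacency, so 10 and 11-50 are adjacent), plus a ``pooled``
    summary row.
    """
    by_gold = _group_by_event(gold)
    by_cons = _group_by_event(consensus)
    pairs: list[tuple[str, int]] = []  # (gold bin label, ordinal distance)
    for cid, gold_rows in by_gold.items():
        cons_rows = by_cons.get(cid, [])
        if not cons_rows or any(g.is_impossible for g in gold_rows):
            continue
        got = frozenset(c.species for c in cons_rows)
        want = _gold_species_set(gold_rows)
        if not got <= want:
            continue
        if single_species_only and len(want) != 1:
            continue
        gold_count = {g.species: g.count for g in gold_rows}
        for c in cons_rows:
            gb = gold_count.get(c.species)
            if gb is None:
                continue
            pairs.append((gb.label, c.count.distance(gb)))
    frame = pd.DataFrame(pairs, columns=["bin", "distance"])
    rows = []
    for label, sub in frame.groupby("bin", sort=False):
        rows.append(
            (
                label,
                len(sub),
                (sub["distance"] == 0).mean(),
                (sub["distance"] <= 1).mean(),
            )
        )
    if len(frame):
        rows.append(
            (
                "pooled",
                len(frame),
                (frame["distance"] == 0).mean(),
                (frame["distance"] <= 1).mean(),
            )
        )
    return pd.DataFrame(rows, columns=["bin", "n", "prop_exact", "prop_within_1"])


def evenness_separation(
    outcomes: Sequence[MatchOutcome],
) -> dict[str, tuple[float, float]]:
    """Mean and standard error of evenness for correct vs incorrect events.

    Returns ``{"correct": (mean, se), "incorrect": (mean, se)}``; a group
    with no members (or only missing evenness) maps to ``(nan, nan)``.
    Difficult images attract disagreement, so the incorrect group is
    expected to sit higher.
    """
    out: dict[str, tuple[float, float]] = {}
    for name, keep in (("correct", True), ("incorrect", False)):
        vals = pd.Series(
            [o.evenness for o in outcomes if o.is_correct == keep], dtype=float
        ).dropna()
        if vals.empty:
            out[name] = (math.nan, math.nan)
        else:
            se = vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else 0.0
            out[name] = (vals.mean(), se)
    return out
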