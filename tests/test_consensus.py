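"""Plurality aggregation, certainty metrics, and their invariants."""

import math
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from camvote.consensus import (
    NoNonBlankError,
    VoteTally,
    aggregate_capture_event,
    aggregate_stream,
    behaviour_proportions,
    median_count,
    median_species_richness,
    percent_support,
    pielou_evenness,
    plurality_species,
)

from conftest import blank_event, make_event


# -- species richness -------------------------------------------------------

@pytest.mark.parametrize(
    "sizes, expected",
    [
        ([1, 1, 1, 1, 1], 1),
        ([1, 1, 2, 2, 2], 2),
        ([1, 1, 2, 2], 1),  # half-integer median rounds down
        ([2], 2),
        ([1, 3], 2),
    ],
)
def test_median_species_richness(sizes, expected):
    pool = ["zebra", "wildebeest", "topi", "eland"]
    events = [
        make_event("E", i, {sp: 1 for sp in pool[:k]}) for i, k in enumerate(sizes)
    ]
    assert median_species_richness(events) == expected


def test_richness_ignores_blanks_and_errors_without_nonblank():
    events = [blank_event("E", 0), make_event("E", 1, {"zebra": 1})]
    assert median_species_richness(events) == 1
    with pytest.raises(NoNonBlankError):
        median_species_richness([blank_event("E", 0)])


# -- plurality selection ----------------------------------------------------

def test_plurality_picks_top_votes():
    tally = VoteTally(
        votes={"spotted hyena": 10, "warthog": 2, "jackal": 1, "wildcat": 1},
        n_classifications=14,
        n_blanks=0,
    )
    winners, tie = plurality_species(tally, 1)
    assert winners == ["spotted hyena"] and not tie


def test_plurality_tie_flagged_and_deterministic():
    tally = VoteTally(
        votes={"impala": 5, "grant's gazelle": 5, "dik dik": 5},
        n_classifications=25,
        n_blanks=3,
    )
    winners, tie = plurality_species(tally, 1)
    assert tie
    assert winners == ["dik dik"]  # votes desc, then alphabetical


def test_plurality_two_species():
    tally = VoteTally(
        votes={"wildebeest": 12, "zebra": 10, "topi": 2},
        n_classifications=12,
        n_blanks=0,
    )
    winners, tie = plurality_species(tally, 2)
    assert winners == ["wildebeest", "zebra"] and not tie


# -- per-species summaries --------------------------------------------------

def test_median_count_lower_middle(giraffe_events):
    assert median_count(giraffe_events, "giraffe").label == "1"
    events = [
        make_event("E", 0, {"zebra": "10"}),
        make_event("E", 1, {"zebra": "11-50"}),
    ]
    assert median_count(events, "zebra").label == "10"
    with pytest.raises(ValueError):
        median_count(events, "eland")


def test_behaviour_proportions_condition_on_species(giraffe_events):
    props = behaviour_proportions(giraffe_events, "giraffe")
    assert props["moving"] == pytest.approx(0.9)
    assert props["standing"] == pytest.approx(0.1)
    assert props["babies"] == 0.0


# -- certainty metrics ------------------------------------------------------

def test_evenness_zero_on_unanimity_and_one_on_even_split():
    unanimous = VoteTally(votes={"giraffe": 10}, n_classifications=10, n_blanks=0)
    assert pielou_evenness(unanimous) == 0.0
    split = VoteTally(votes={"zebra": 5, "topi": 5}, n_classifications=10, n_blanks=0)
    assert pielou_evenness(split) == pytest.approx(1.0)


def test_evenness_matches_direct_formula_on_random_tallies():
    """Oracle equivalence on 1,000 random tallies at 1e-12 relative tol."""
    rng = random.Random(150_026)
    pool = ["zebra", "topi", "eland", "impala", "giraffe", "warthog", "buffalo"]
    for _ in range(1000):
        s = rng.randint(1, len(pool))
        votes = {sp: rng.randint(1, 30) for sp in pool[:s]}
        tally = VoteTally(votes=votes, n_classifications=300, n_blanks=0)
        got = pielou_evenness(tally)
        if s == 1:
            assert got == 0.0
            continue
        total = sum(votes.values())
        p = [v / total for v in votes.values()]
        expected = -sum(pi * math.log(pi) for pi in p) / math.log(s)
        assert got == pytest.approx(expected, rel=1e-12)
        assert 0.0 <= got <= 1.0 + 1e-12


def test_percent_support_counts_blanks_in_denominator(hyena_events):
    tally = VoteTally.from_events(hyena_events)
    assert percent_support(tally, "spotted hyena") == pytest.approx(10 / 14)
    with_blanks = VoteTally(votes={"zebra": 5}, n_classifications=25, n_blanks=20)
    assert percent_support(with_blanks, "zebra") == pytest.approx(0.2)


# -- full aggregation -------------------------------------------------------

def test_aggregate_unanimous_giraffe(giraffe_events):
    (rec,) = aggregate_capture_event(giraffe_events)
    assert rec.species == "giraffe"
    assert rec.count.label == "1"
    assert rec.evenness == 0.0
    assert rec.num_votes == rec.num_classifications == 10
    assert rec.num_blanks == 0 and not rec.tie


def test_aggregate_all_blank_emits_nothing():
    assert aggregate_capture_event([blank_event("E", i) for i in range(5)]) == []
    assert aggregate_capture_event([]) == []


def test_aggregate_two_species_event():
    events = [
        make_event("E", i, {"wildebeest": 3, "zebra": 2}) for i in range(8)
    ] + [make_event("E", 8, {"wildebeest": 3})]
    records = aggregate_capture_event(events)
    assert [r.species for r in records] == ["wildebeest", "zebra"]
    assert all(r.num_species == 2 for r in records)
    assert records[0].num_votes == 9 and records[1].num_votes == 8
    assert records[0].evenness == records[1].evenness > 0


def test_aggregate_is_permutation_invariant(hyena_events):
    rng = random.Random(7)
    base = aggregate_capture_event(hyena_events)
    for _ in range(5):
        shuffled = hyena_events[:]
        rng.shuffle(shuffled)
        assert aggregate_capture_event(shuffled) == base


def test_vote_conservation(antelope_events):
    records = aggregate_capture_event(antelope_events)
    named = sum(len(ev.species_set) for ev in antelope_events)
    assert sum(r.num_votes for r in records) <= named


@given(st.integers(1, 12), st.integers(0, 6))
def test_extra_vote_for_winner_never_dethrones(winner_votes, gap):
    votes = {"zebra": winner_votes + gap, "topi": winner_votes}
    tally = VoteTally(votes=votes, n_classifications=50, n_blanks=0)
    before, _ = plurality_species(tally, 1)
    bumped = VoteTally(
        votes={**votes, before[0]: votes[before[0]] + 1},
        n_classifications=51,
        n_blanks=0,
    )
    after, _ = plurality_species(bumped, 1)
    assert after == before


def test_aggregate_stream_groups_noncontiguous_events(giraffe_events, hyena_events):
    interleaved = [ev for pair in zip(giraffe_events, hyena_events) for ev in pair]
    interleaved += hyena_events[10:]
    records = aggregate_stream(interleaved)
    assert {r.species for r in records} == {"giraffe", "spotted hyena"}
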