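"""Synthetic scene and volunteer generator: determinism, calibration,
error-structure bounds."""

import numpy as np
import pytest
from scipy import stats

from camvote.consensus import aggregate_stream
from camvote.normalize import normalize_stream
from camvote.simulate import (
    SimulationConfig,
    build_confusion,
    classification_accuracy,
    generate_classifications,
    generate_gold,
    generate_scenes,
    generate_volunteers,
)
from camvote.vocabulary import IMPOSSIBLE, SPECIES


def _binomial_bounds(n, p, level=0.99):
    lo, hi = stats.binom.interval(level, n, p)
    return lo, hi


def test_generate_scenes_edge_cases():
    assert generate_scenes(0) == []
    config = SimulationConfig(blank_fraction=1.0)
    assert all(s.is_blank for s in generate_scenes(200, config, seed=1))
    config = SimulationConfig(blank_fraction=0.0)
    assert not any(s.is_blank for s in generate_scenes(200, config, seed=1))


def test_blank_fraction_within_binomial_bounds():
    n = 1000
    scenes = generate_scenes(n, SimulationConfig(blank_fraction=0.73), seed=42)
    n_blank = sum(s.is_blank for s in scenes)
    lo, hi = _binomial_bounds(n, 0.73)
    assert lo <= n_blank <= hi


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(blank_fraction=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(prevalence={"unicorn": 1.0})
    with pytest.raises(ValueError):
        SimulationConfig.from_dict({"no_such_key": 1})


def test_confusion_rows_are_stochastic():
    mat = build_confusion(0.85)
    assert mat.shape == (48, 48)
    assert np.allclose(mat.sum(axis=1), 1.0)
    assert np.allclose(np.diag(mat), 0.85)


def test_fixed_seed_reproduces_everything():
    config = SimulationConfig(n_volunteers=10)
    runs = []
    for _ in range(2):
        scenes = generate_scenes(50, config, seed=7)
        volunteers = generate_volunteers(config, seed=8)
        events = generate_classifications(scenes, volunteers, 5, seed=9, config=config)
        gold = generate_gold(scenes, 0.1, seed=10)
        runs.append((scenes, events, gold))
    assert runs[0] == runs[1]


def test_perfect_volunteers_reproduce_truth_exactly():
    config = SimulationConfig(
        blank_fraction=0.3,
        volunteer_accuracy=1.0,
        blank_propensity=0.0,
        count_noise_step=0.0,
        behaviour_error=0.0,
        two_species_fraction=0.2,
        n_volunteers=30,
    )
    scenes = generate_scenes(100, config, seed=3)
    volunteers = generate_volunteers(config, seed=4)
    events = generate_classifications(scenes, volunteers, 10, seed=5, config=config)
    truth = {s.capture_event_id: s for s in scenes}
    for ev in events:
        scene = truth[ev.capture_event_id]
        assert ev.species_set == frozenset(scene.species)
        for ann in ev.annotations:
            assert ann.count == scene.species[ann.species]
    assert classification_accuracy(events, scenes) == 1.0
    records = aggregate_stream(normalize_stream(events))
    by_event = {}
    for r in records:
        by_event.setdefault(r.capture_event_id, set()).add(r.species)
    for s in scenes:
        if not s.is_blank:
            assert by_event[s.capture_event_id] == set(s.species)


def test_gazelle_confusion_rate_within_bounds():
    """A 10% Thomson's->Grant's swap shows up at the configured rate."""
    n_scenes = 400
    config = SimulationConfig(
        blank_fraction=0.0,
        two_species_fraction=0.0,
        prevalence={"thomson's gazelle": 1.0},
        volunteer_accuracy=0.9,
        confusable_weight=1.0,  # all error mass on the look-alike partners
        blank_propensity=0.0,
        n_volunteers=50,
    )
    scenes = generate_scenes(n_scenes, config, seed=11)
    volunteers = generate_volunteers(config, seed=12)
    events = generate_classifications(scenes, volunteers, 1, seed=13, config=config)
    reported = [next(iter(ev.species_set)) for ev in events]
    n_swapped = sum(r != "thomson's gazelle" for r in reported)
    lo, hi = _binomial_bounds(n_scenes, 0.10)
    assert lo <= n_swapped <= hi
    partners = {"grant's gazelle", "impala"}
    assert all(r in partners | {"thomson's gazelle"} for r in reported)


def test_blank_propensity_scales_with_difficulty():
    config = SimulationConfig(
        blank_fraction=0.0,
        volunteer_accuracy=1.0,
        blank_propensity=1.0,
        difficulty_alpha=5.0,
        difficulty_beta=1.0,  # hard images
        n_volunteers=20,
    )
    scenes = generate_scenes(150, config, seed=21)
    volunteers = generate_volunteers(config, seed=22)
    events = generate_classifications(scenes, volunteers, 10, seed=23, config=config)
    blank_share = sum(ev.is_blank for ev in events) / len(events)
    expected = float(np.mean([s.difficulty for s in scenes]))
    assert blank_share == pytest.approx(expected, abs=0.05)


def test_gold_impossible_fraction_within_bounds():
    config = SimulationConfig(blank_fraction=0.0)
    scenes = generate_scenes(10_000, config, seed=31)
    gold = generate_gold(scenes, impossible_fraction=0.002, seed=32)
    n_impossible = sum(g.is_impossible for g in gold)
    lo, hi = _binomial_bounds(10_000, 0.002)
    assert lo <= n_impossible <= hi
    assert all(g.count is None for g in gold if g.is_impossible)


def test_gold_fraction_edge_cases(small_survey):
    scenes = small_survey["scenes"]
    animal = [s for s in scenes if not s.is_blank]
    exact = generate_gold(scenes, 0.0, seed=1)
    assert len(exact) == sum(len(s.species) for s in animal)
    assert not any(g.is_impossible for g in exact)
    all_imp = generate_gold(scenes, 1.0, seed=1)
    assert all(g.is_impossible for g in all_imp)
    assert len(all_imp) == len(animal)


def test_simulated_raw_table_round_trips(small_survey, tmp_path):
    from camvote.tables_io import read_raw_classifications, write_raw_classifications

    path = tmp_path / "raw.csv"
    with open(path, "w") as fh:
        write_raw_classifications(small_survey["events"], fh)
    back = list(read_raw_classifications(path))
    assert back == small_survey["events"]
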