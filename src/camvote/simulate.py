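"""Synthetic camera-trap scenes and volunteer classification streams.

The generator emulates the statistical structure of a large citizen-science
camera survey so that every pipeline stage — retirement, normalization,
consensus, validation — can be exercised end to end without any external
download:

* **Scenes** mimic capture events: most triggers are misfires (no animal;
  the default blank fraction of 0.73 matches the roughly three-quarters of
  real triggers set off by heat or vegetation), the rest carry one or
  occasionally two species drawn from the observed relative frequencies of
  the 48 species options, a true count on the ordinal bin scale, true
  behaviour flags, and a difficulty score in [0, 1].
* **Volunteers** carry a row-stochastic confusion matrix over the species
  vocabulary (errors concentrate on look-alike pairs such as the two
  gazelles), a blank-when-unsure propensity that scales with scene
  difficulty — real volunteers pressed 'nothing here' rather than guess on
  hard images — plus geometric-tailed count displacement on the ordinal
  scale and independent behaviour-flag flips.
* **Gold tables** equal the truth except for a seeded fraction marked
  ``impossible`` (default 0.2%, the rate at which real expert panels gave
  up on an image).

All randomness flows from one seed through ``numpy`` SeedSequence spawning;
no global state is touched, and a fixed seed reproduces output exactly.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from typing import Mapping, Sequence

import numpy as np

from .counts import COUNT_BINS, CountBin
from .tables_io import (
    BEHAVIOURS,
    CaptureMetadata,
    ClassificationEvent,
    GoldRecord,
    SpeciesAnnotation,
)
from .vocabulary import IMPOSSIBLE, SPECIES

__all__ = [
    "SceneTruth",
    "VolunteerProfile",
    "SimulationConfig",
    "build_confusion",
    "generate_scenes",
    "generate_volunteers",
    "generate_classifications",
    "generate_gold",
    "scene_metadata",
    "classification_accuracy",
]

_SPECIES_INDEX = {s: i for i, s in enumerate(SPECIES)}

# Relative encounter frequencies of the 48 options, proportional to the
# raw capture-event totals observed in the Serengeti survey; rare and
# charismatic species stay rare in the fixtures.
_DEFAULT_PREVALENCE: dict[str, int] = {
    "aardvark": 386, "aardwolf": 162, "baboon": 1556, "bat eared fox": 291,
    "buffalo": 13672, "bushbuck": 252, "caracal": 79, "cheetah": 1272,
    "civet": 37, "dik dik": 1483, "eland": 2689, "elephant": 10178,
    "genet": 27, "giraffe": 8386, "grant's gazelle": 7723,
    "guinea fowl": 7793, "hare": 398, "hartebeest": 12431,
    "hippopotamus": 2611, "honey badger": 35, "human": 9851, "impala": 8286,
    "jackal": 561, "kori bustard": 688, "leopard": 228,
    "lion female&cub": 3343, "lion male": 923, "mongoose": 246,
    "ostrich": 673, "other bird": 5549, "porcupine": 288, "reedbuck": 2875,
    "reptiles": 131, "rhinoceros": 30, "rodents": 48, "secretary bird": 434,
    "serval": 458, "spotted hyena": 5303, "striped hyena": 115,
    "thomson's gazelle": 41420, "topi": 2299, "vervet monkey": 314,
    "warthog": 7493, "waterbuck": 353, "wildcat": 47, "wildebeest": 100660,
    "zebra": 70577, "zorilla": 17,
}

# Look-alike pairs/groups where volunteer confusion concentrates.
_CONFUSABLE: dict[str, tuple[str, ...]] = {
    "thomson's gazelle": ("grant's gazelle", "impala"),
    "grant's gazelle": ("thomson's gazelle", "impala"),
    "impala": ("grant's gazelle", "thomson's gazelle"),
    "spotted hyena": ("striped hyena", "aardwolf"),
    "striped hyena": ("spotted hyena", "aardwolf"),
    "aardwolf": ("striped hyena", "jackal"),
    "wildebeest": ("buffalo", "hartebeest"),
    "buffalo": ("wildebeest",),
    "hartebeest": ("topi", "wildebeest"),
    "topi": ("hartebeest",),
    "cheetah": ("leopard", "serval"),
    "leopard": ("cheetah", "serval"),
    "serval": ("wildcat", "caracal", "cheetah"),
    "wildcat": ("serval", "caracal"),
    "caracal": ("serval", "wildcat"),
    "lion female&cub": ("lion male",),
    "lion male": ("lion female&cub",),
    "jackal": ("bat eared fox", "aardwolf"),
    "bat eared fox": ("jackal",),
    "reedbuck": ("bushbuck", "waterbuck"),
    "bushbuck": ("reedbuck", "waterbuck"),
    "waterbuck": ("reedbuck", "bushbuck"),
    "other bird": ("guinea fowl", "kori bustard", "secretary bird"),
    "guinea fowl": ("other bird",),
    "kori bustard": ("other bird", "secretary bird"),
    "secretary bird": ("other bird", "kori bustard"),
    "genet": ("civet", "zorilla"),
    "civet": ("genet", "zorilla"),
    "zorilla": ("honey badger", "civet"),
    "honey badger": ("zorilla",),
    "mongoose": ("rodents",),
    "hare": ("rodents",),
}


@dataclasses.dataclass(frozen=True)
class SceneTruth:
    """Ground truth for one simulated capture event.

    ``lookalike`` records, per true species, which look-alike the image
    happens to resemble: misidentifications of a given hard image pile onto
    the same wrong species for every volunteer (the way real crowds
    systematically mistake one gazelle for the other), rather than
    scattering independently.
    """

    capture_event_id: str
    species: Mapping[str, CountBin]  # empty for blank scenes
    behaviours: Mapping[str, tuple[bool, ...]]  # per species, 6 flags
    lookalike: Mapping[str, str]  # per species, the scene's deceptive twin
    difficulty: float
    site_id: str
    datetime: _dt.datetime

    @property
    def is_blank(self) -> bool:
        return not self.species


@dataclasses.dataclass(frozen=True)
class VolunteerProfile:
    """One volunteer's error model.

    ``confusion`` rows are indexed by true species, columns by reported
    species, both in vocabulary order; each row sums to one. The volunteer
    answers blank with probability ``blank_propensity * difficulty``.
    ``count_noise_step`` is the continuation probability of the geometric
    ordinal displacement, ``behaviour_error`` the per-flag flip rate.
    """

    user_id: str
    confusion: np.ndarray
    blank_propensity: float
    count_noise_step: float
    behaviour_error: float

    def __post_init__(self) -> None:
        if self.confusion.shape != (len(SPECIES), len(SPECIES)):
            raise ValueError("confusion matrix must cover the full vocabulary")
        if not np.allclose(self.confusion.sum(axis=1), 1.0):
            raise ValueError("confusion rows must sum to 1")
        if not 0.0 <= self.blank_propensity <= 1.0:
            raise ValueError("blank_propensity must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the generator.

    Defaults emulate the real survey: ~73% misfire (blank) scenes, species
    drawn from observed relative frequencies, a small share of two-species
    scenes, 85% mean single-species volunteer accuracy, and a mild
    blank-when-unsure propensity.
    """

    blank_fraction: float = 0.73
    two_species_fraction: float = 0.05
    prevalence: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_PREVALENCE)
    )
    #: Geometric decay of true group size across ordinal bins.
    count_decay: float = 0.55
    #: Beta(a, b) distribution of scene difficulty.
    difficulty_alpha: float = 2.0
    difficulty_beta: float = 5.0
    volunteer_accuracy: float = 0.85
    accuracy_sd: float = 0.0
    #: Share of a volunteer's error mass aimed at look-alike species.
    confusable_weight: float = 0.7
    #: Misidentification scales with difficulty^exponent, normalised so the
    #: marginal error rate stays at 1 - volunteer_accuracy; hard images
    #: concentrate the errors, as observed in real surveys.
    difficulty_error_exponent: float = 2.0
    #: Per-classification misidentification probability is capped here.
    max_error_rate: float = 0.9
    blank_propensity: float = 0.3
    count_noise_step: float = 0.25
    behaviour_error: float = 0.05
    behaviour_base_rate: float = 0.3
    n_volunteers: int = 100
    n_sites: int = 25

    def __post_init__(self) -> None:
        for name in (
            "blank_fraction", "two_species_fraction", "count_decay",
            "volunteer_accuracy", "confusable_weight", "blank_propensity",
            "count_noise_step", "behaviour_error", "behaviour_base_rate",
            "max_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.difficulty_error_exponent <= 0:
            raise ValueError("difficulty_error_exponent must be positive")
        if any(p < 0 for p in self.prevalence.values()):
            raise ValueError("prevalences must be non-negative")
        unknown = set(self.prevalence) - set(SPECIES)
        if unknown:
            raise ValueError(f"prevalence for unknown species: {sorted(unknown)}")

    def error_scale(self, difficulty: float) -> float:
        """Multiplier applied to a volunteer's base error rate on a scene of
        this difficulty; averages to 1 over the difficulty distribution."""
        import math

        a, b, g = self.difficulty_alpha, self.difficulty_beta, self.difficulty_error_exponent
        # E[d^g] for d ~ Beta(a, b)
        moment = math.exp(
            math.lgamma(a + g) + math.lgamma(a + b) - math.lgamma(a) - math.lgamma(a + b + g)
        )
        return difficulty ** g / moment

    @classmethod
    def from_dict(cls, data: Mapping[str, object]) -> "SimulationConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown simulation config key(s): {sorted(unknown)}")
        return cls(**data)  # type: ignore[arg-type]


def build_confusion(
    accuracy: float, confusable_weight: float = 0.7
) -> np.ndarray:
    """Row-stochastic confusion matrix with ``accuracy`` on the diagonal.

    Off-diagonal mass goes preferentially (``confusable_weight``) to the
    species' look-alike partners, the remainder uniformly elsewhere.
    """
    if not 0.0 < accuracy <= 1.0:
        raise ValueError("accuracy must lie in (0, 1]")
    n = len(SPECIES)
    mat = np.zeros((n, n))
    for i, sp in enumerate(SPECIES):
        mat[i, i] = accuracy
        err = 1.0 - accuracy
        if err == 0.0:
            continue
        partners = [_SPECIES_INDEX[p] for p in _CONFUSABLE.get(sp, ())]
        others = [j for j in range(n) if j != i and j not in partners]
        if partners:
            mat[i, partners] = err * confusable_weight / len(partners)
            mat[i, others] += err * (1 - confusable_weight) / len(others)
        else:
            mat[i, others] += err / len(others)
    return mat


def _sample_count(rng: np.random.Generator, decay: float) -> CountBin:
    w = decay ** np.arange(len(COUNT_BINS))
    return COUNT_BINS[rng.choice(len(COUNT_BINS), p=w / w.sum())]


def _sample_behaviours(
    rng: np.random.Generator, base_rate: float
) -> tuple[bool, ...]:
    flags = rng.random(len(BEHAVIOURS) + 1) < base_rate
    if not flags[: len(BEHAVIOURS)].any():
        flags[rng.integers(len(BEHAVIOURS))] = True  # animals always do something
    return tuple(bool(f) for f in flags)


def generate_scenes(
    n: int, config: SimulationConfig | None = None, seed: int | np.random.SeedSequence = 0
) -> list[SceneTruth]:
    """Draw ``n`` ground-truth scenes; reproducible for a fixed seed."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    labels = [s for s in SPECIES if config.prevalence.get(s, 0) > 0]
    weights = np.array([config.prevalence[s] for s in labels], dtype=float)
    if not labels:
        raise ValueError("no species has positive prevalence")
    weights /= weights.sum()
    start = _dt.datetime(2012, 1, 1, 0, 0, 0)
    scenes = []
    for i in range(n):
        cid = f"SIM{i:07d}"
        site = f"S{rng.integers(1, config.n_sites + 1):03d}"
        when = start + _dt.timedelta(minutes=int(rng.integers(0, 525_600)))
        difficulty = float(rng.beta(config.difficulty_alpha, config.difficulty_beta))
        species: dict[str, CountBin] = {}
        behaviours: dict[str, tuple[bool, ...]] = {}
        lookalike: dict[str, str] = {}
        if rng.random() >= config.blank_fraction:
            k = 2 if rng.random() < config.two_species_fraction else 1
            for idx in rng.choice(len(labels), size=min(k, len(labels)), replace=False, p=weights):
                sp = labels[int(idx)]
                species[sp] = _sample_count(rng, config.count_decay)
                behaviours[sp] = _sample_behaviours(rng, config.behaviour_base_rate)
                partners = _CONFUSABLE.get(sp) or tuple(
                    s for s in SPECIES if s != sp
                )
                lookalike[sp] = partners[int(rng.integers(len(partners)))]
        scenes.append(
            SceneTruth(
                capture_event_id=cid,
                species=species,
                behaviours=behaviours,
                lookalike=lookalike,
                difficulty=difficulty,
                site_id=site,
                datetime=when,
            )
        )
    return scenes


def generate_volunteers(
    config: SimulationConfig | None = None, seed: int | np.random.SeedSequence = 0
) -> list[VolunteerProfile]:
    """Build the volunteer pool; accuracies may jitter around the mean."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(config.n_volunteers):
        acc = config.volunteer_accuracy
        if config.accuracy_sd > 0:
            acc = float(
                np.clip(rng.normal(acc, config.accuracy_sd), 0.5, 0.999)
            )
        profiles.append(
            VolunteerProfile(
                user_id=f"vol{i:04d}",
                confusion=build_confusion(acc, config.confusable_weight),
                blank_propensity=config.blank_propensity,
                count_noise_step=config.count_noise_step,
                behaviour_error=config.behaviour_error,
            )
        )
    return profiles


def _displace_count(
    rng: np.random.Generator, count: CountBin, step: float
) -> CountBin:
    """Geometric-tailed displacement on the ordinal scale, truncated at the
    ends; larger groups wander further in expectation only through the
    tail, matching how count accuracy degrades with group size."""
    d = 0
    while step > 0 and rng.random() < step:
        d += 1
    if d == 0:
        return count
    if rng.random() < 0.5:
        d = -d
    level = int(np.clip(count.level + d, 0, len(COUNT_BINS) - 1))
    return COUNT_BINS[level]


def generate_classifications(
    scenes: Sequence[SceneTruth],
    volunteers: Sequence[VolunteerProfile],
    per_event_n: int,
    seed: int | np.random.SeedSequence = 0,
    config: SimulationConfig | None = None,
) -> list[ClassificationEvent]:
    """Simulate ``per_event_n`` volunteer classifications per scene.

    Each sampled volunteer either answers blank (probability
    ``blank_propensity * difficulty``; blank scenes are always answered
    blank) or reports every true species, misidentified with probability
    ``(1 - diagonal) * error_scale(difficulty)``: errors go preferentially
    to the scene's look-alike species (so hard images mislead different
    volunteers the same way), the rest scatter along the volunteer's
    confusion row. Counts are displaced on the ordinal scale and behaviour
    flags flipped independently. Two true species collapsing to one
    reported species yield duplicate species rows under one
    ClassificationID, exactly the artefact the normalization stage merges.

    ``config`` must describe the same difficulty distribution the scenes
    were generated under; it defaults to the standard conditions.
    """
    if per_event_n < 1:
        raise ValueError("per_event_n must be >= 1")
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    n_vol = len(volunteers)
    events: list[ClassificationEvent] = []
    serial = 0
    for scene in scenes:
        replace = per_event_n > n_vol
        chosen = rng.choice(n_vol, size=per_event_n, replace=replace)
        for v_idx in chosen:
            vol = volunteers[int(v_idx)]
            serial += 1
            cls_id = f"C{serial:09d}"
            annotations: list[SpeciesAnnotation] = []
            goes_blank = scene.is_blank or (
                rng.random() < vol.blank_propensity * scene.difficulty
            )
            if not goes_blank:
                scale = config.error_scale(scene.difficulty)
                for sp, true_count in scene.species.items():
                    i = _SPECIES_INDEX[sp]
                    e = min(
                        config.max_error_rate,
                        (1.0 - vol.confusion[i, i]) * scale,
                    )
                    if rng.random() >= e:
                        reported = sp
                    elif rng.random() < config.confusable_weight:
                        reported = scene.lookalike[sp]
                    else:
                        row = vol.confusion[i].copy()
                        row[i] = 0.0
                        row /= row.sum()
                        reported = SPECIES[int(rng.choice(len(SPECIES), p=row))]
                    flags = [
                        f != (rng.random() < vol.behaviour_error)
                        for f in scene.behaviours[sp]
                    ]
                    annotations.append(
                        SpeciesAnnotation(
                            species=reported,
                            count=_displace_count(
                                rng, true_count, vol.count_noise_step
                            ),
                            standing=flags[0],
                            resting=flags[1],
                            moving=flags[2],
                            eating=flags[3],
                            interacting=flags[4],
                            babies=flags[5],
                        )
                    )
            events.append(
                ClassificationEvent(
                    capture_event_id=scene.capture_event_id,
                    classification_id=cls_id,
                    user_id=vol.user_id,
                    annotations=tuple(annotations),
                )
            )
    return events


def generate_gold(
    scenes: Sequence[SceneTruth],
    impossible_fraction: float = 0.002,
    seed: int | np.random.SeedSequence = 0,
) -> list[GoldRecord]:
    """Expert gold table: the truth, except a seeded fraction of animal
    scenes marked ``impossible``. Blank scenes are not covered (experts
    reviewed animal images)."""
    if not 0.0 <= impossible_fraction <= 1.0:
        raise ValueError("impossible_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    records: list[GoldRecord] = []
    for scene in scenes:
        if scene.is_blank:
            continue
        if rng.random() < impossible_fraction:
            records.append(
                GoldRecord(
                    capture_event_id=scene.capture_event_id,
                    num_species=1,
                    species=IMPOSSIBLE,
                    count=None,
                )
            )
            continue
        for sp, count in scene.species.items():
            records.append(
                GoldRecord(
                    capture_event_id=scene.capture_event_id,
                    num_species=len(scene.species),
                    species=sp,
                    count=count,
                )
            )
    return records


def scene_metadata(scenes: Sequence[SceneTruth]) -> dict[str, CaptureMetadata]:
    """Capture metadata keyed by event id, for the consensus writer."""
    return {
        s.capture_event_id: CaptureMetadata(
            capture_event_id=s.capture_event_id,
            num_images=3,
            datetime=s.datetime,
            site_id=s.site_id,
            location_x=700_000.0,
            location_y=9_700_000.0,
        )
        for s in scenes
    }


def classification_accuracy(
    events: Sequence[ClassificationEvent], scenes: Sequence[SceneTruth]
) -> float:
    """Share of individual classifications of animal scenes whose species
    set equals the truth (a blank answer on an animal scene is wrong).

    The consensus counterpart of this quantity should exceed it whenever
    aggregation adds value.
    """
    truth = {s.capture_event_id: frozenset(s.species) for s in scenes if not s.is_blank}
    scored = [
        ev.species_set == truth[ev.capture_event_id]
        for ev in events
        if ev.capture_event_id in truth
    ]
    if not scored:
        raise ValueError("no classifications of animal scenes")
    return sum(scored) / len(scored)
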