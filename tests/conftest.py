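import datetime as dt
import io

import pytest
from hypothesis import HealthCheck, settings

from camvote import examples
from camvote.counts import COUNT_BINS
from camvote.tables_io import (
    ClassificationEvent,
    SpeciesAnnotation,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_event(capture, serial, species_counts, user=None, **flags):
    """Build a ClassificationEvent from {species: bin-label} (None = blank)."""
    annotations = []
    if species_counts:
        for sp, label in species_counts.items():
            annotations.append(
                SpeciesAnnotation(
                    species=sp,
                    count=next(b for b in COUNT_BINS if b.label == str(label)),
                    **flags,
                )
            )
    return ClassificationEvent(
        capture_event_id=capture,
        classification_id=f"{capture}-c{serial}",
        user_id=user or f"u{serial}",
        annotations=tuple(annotations),
    )


def blank_event(capture, serial):
    return make_event(capture, serial, None)


@pytest.fixture
def giraffe_events():
    return examples.giraffe_stream()


@pytest.fixture
def hyena_events():
    return examples.hyena_stream()


@pytest.fixture
def antelope_events():
    return examples.antelope_stream()


@pytest.fixture
def raw_csv_text(giraffe_events, hyena_events, antelope_events):
    from camvote.tables_io import write_raw_classifications

    buf = io.StringIO()
    write_raw_classifications(
        giraffe_events + hyena_events + antelope_events, buf
    )
    return buf.getvalue()


@pytest.fixture
def small_survey():
    """A deterministic end-to-end simulation shared across tests."""
    import numpy as np

    from camvote.simulate import (
        SimulationConfig,
        generate_classifications,
        generate_gold,
        generate_scenes,
        generate_volunteers,
    )

    config = SimulationConfig(n_volunteers=40)
    root = np.random.SeedSequence(20_150_609)
    s1, s2, s3, s4 = root.spawn(4)
    scenes = generate_scenes(300, config, s1)
    volunteers = generate_volunteers(config, s2)
    events = generate_classifications(scenes, volunteers, 15, s3, config)
    gold = generate_gold(scenes, 0.01, s4)
    return {"config": config, "scenes": scenes, "volunteers": volunteers,
            "events": events, "gold": gold}
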