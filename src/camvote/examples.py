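"""Published Snapshot Serengeti sample classification streams.

Three image sets whose per-volunteer classifications were released as
worked examples of the retirement and consensus machinery:

* ``ASG0010cz5`` — ten identical 'giraffe, count 1' answers (nine flagged
  moving, one standing); retires as *Consensus* on the tenth matching
  classification and aggregates to a unanimous giraffe record.
* ``ASG0000009`` — fourteen answers dominated by spotted hyena (10 votes)
  with scattered warthog, jackal and wildcat votes; retires as *Consensus*
  and aggregates to spotted hyena.
* ``ASG000xzxd`` — twenty-five answers (three blank) split across five
  antelope species; no combination reaches ten votes, so it retires as
  *Complete*. The released sample tallies impala, Grant's gazelle and
  dik dik at five votes each, an exact three-way tie the aggregation flags.

Each stream is constructed programmatically as ClassificationEvents (one
volunteer per classification, synthetic user ids) matching the published
rows verbatim in species, count and behaviour flags.
"""

from __future__ import annotations

from .counts import CountBin
from .tables_io import ClassificationEvent, SpeciesAnnotation

__all__ = ["giraffe_stream", "hyena_stream", "antelope_stream"]

_ONE = CountBin.parse("1")


def _event(
    capture: str, serial: int, species: str | None, **flags: bool
) -> ClassificationEvent:
    annotations = ()
    if species is not None:
        annotations = (SpeciesAnnotation(species=species, count=_ONE, **flags),)
    return ClassificationEvent(
        capture_event_id=capture,
        classification_id=f"{capture}-c{serial:02d}",
        user_id=f"user{serial:02d}",
        annotations=annotations,
    )


def giraffe_stream() -> list[ClassificationEvent]:
    """Image set ASG0010cz5: 10 matching giraffe classifications."""
    events = [
        _event("ASG0010cz5", i, "giraffe", moving=True) for i in range(1, 10)
    ]
    events.append(_event("ASG0010cz5", 10, "giraffe", standing=True))
    return events


def hyena_stream() -> list[ClassificationEvent]:
    """Image set ASG0000009: spotted hyena reaches 10 votes among 14
    classifications (tally hyena 10, warthog 2, jackal 1, wildcat 1)."""
    rows = [
        ("spotted hyena", dict(moving=True)),
        ("jackal", dict(moving=True)),
        ("spotted hyena", dict(moving=True)),
        ("warthog", dict(standing=True)),
        ("spotted hyena", dict(standing=True)),
        ("spotted hyena", dict(moving=True)),
        ("spotted hyena", dict(moving=True)),
        ("spotted hyena", dict(moving=True)),
        ("warthog", dict(moving=True)),
        ("spotted hyena", dict(moving=True)),
        ("wildcat", dict(moving=True)),
        ("spotted hyena", dict(moving=True)),
        ("spotted hyena", dict(moving=True)),
        ("spotted hyena", dict(moving=True)),
    ]
    return [
        _event("ASG0000009", i, sp, **flags)
        for i, (sp, flags) in enumerate(rows, start=1)
    ]


def antelope_stream() -> list[ClassificationEvent]:
    """Image set ASG000xzxd: 25 sample rows (3 blank) over five antelope
    species.

    Tally: impala 5, Grant's gazelle 5, dik dik 5, reedbuck 3,
    Thomson's gazelle 3, waterbuck 1; blanks 3. No species combination
    approaches 10 matching votes and blanks stay below every blank rule, so
    Complete (25 non-blank answers) is the only retirement rule the image
    set's published retirement is consistent with; the full stream was
    longer than this released sample, as it was for all animal images
    (11-57 classifications each).
    """
    rows: list[tuple[str | None, dict[str, bool]]] = [
        ("impala", dict(standing=True)),
        ("grant's gazelle", dict(moving=True)),
        ("reedbuck", dict(standing=True)),
        ("reedbuck", dict(standing=True)),
        ("dik dik", dict(standing=True, moving=True)),
        (None, {}),
        ("dik dik", dict(standing=True)),
        ("impala", dict(standing=True)),
        (None, {}),
        ("reedbuck", dict(standing=True)),
        (None, {}),
        ("impala", dict(standing=True)),
        ("impala", dict(standing=True)),
        ("dik dik", dict(standing=True)),
        ("thomson's gazelle", dict(standing=True)),
        ("grant's gazelle", dict(standing=True)),
        ("grant's gazelle", dict(standing=True)),
        ("impala", dict(standing=True)),
        ("thomson's gazelle", dict(standing=True)),
        ("thomson's gazelle", dict(standing=True)),
        ("dik dik", dict(standing=True)),
        ("waterbuck", dict(standing=True)),
        ("grant's gazelle", dict(standing=True)),
        ("grant's gazelle", dict(standing=True)),
        ("dik dik", dict(standing=True)),
    ]
    return [
        _event("ASG000xzxd", i, sp, **flags)
        for i, (sp, flags) in enumerate(rows, start=1)
    ]
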