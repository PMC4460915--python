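"""Schema-faithful I/O for the five survey tables."""

import datetime as dt
import io

import pytest
from hypothesis import given
from hypothesis import strategies as st

from camvote.counts import COUNT_BINS
from camvote.tables_io import (
    CONSENSUS_COLUMNS,
    CaptureMetadata,
    ClassificationEvent,
    ConsensusRecord,
    GoldRecord,
    OperationInterval,
    SchemaError,
    SpeciesAnnotation,
    read_consensus,
    read_effort,
    read_gold,
    read_image_index,
    read_raw_classifications,
    write_consensus,
    write_effort,
    write_gold,
    write_image_index,
    write_raw_classifications,
)
from camvote.vocabulary import IMPOSSIBLE, SPECIES

# -- strategies -------------------------------------------------------------

species_st = st.sampled_from(SPECIES)
bin_st = st.sampled_from(COUNT_BINS)
flag_st = st.booleans()

annotation_st = st.builds(
    SpeciesAnnotation,
    species=species_st,
    count=bin_st,
    standing=flag_st,
    resting=flag_st,
    moving=flag_st,
    eating=flag_st,
    interacting=flag_st,
    babies=flag_st,
)


@st.composite
def events_st(draw):
    n = draw(st.integers(0, 12))
    events = []
    for i in range(n):
        annotations = tuple(draw(st.lists(annotation_st, max_size=3)))
        events.append(
            ClassificationEvent(
                capture_event_id=f"EV{draw(st.integers(0, 3))}",
                classification_id=f"C{i:04d}",
                user_id=f"u{i}",
                annotations=annotations,
            )
        )
    return events


# -- raw classifications ----------------------------------------------------

@given(events_st())
def test_raw_round_trip_and_conservation(events):
    buf = io.StringIO()
    write_raw_classifications(events, buf)
    buf.seek(0)
    back = list(read_raw_classifications(buf))
    assert back == events
    n_rows = buf.getvalue().count("\n") - 1
    assert n_rows == sum(max(1, len(ev.annotations)) for ev in events)


def test_grouping_shares_classification_id():
    csv = (
        "CaptureEventID,ClassificationID,UserID,Species,Count,Standing,"
        "Resting,Moving,Eating,Interacting,Babies\n"
        "E1,C1,u1,zebra,2,1,0,0,0,0,0\n"
        "E1,C1,u1,wildebeest,5,0,0,1,0,0,0\n"
        "E1,C2,u2,blank,,,,,,,\n"
    )
    events = list(read_raw_classifications(io.StringIO(csv)))
    assert len(events) == 2
    assert events[0].species_set == {"zebra", "wildebeest"}
    assert events[1].is_blank


def test_raw_accepts_y_n_flags():
    csv = (
        "CaptureEventID,ClassificationID,UserID,Species,Count,Standing,"
        "Resting,Moving,Eating,Interacting,Babies\n"
        "E1,C1,u1,giraffe,1,N,N,Y,N,N,N\n"
    )
    (event,) = read_raw_classifications(io.StringIO(csv))
    assert event.annotations[0].moving and not event.annotations[0].standing


def test_raw_errors_name_the_problem():
    head = (
        "CaptureEventID,ClassificationID,UserID,Species,Count,Standing,"
        "Resting,Moving,Eating,Interacting,Babies\n"
    )
    with pytest.raises(SchemaError, match="row 2"):
        list(read_raw_classifications(io.StringIO(head + "E,C,u,unicorn,1,0,0,0,0,0,0\n")))
    with pytest.raises(SchemaError, match="missing column"):
        list(read_raw_classifications(io.StringIO("Species\nzebra\n")))
    # blank rows carrying stray values are warned about, not fatal
    with pytest.warns(UserWarning, match="blank classification"):
        (event,) = read_raw_classifications(
            io.StringIO(head + "E,C,u,blank,3,1,0,0,0,0,0\n")
        )
    assert event.is_blank


def test_empty_table_with_header_yields_empty_stream():
    head = ",".join(
        ["CaptureEventID", "ClassificationID", "UserID", "Species", "Count",
         "Standing", "Resting", "Moving", "Eating", "Interacting", "Babies"]
    )
    assert list(read_raw_classifications(io.StringIO(head + "\n"))) == []


# -- consensus --------------------------------------------------------------

def _consensus_record(cid="E1", species="giraffe", num_species=1):
    meta = CaptureMetadata(
        capture_event_id=cid,
        num_images=3,
        datetime=dt.datetime(2012, 3, 4, 5, 6, 7),
        site_id="B04",
        location_x=712345.0,
        location_y=9723456.0,
    )
    return ConsensusRecord(
        metadata=meta,
        num_species=num_species,
        species=species,
        count=COUNT_BINS[0],
        standing=0.1,
        resting=0.0,
        moving=0.9,
        eating=0.0,
        interacting=0.0,
        babies=0.0,
        num_classifications=10,
        num_votes=10,
        num_blanks=0,
        evenness=0.0,
    )


def test_consensus_round_trip_and_column_layout():
    records = [
        _consensus_record(),
        _consensus_record(cid="E2", species="wildebeest", num_species=2),
        _consensus_record(cid="E2", species="zebra", num_species=2),
    ]
    buf = io.StringIO()
    write_consensus(records, buf)
    header = buf.getvalue().splitlines()[0]
    assert header == ",".join(CONSENSUS_COLUMNS)
    assert len(CONSENSUS_COLUMNS) == 19
    buf.seek(0)
    assert read_consensus(buf) == records


def test_consensus_empty_list_is_header_only():
    buf = io.StringIO()
    write_consensus([], buf)
    assert buf.getvalue().strip() == ",".join(CONSENSUS_COLUMNS)


def test_consensus_diagnostics_columns_round_trip():
    rec = _consensus_record()
    rec = type(rec)(**{**rec.__dict__, "tie": True, "percent_support": 0.7})
    buf = io.StringIO()
    write_consensus([rec], buf, diagnostics=True)
    assert buf.getvalue().splitlines()[0].endswith("Tie,PercentSupport")
    buf.seek(0)
    (back,) = read_consensus(buf)
    assert back.tie and back.percent_support == 0.7


# -- gold, effort, images ---------------------------------------------------

def test_gold_round_trip_and_impossible():
    records = [
        GoldRecord("E1", 1, "giraffe", COUNT_BINS[2]),
        GoldRecord("E2", 1, IMPOSSIBLE, None),
    ]
    buf = io.StringIO()
    write_gold(records, buf)
    buf.seek(0)
    back = read_gold(buf)
    assert back == records
    assert back[1].is_impossible


def test_gold_impossible_must_be_alone():
    csv = (
        "CaptureEventID,NumSpecies,Species,Count\n"
        "E1,2,impossible,\n"
        "E1,2,zebra,3\n"
    )
    with pytest.raises(SchemaError, match="only gold row"):
        read_gold(io.StringIO(csv))


def test_effort_round_trip_and_date_order():
    intervals = [
        OperationInterval("B04", dt.date(2012, 1, 1), dt.date(2012, 2, 1)),
        OperationInterval("C07", dt.date(2012, 3, 1), dt.date(2012, 3, 1)),
    ]
    buf = io.StringIO()
    write_effort(intervals, buf)
    buf.seek(0)
    assert read_effort(buf) == intervals
    with pytest.raises(SchemaError):
        OperationInterval("B04", dt.date(2012, 2, 2), dt.date(2012, 2, 1))


def test_image_index_round_trip_keeps_suffix_verbatim():
    pairs = [("E1", "S1/B04/B04_R1/S1_B04_R1_PICT0012.JPG")]
    buf = io.StringIO()
    write_image_index(pairs, buf)
    buf.seek(0)
    assert read_image_index(buf) == pairs
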