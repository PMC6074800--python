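"""Coding-sheet I/O, vocabularies and validation."""

import io

import pytest

from pcmckit.ethogram_model import (
    FormatError, InterventionRecord, RowError, dump_setup, load_setup,
    read_coding_sheet, validate_log, write_coding_sheet,
)
from pcmckit.synthetic_data import SimulationConfig, simulate_log


def roundtrip(log):
    buf = io.StringIO()
    write_coding_sheet(log, buf)
    buf.seek(0)
    return read_coding_sheet(buf, log.setup)


def test_three_row_sheet_parses_with_zero_skips(toy_setup):
    sheet = (
        "record_type,event_id,date,onset_s,offset_s,condition,actor,target,"
        "intensity,context,behaviour\n"
        "aggression,e1,2020-01-01,10,40,indoor,a,b,low,weaning,gentle_push\n"
        "aggression,e2,2020-01-01,100,130,indoor,b,a,high,spontaneous,bite\n"
        "affiliation,e3,2020-01-01,200,,indoor,a,b,,,contact_sitting\n"
    )
    log, report = read_coding_sheet(io.StringIO(sheet), toy_setup)
    assert report.n_rows == 3 and report.n_skipped == 0
    assert len(log.aggressions) == 2 and len(log.affiliations) == 1
    assert log.aggressions[0].behaviour_elements == ("gentle_push",)


def test_unknown_vocabulary_value_strict_vs_lenient(toy_setup):
    sheet = (
        "record_type,event_id,date,onset_s,offset_s,condition,actor,target,"
        "intensity,context\n"
        "aggression,e1,2020-01-01,10,40,indoor,a,b,severe,spontaneous\n"
    )
    with pytest.raises(RowError, match="row 2.*severe"):
        read_coding_sheet(io.StringIO(sheet), toy_setup)
    log, report = read_coding_sheet(io.StringIO(sheet), toy_setup,
                                    strict=False)
    assert not log.aggressions and report.n_skipped == 1


def test_missing_mandatory_column_and_bad_time(toy_setup):
    with pytest.raises(FormatError, match="actor"):
        read_coding_sheet(io.StringIO("record_type,event_id,date,onset_s,"
                                      "condition,target\n"), toy_setup)
    sheet = (
        "record_type,event_id,date,onset_s,condition,actor,target\n"
        "aggression,e1,2020-01-01,ten,indoor,a,b\n"
    )
    with pytest.raises(RowError, match="row 2.*unparseable time"):
        read_coding_sheet(io.StringIO(sheet), toy_setup)


def test_column_mapping_resolves_foreign_headers(toy_setup):
    sheet = (
        "kind,id,day,start,stop,cond,agg,vic\n"
        "aggression,e1,2020-01-01,10,40,indoor,a,b\n"
    )
    mapping = dict(record_type="kind", event_id="id", date="day",
                   onset_s="start", offset_s="stop", condition="cond",
                   actor="agg", target="vic")
    log, _ = read_coding_sheet(io.StringIO(sheet), toy_setup, mapping=mapping)
    assert log.aggressions[0].aggressor_id == "a"


def test_empty_log_writes_header_only(toy_log):
    buf = io.StringIO()
    write_coding_sheet(toy_log(), buf)
    assert buf.getvalue().count("\n") == 1


def test_roundtrip_identity_on_simulated_log():
    log = simulate_log(SimulationConfig(seed=3))
    back, report = roundtrip(log)
    assert report.n_skipped == 0
    assert back.aggressions == log.aggressions
    assert back.affiliations == log.affiliations


def test_two_behaviour_affiliation_serialised_with_plus(toy_setup, toy_log):
    from tests.conftest import aff
    log = toy_log(affiliations=[
        aff(toy_setup, "f1", 0, 5.0, "a", "b",
            behaviour_types=("embrace", "touch_body"))])
    buf = io.StringIO()
    write_coding_sheet(log, buf)
    assert "embrace+touch_body" in buf.getvalue()
    back, _ = roundtrip(log)
    assert back.affiliations[0].behaviour_types == ("embrace", "touch_body")


def test_events_sorted_chronologically(toy_setup, toy_log):
    from tests.conftest import agg
    log = toy_log(aggressions=[
        agg(toy_setup, "late", 1, 50.0, "a", "b"),
        agg(toy_setup, "early", 0, 500.0, "a", "b"),
    ])
    assert [e.event_id for e in log.aggressions] == ["early", "late"]


def test_validate_log_flags_each_invariant(toy_setup, toy_log):
    from tests.conftest import agg, aff
    clean = toy_log(aggressions=[agg(toy_setup, "e1", 0, 10.0, "a", "b")])
    assert validate_log(clean).ok

    bad = toy_log(
        aggressions=[agg(toy_setup, "e2", 0, 10.0, "a", "zz")],
        affiliations=[aff(toy_setup, "f1", 0, 999999.0, "a", "b")],
    )
    report = validate_log(bad)
    assert any("unknown individual 'zz'" in v for v in report.violations)
    assert any("outside session duration" in v for v in report.violations)


def test_validate_log_requires_indoor_subgroup(toy_setup, toy_log):
    from tests.conftest import agg
    toy_setup.roster[0] = type(toy_setup.roster[0])(
        "a", "female", "adult", "none")
    log = toy_log(aggressions=[agg(toy_setup, "e1", 0, 10.0, "a", "b")])
    report = validate_log(log)
    assert any("no subgroup" in v for v in report.violations)


def test_intervener_cannot_be_party():
    with pytest.raises(ValueError):
        from pcmckit.ethogram_model import AggressionEvent
        import datetime as dt
        AggressionEvent(
            event_id="x", date=dt.date(2020, 1, 1), onset_s=0, offset_s=1,
            condition="indoor", aggressor_id="a", victim_id="b",
            interventions=(InterventionRecord("a", "peaceful", "b"),))


def test_setup_yaml_roundtrip(toy_setup):
    text = dump_setup(toy_setup)
    back = load_setup(io.StringIO(text))
    assert [i.id for i in back.roster] == [i.id for i in toy_setup.roster]
    assert back.hours_by_condition == pytest.approx(
        toy_setup.hours_by_condition)
    assert back.session_calendar == toy_setup.session_calendar
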