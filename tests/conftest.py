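import datetime as dt

import pytest

from pcmckit.ethogram_model import (
    AffiliationEvent, AggressionEvent, EventLog, Individual, SessionInfo,
    StudySetup,
)
from pcmckit.pipeline import run_pipeline
from pcmckit.studylike import study_mimic_log


@pytest.fixture(scope="session")
def mimic_log():
    return study_mimic_log()


@pytest.fixture(scope="session")
def mimic_report(mimic_log):
    return run_pipeline(mimic_log)


@pytest.fixture()
def toy_setup():
    """Three-individual group, five consecutive 2-hour indoor sessions."""
    roster = [
        Individual("a", "female", "adult", "A"),
        Individual("b", "female", "adult", "A"),
        Individual("c", "male", "adult", "B"),
    ]
    day0 = dt.date(2020, 1, 1)
    cal = [SessionInfo(day0 + dt.timedelta(days=i), dt.time(9, 0),
                       7200.0, "indoor") for i in range(5)]
    return StudySetup(roster=roster, session_calendar=cal)


def agg(setup, event_id, day, onset, aggressor, victim, *, offset=None,
        condition="indoor", **kw):
    date = setup.session_calendar[day].date
    return AggressionEvent(
        event_id=event_id, date=date, onset_s=onset,
        offset_s=onset + 30.0 if offset is None else offset,
        condition=condition, aggressor_id=aggressor, victim_id=victim, **kw)


def aff(setup, event_id, day, onset, a, b, *, condition="indoor", **kw):
    date = setup.session_calendar[day].date
    return AffiliationEvent(
        event_id=event_id, date=date, onset_s=onset, condition=condition,
        participant_a=a, participant_b=b, **kw)


@pytest.fixture()
def toy_log(toy_setup):
    def make(aggressions=(), affiliations=()):
        return EventLog(setup=toy_setup, aggressions=list(aggressions),
                        affiliations=list(affiliations)).sort()
    return make
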