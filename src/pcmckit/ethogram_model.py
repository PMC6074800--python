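"""Domain types for behavioural event logs and the coding-sheet format.

The unit of observation is a coded event from continuous video of a small
captive primate group: an aggressive interaction (aggressor, victim,
intensity, context, any third-party interventions) or an affiliative
contact (dyad, behaviour type(s), initiator).  Times are stored as seconds
from the start of the recording session on a given date; all window
arithmetic downstream is done in seconds, with the session calendar
mapping (date, clock time) to absolute time.

The on-disk format is a plain CSV coding sheet with one row per event and
a ``record_type`` column distinguishing aggression from affiliation rows.
Column names other than the canonical ones can be supplied through a
column map, since field names in hand-maintained coding sheets vary
between labs.  The roster and session calendar travel in a separate YAML
document.
"""

from __future__ import annotations

import csv
import datetime as dt
import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence, TextIO, Union

import yaml

__all__ = [
    "CONDITIONS", "INTENSITIES", "CONTEXTS", "REACTIONS", "SEXES",
    "AGE_CLASSES", "SUBGROUPS",
    "Individual", "SessionInfo", "StudySetup", "InterventionRecord",
    "AggressionEvent", "AffiliationEvent", "EventLog",
    "ParseReport", "ValidationReport", "FormatError", "RowError",
    "read_coding_sheet", "write_coding_sheet", "validate_log",
    "load_setup", "dump_setup",
]

CONDITIONS = ("outdoor", "indoor")
INTENSITIES = ("low", "medium", "high", "undetermined")
CONTEXTS = ("spontaneous", "sexual_coercion", "weaning", "food", "object",
            "punishment", "unknown")
REACTIONS = ("avoidance", "nonaggressive_cease", "counter_aggression",
             "redirection", "none")
SEXES = ("male", "female")
AGE_CLASSES = ("adult", "semi_dependent_immature", "dependent_immature")
SUBGROUPS = ("A", "B", "none")

#: separator joining the (at most two) behaviour types of one affiliative
#: contact in a single CSV cell
TYPE_SEP = "+"
LIST_SEP = ";"


class FormatError(ValueError):
    """A structural problem with a coding sheet (e.g. a missing column)."""


class RowError(ValueError):
    """A row-level parsing problem; carries the offending row index."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Individual:
    id: str
    sex: str
    age_class: str
    subgroup: str = "none"
    kin_links: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.age_class not in AGE_CLASSES:
            raise ValueError(f"unknown age class {self.age_class!r}")
        if self.subgroup not in SUBGROUPS:
            raise ValueError(f"unknown subgroup {self.subgroup!r}")


@dataclass(frozen=True)
class SessionInfo:
    date: dt.date
    start: dt.time
    duration_s: float
    condition: str

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.duration_s <= 0:
            raise ValueError("session duration must be positive")

    @property
    def start_dt(self) -> dt.datetime:
        return dt.datetime.combine(self.date, self.start)

    @property
    def end_dt(self) -> dt.datetime:
        return self.start_dt + dt.timedelta(seconds=self.duration_s)


@dataclass
class StudySetup:
    """Group roster plus the session calendar.

    ``hours_by_condition`` must equal the summed session durations per
    condition (checked on construction, to 1e-6 h)."""

    roster: list[Individual]
    session_calendar: list[SessionInfo]
    hours_by_condition: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        ids = [ind.id for ind in self.roster]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate individual ids in roster")
        sums = {c: 0.0 for c in CONDITIONS}
        for s in self.session_calendar:
            sums[s.condition] += s.duration_s / 3600.0
        if not self.hours_by_condition:
            self.hours_by_condition = {c: h for c, h in sums.items() if h > 0}
        else:
            for c, h in self.hours_by_condition.items():
                if abs(sums.get(c, 0.0) - h) > 1e-6:
                    raise ValueError(
                        f"hours_by_condition[{c!r}]={h} != calendar sum {sums.get(c, 0.0):.6f}"
                    )

    def individual(self, ind_id: str) -> Individual:
        for ind in self.roster:
            if ind.id == ind_id:
                return ind
        raise KeyError(ind_id)

    def session_on(self, date: dt.date) -> Optional[SessionInfo]:
        for s in self.session_calendar:
            if s.date == date:
                return s
        return None

    @property
    def dates(self) -> list[dt.date]:
        return sorted(s.date for s in self.session_calendar)


@dataclass(frozen=True)
class InterventionRecord:
    intervener_id: str
    mode: str  # peaceful | aggressive
    supported_id: str = ""
    successful: bool = True

    def __post_init__(self):
        if self.mode not in ("peaceful", "aggressive"):
            raise ValueError(f"unknown intervention mode {self.mode!r}")


@dataclass(frozen=True)
class AggressionEvent:
    event_id: str
    date: dt.date
    onset_s: float
    offset_s: float
    condition: str
    aggressor_id: str
    victim_id: str
    intensity: str = "undetermined"
    context: str = "unknown"
    behaviour_elements: tuple[str, ...] = ()
    through_mesh: bool = False
    reaction: frozenset[str] = frozenset()
    interventions: tuple[InterventionRecord, ...] = ()
    intervention_undetermined: bool = False

    def __post_init__(self):
        if self.offset_s < self.onset_s:
            raise ValueError("offset before onset")
        if self.aggressor_id == self.victim_id:
            raise ValueError("aggressor and victim must differ")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.intensity not in INTENSITIES:
            raise ValueError(f"unknown intensity {self.intensity!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        bad = self.reaction - set(REACTIONS)
        if bad:
            raise ValueError(f"unknown reaction value(s) {sorted(bad)}")
        for rec in self.interventions:
            if rec.intervener_id in (self.aggressor_id, self.victim_id):
                raise ValueError("intervener cannot be aggressor or victim")

    @property
    def dyad(self) -> frozenset[str]:
        return frozenset((self.aggressor_id, self.victim_id))


@dataclass(frozen=True)
class AffiliationEvent:
    event_id: str
    date: dt.date
    onset_s: float
    condition: str
    participant_a: str
    participant_b: str
    behaviour_types: tuple[str, ...] = ("contact_sitting",)
    initiator_id: str = ""
    visibility_ok: bool = True

    def __post_init__(self):
        if self.participant_a == self.participant_b:
            raise ValueError("affiliation participants must differ")
        if not (1 <= len(self.behaviour_types) <= 2):
            raise ValueError("an affiliative contact carries 1 or 2 behaviour types")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def dyad(self) -> frozenset[str]:
        return frozenset((self.participant_a, self.participant_b))

    def involves(self, ind_id: str) -> bool:
        return ind_id in (self.participant_a, self.participant_b)


@dataclass
class EventLog:
    setup: StudySetup
    aggressions: list[AggressionEvent] = field(default_factory=list)
    affiliations: list[AffiliationEvent] = field(default_factory=list)

    def sort(self) -> "EventLog":
        self.aggressions.sort(key=lambda e: (e.date, e.onset_s, e.event_id))
        self.affiliations.sort(key=lambda e: (e.date, e.onset_s, e.event_id))
        return self


# ---------------------------------------------------------------------------
# coding-sheet CSV
# ---------------------------------------------------------------------------

CANONICAL_COLUMNS = [
    "record_type", "event_id", "date", "onset_s", "offset_s", "condition",
    "actor", "target", "intensity", "context", "behaviour",
    "through_mesh", "reaction", "interventions",
    "intervention_undetermined", "initiator", "visibility_ok",
]

MANDATORY_COLUMNS = ["record_type", "event_id", "date", "onset_s",
                     "condition", "actor", "target"]


@dataclass
class ParseReport:
    n_rows: int = 0
    n_aggressions: int = 0
    n_affiliations: int = 0
    skipped: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def _parse_bool(s: str) -> bool:
    return s.strip().lower() in ("1", "true", "yes", "y")


def _fmt_interventions(recs: Sequence[InterventionRecord]) -> str:
    parts = []
    for r in recs:
        parts.append(
            f"{r.intervener_id}:{r.mode}:{r.supported_id}:{int(r.successful)}"
        )
    return LIST_SEP.join(parts)


def _parse_interventions(cell: str) -> tuple[InterventionRecord, ...]:
    cell = cell.strip()
    if not cell:
        return ()
    out = []
    for part in cell.split(LIST_SEP):
        intervener, mode, supported, success = part.split(":")
        out.append(InterventionRecord(intervener, mode, supported,
                                      bool(int(success))))
    return tuple(out)


def read_coding_sheet(
    source: Union[str, TextIO],
    setup: StudySetup,
    mapping: Optional[dict[str, str]] = None,
    strict: bool = True,
) -> tuple[EventLog, ParseReport]:
    """Read a coding-sheet CSV into an :class:`EventLog`.

    ``mapping`` maps canonical field names to the column headers actually
    present in the sheet (identity for canonical sheets).  In strict mode
    any malformed row raises :class:`RowError`; in lenient mode bad rows
    are skipped and listed in the returned :class:`ParseReport`.
    """
    close = False
    if isinstance(source, str):
        fh: TextIO = open(source, newline="", encoding="utf-8")
        close = True
    else:
        fh = source
    try:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError("coding sheet has no header row")
        colmap = {c: c for c in CANONICAL_COLUMNS}
        if mapping:
            colmap.update(mapping)
        for canon in MANDATORY_COLUMNS:
            if colmap[canon] not in reader.fieldnames:
                raise FormatError(f"missing mandatory column {colmap[canon]!r}")
        present = set(reader.fieldnames)

        def get(row: dict, canon: str, default: str = "") -> str:
            col = colmap[canon]
            if col not in present:
                return default
            return (row.get(col) or default).strip()

        log = EventLog(setup=setup)
        report = ParseReport()
        for idx, row in enumerate(reader, start=2):  # 1-based incl. header
            report.n_rows += 1
            try:
                rtype = get(row, "record_type").lower()
                date_str = get(row, "date")
                try:
                    date = dt.date.fromisoformat(date_str)
                except ValueError:
                    raise RowError(idx, f"unparseable date {date_str!r}")
                try:
                    onset = float(get(row, "onset_s"))
                except ValueError:
                    raise RowError(idx, f"unparseable time {get(row, 'onset_s')!r}")
                common = dict(
                    event_id=get(row, "event_id"),
                    date=date,
                    condition=get(row, "condition"),
                )
                if rtype == "aggression":
                    off_cell = get(row, "offset_s")
                    try:
                        offset = float(off_cell) if off_cell else onset
                    except ValueError:
                        raise RowError(idx, f"unparseable time {off_cell!r}")
                    intensity = get(row, "intensity", "undetermined") or "undetermined"
                    context = get(row, "context", "unknown") or "unknown"
                    if intensity not in INTENSITIES:
                        raise RowError(idx, f"unknown intensity value {intensity!r}")
                    if context not in CONTEXTS:
                        raise RowError(idx, f"unknown context value {context!r}")
                    reaction = frozenset(
                        r for r in get(row, "reaction").split(LIST_SEP) if r
                    )
                    try:
                        ev: Union[AggressionEvent, AffiliationEvent] = AggressionEvent(
                            onset_s=onset,
                            offset_s=offset,
                            aggressor_id=get(row, "actor"),
                            victim_id=get(row, "target"),
                            intensity=intensity,
                            context=context,
                            behaviour_elements=tuple(
                                b for b in get(row, "behaviour").split(TYPE_SEP) if b
                            ),
                            through_mesh=_parse_bool(get(row, "through_mesh")),
                            reaction=reaction,
                            interventions=_parse_interventions(get(row, "interventions")),
                            intervention_undetermined=_parse_bool(
                                get(row, "intervention_undetermined")
                            ),
                            **common,
                        )
                    except ValueError as exc:
                        raise RowError(idx, str(exc))
                    log.aggressions.append(ev)
                    report.n_aggressions += 1
                elif rtype == "affiliation":
                    types = tuple(
                        b for b in get(row, "behaviour").split(TYPE_SEP) if b
                    )
                    try:
                        ev = AffiliationEvent(
                            onset_s=onset,
                            participant_a=get(row, "actor"),
                            participant_b=get(row, "target"),
                            behaviour_types=types or ("contact_sitting",),
                            initiator_id=get(row, "initiator"),
                            visibility_ok=_parse_bool(get(row, "visibility_ok") or "true"),
                            **common,
                        )
                    except ValueError as exc:
                        raise RowError(idx, str(exc))
                    log.affiliations.append(ev)
                    report.n_affiliations += 1
                else:
                    raise RowError(idx, f"unknown record_type {rtype!r}")
            except RowError as exc:
                if strict:
                    raise
                report.skipped.append((exc.row, str(exc)))
        return log.sort(), report
    finally:
        if close:
            fh.close()


def write_coding_sheet(log: EventLog, target: Union[str, TextIO]) -> None:
    """Serialise an event log to the canonical coding-sheet CSV.

    The output is a bit-exact fixed dialect (UTF-8, comma-separated,
    ``+``-joined behaviour types) so that write/read round-trips are
    identities on valid logs."""
    close = False
    if isinstance(target, str):
        fh: TextIO = open(target, "w", newline="", encoding="utf-8")
        close = True
    else:
        fh = target
    try:
        writer = csv.DictWriter(fh, fieldnames=CANONICAL_COLUMNS)
        writer.writeheader()
        rows: list[tuple[tuple, dict]] = []
        for ev in log.aggressions:
            rows.append(((ev.date, ev.onset_s, 0, ev.event_id), {
                "record_type": "aggression",
                "event_id": ev.event_id,
                "date": ev.date.isoformat(),
                "onset_s": repr(ev.onset_s),
                "offset_s": repr(ev.offset_s),
                "condition": ev.condition,
                "actor": ev.aggressor_id,
                "target": ev.victim_id,
                "intensity": ev.intensity,
                "context": ev.context,
                "behaviour": TYPE_SEP.join(ev.behaviour_elements),
                "through_mesh": int(ev.through_mesh),
                "reaction": LIST_SEP.join(sorted(ev.reaction)),
                "interventions": _fmt_interventions(ev.interventions),
                "intervention_undetermined": int(ev.intervention_undetermined),
                "initiator": "",
                "visibility_ok": "",
            }))
        for ev in log.affiliations:
            rows.append(((ev.date, ev.onset_s, 1, ev.event_id), {
                "record_type": "affiliation",
                "event_id": ev.event_id,
                "date": ev.date.isoformat(),
                "onset_s": repr(ev.onset_s),
                "offset_s": "",
                "condition": ev.condition,
                "actor": ev.participant_a,
                "target": ev.participant_b,
                "intensity": "",
                "context": "",
                "behaviour": TYPE_SEP.join(ev.behaviour_types),
                "through_mesh": "",
                "reaction": "",
                "interventions": "",
                "intervention_undetermined": "",
                "initiator": ev.initiator_id,
                "visibility_ok": int(ev.visibility_ok),
            }))
        for _, row in sorted(rows, key=lambda r: r[0]):
            writer.writerow(row)
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_text(self) -> str:
        if self.ok:
            return "log valid: no violations\n"
        return "\n".join(self.violations) + "\n"


def validate_log(log: EventLog) -> ValidationReport:
    """Check every type invariant across an event log.

    Reports (never raises): unknown individual ids, negative durations,
    self-directed aggression, intervener involvement, missing subgroup for
    indoor events, events outside any recorded session."""
    rep = ValidationReport()
    ids = {ind.id for ind in log.setup.roster}
    by_date = {s.date: s for s in log.setup.session_calendar}

    def check_session(ev, onset, kind):
        s = by_date.get(ev.date)
        if s is None:
            rep.violations.append(f"{kind} {ev.event_id}: no session on {ev.date}")
        elif not (0 <= onset <= s.duration_s):
            rep.violations.append(
                f"{kind} {ev.event_id}: onset {onset} outside session duration"
            )
        elif s.condition != ev.condition:
            rep.violations.append(
                f"{kind} {ev.event_id}: condition {ev.condition} != session {s.condition}"
            )

    def check_subgroup(ev, ind_id, kind):
        if ev.condition == "indoor" and ind_id in ids:
            if log.setup.individual(ind_id).subgroup == "none":
                rep.violations.append(
                    f"{kind} {ev.event_id}: indoor event but {ind_id} has no subgroup"
                )

    for ev in log.aggressions:
        for who in (ev.aggressor_id, ev.victim_id):
            if who not in ids:
                rep.violations.append(
                    f"aggression {ev.event_id}: unknown individual {who!r}"
                )
            check_subgroup(ev, who, "aggression")
        for rec in ev.interventions:
            if rec.intervener_id not in ids:
                rep.violations.append(
                    f"aggression {ev.event_id}: unknown intervener {rec.intervener_id!r}"
                )
        check_session(ev, ev.onset_s, "aggression")
    for ev in log.affiliations:
        for who in (ev.participant_a, ev.participant_b):
            if who not in ids:
                rep.violations.append(
                    f"affiliation {ev.event_id}: unknown individual {who!r}"
                )
            check_subgroup(ev, who, "affiliation")
        if ev.initiator_id and not ev.involves(ev.initiator_id):
            rep.violations.append(
                f"affiliation {ev.event_id}: initiator not a participant"
            )
        check_session(ev, ev.onset_s, "affiliation")
    return rep


# ---------------------------------------------------------------------------
# roster / calendar YAML
# ---------------------------------------------------------------------------


def dump_setup(setup: StudySetup) -> str:
    doc = {
        "roster": [
            {
                "id": i.id, "sex": i.sex, "age_class": i.age_class,
                "subgroup": i.subgroup,
                "kin_links": sorted([list(k) for k in i.kin_links]),
            }
            for i in setup.roster
        ],
        "hours_by_condition": dict(setup.hours_by_condition),
        "sessions": [
            {
                "date": s.date.isoformat(),
                "start": s.start.isoformat(),
                "duration_s": s.duration_s,
                "condition": s.condition,
            }
            for s in setup.session_calendar
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def load_setup(source: Union[str, TextIO]) -> StudySetup:
    if isinstance(source, str):
        with open(source, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(source)
    roster = [
        Individual(
            id=r["id"], sex=r["sex"], age_class=r["age_class"],
            subgroup=r.get("subgroup", "none"),
            kin_links=frozenset(tuple(k) for k in r.get("kin_links", [])),
        )
        for r in doc["roster"]
    ]
    sessions = [
        SessionInfo(
            date=dt.date.fromisoformat(s["date"]),
            start=dt.time.fromisoformat(s["start"]),
            duration_s=float(s["duration_s"]),
            condition=s["condition"],
        )
        for s in doc["sessions"]
    ]
    return StudySetup(
        roster=roster, session_calendar=sessions,
        hours_by_condition={
            k: float(v) for k, v in doc.get("hours_by_condition", {}).items()
        },
    )
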