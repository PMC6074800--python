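"""Post-conflict / matched-control (PC/MC) extraction and classification.

For every conflict the 10-minute post-conflict window (PC) is anchored at
the conflict's end, with the restart rule: if the same opponents resume
fighting within the first 3 minutes, the PC is abandoned and re-anchored
immediately after the resumed aggression ends (recursively).  Each PC is
paired with a matched-control window (MC) on the nearest recorded day at
the same clock time (±60 min, ±7 days) that was not preceded by a
conflict within 10 minutes.  First affiliative-contact latencies of the
victim — with the former opponent and with uninvolved third parties — are
coded into 1-minute intervals, and each PC-MC pair is classified
attracted / dispersed / neutral per target.  The per-victim proportions
feed the exact signed-rank reconciliation (and third-party-affiliation)
test.

Conflicts in the context of male sexual coercion run through the same
machinery but are kept as a separate pair set and never pooled.
"""

from __future__ import annotations

import bisect
import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import pandas as pd

from .ethogram_model import (
    AffiliationEvent, AggressionEvent, EventLog, StudySetup,
)
from .stats_core import SignedRankResult, exact_signed_rank_test

__all__ = [
    "UNSPECIFIABLE", "PC_WINDOW_S", "RESTART_S", "Window", "PCRecord",
    "MCRecord", "PCMCPair", "PCMCAnalysis", "is_male_coercion",
    "build_chains", "extract_pc", "select_mc", "first_affiliation_latency",
    "classify_pair", "victim_proportions", "reconciliation_test",
    "build_pairs",
]

PC_WINDOW_S = 600.0   # 10-minute observation window
RESTART_S = 180.0     # conflict resumed within the first 3 min restarts the PC
MC_MAX_CLOCK_OFF_MIN = 60
MC_MAX_DAY_OFF = 7
MC_PRE_QUIET_S = 600.0  # required conflict-free span before an MC window

#: sentinel for a latency that exists but could not be coded (visibility)
UNSPECIFIABLE = "unspecifiable"

Latency = object  # int 1..10 | None | UNSPECIFIABLE
Target = Literal["opponent", "third_party"]


def is_male_coercion(ev: AggressionEvent, setup: StudySetup) -> bool:
    """Sexual-coercion event involving a male (forced copulation or a
    counter-aggression within such an episode).  Female-female coercion
    stays with the general conflict set."""
    if ev.context != "sexual_coercion":
        return False
    try:
        sexes = {setup.individual(ev.aggressor_id).sex,
                 setup.individual(ev.victim_id).sex}
    except KeyError:
        return False
    return "male" in sexes


@dataclass(frozen=True)
class Window:
    date: dt.date
    start_s: float      # seconds from that day's session start
    length_s: float = PC_WINDOW_S
    condition: str = "indoor"

    def contains(self, date: dt.date, s: float) -> bool:
        return date == self.date and self.start_s <= s <= self.start_s + self.length_s


@dataclass
class PCRecord:
    conflict_id: str
    focal: str
    opponent: str
    window: Optional[Window]          # None when the recording ended early
    restarted_from: tuple[str, ...] = ()   # consumed resumption event ids
    opponent_latency: Latency = None
    third_party_latency: Latency = None
    third_party_partner: Optional[str] = None

    @property
    def available(self) -> bool:
        return self.window is not None


@dataclass
class MCRecord:
    matched_pc: str
    window: Optional[Window]
    day_offset: int = 0
    clock_offset_min: int = 0
    opponent_latency: Latency = None
    third_party_latency: Latency = None

    @property
    def available(self) -> bool:
        return self.window is not None


Classification = Literal["attracted", "dispersed", "neutral", "excluded"]


@dataclass
class PCMCPair:
    pc: PCRecord
    mc: MCRecord
    classification_opponent: Classification = "excluded"
    classification_third_party: Classification = "excluded"
    exclusion_reason: Optional[str] = None
    condition: str = "indoor"

    @property
    def conflict_id(self) -> str:
        return self.pc.conflict_id

    @property
    def focal(self) -> str:
        return self.pc.focal

    def classification(self, target: Target) -> Classification:
        return (self.classification_opponent if target == "opponent"
                else self.classification_third_party)

    def analysable(self, target: Target) -> bool:
        return self.classification(target) != "excluded"

    def latencies(self, target: Target) -> tuple[Latency, Latency]:
        if target == "opponent":
            return self.pc.opponent_latency, self.mc.opponent_latency
        return self.pc.third_party_latency, self.mc.third_party_latency


# ---------------------------------------------------------------------------
# chain construction and PC extraction
# ---------------------------------------------------------------------------


def build_chains(
    aggressions: Sequence[AggressionEvent],
) -> list[list[AggressionEvent]]:
    """Group conflicts into resumption chains.

    Walking forward in time, a conflict's PC is restarted by any
    same-dyad aggression beginning within ``RESTART_S`` of the current
    anchor; such an event is consumed by the chain and never opens a PC
    of its own.  Returns chains in chronological order; singletons are
    chains of length one.
    """
    events = sorted(aggressions, key=lambda e: (e.date, e.onset_s, e.event_id))
    consumed: set[str] = set()
    chains: list[list[AggressionEvent]] = []
    for i, head in enumerate(events):
        if head.event_id in consumed:
            continue
        chain = [head]
        anchor = head.offset_s
        j = i + 1
        while j < len(events):
            nxt = events[j]
            j += 1
            if nxt.event_id in consumed or nxt.date != head.date:
                continue
            if nxt.onset_s >= anchor + RESTART_S:
                break
            if nxt.dyad == head.dyad:
                consumed.add(nxt.event_id)
                chain.append(nxt)
                anchor = nxt.offset_s
        chains.append(chain)
    return chains


def extract_pc(
    chain: Sequence[AggressionEvent], setup: StudySetup
) -> PCRecord:
    """PC window for a conflict chain: anchored at the end of the last
    resumption, marked unavailable when fewer than ``PC_WINDOW_S`` seconds
    of recording remain in the session."""
    head, last = chain[0], chain[-1]
    session = setup.session_on(head.date)
    anchor = last.offset_s
    window: Optional[Window] = None
    if session is not None and anchor + PC_WINDOW_S <= session.duration_s:
        window = Window(date=head.date, start_s=anchor, condition=head.condition)
    return PCRecord(
        conflict_id=head.event_id,
        focal=head.victim_id,
        opponent=head.aggressor_id,
        window=window,
        restarted_from=tuple(e.event_id for e in chain[1:]),
    )


# ---------------------------------------------------------------------------
# matched-control selection
# ---------------------------------------------------------------------------


def _clock_of(setup: StudySetup, date: dt.date, s: float) -> Optional[float]:
    session = setup.session_on(date)
    if session is None:
        return None
    return (session.start.hour * 3600 + session.start.minute * 60
            + session.start.second + s)


def select_mc(
    pc: PCRecord,
    aggressions: Sequence[AggressionEvent],
    setup: StudySetup,
) -> MCRecord:
    """Deterministic matched-control selection.

    Candidates are windows on recorded days within ±7 days at clock
    offsets of 0..±60 whole minutes from the PC window's onset time,
    fully inside the session, with no conflict overlapping the 10 minutes
    before the window.  The first admissible candidate in the order
    (|day offset|, |clock offset|, earlier clock time, future day first)
    is selected; if none exists the MC is unavailable.
    """
    if pc.window is None:
        return MCRecord(matched_pc=pc.conflict_id, window=None)
    pc_clock = _clock_of(setup, pc.window.date, pc.window.start_s)
    assert pc_clock is not None
    by_date: dict[dt.date, list[tuple[float, float]]] = {}
    for ev in aggressions:
        by_date.setdefault(ev.date, []).append((ev.onset_s, ev.offset_s))

    def admissible(date: dt.date, start_s: float, session) -> bool:
        if start_s < 0 or start_s + PC_WINDOW_S > session.duration_s:
            return False
        lo = start_s - MC_PRE_QUIET_S
        for onset, offset in by_date.get(date, ()):  # conflict overlapping pre-gap
            if offset > lo and onset < start_s:
                return False
        return True

    for abs_day in range(1, MC_MAX_DAY_OFF + 1):
        for abs_min in range(0, MC_MAX_CLOCK_OFF_MIN + 1):
            signs = (0,) if abs_min == 0 else (-1, 1)  # earlier clock first
            for sign in signs:
                for day_off in (abs_day, -abs_day):    # future day preferred
                    date2 = pc.window.date + dt.timedelta(days=day_off)
                    session = setup.session_on(date2)
                    if session is None:
                        continue
                    clock2 = pc_clock + sign * abs_min * 60
                    start2 = clock2 - (session.start.hour * 3600
                                       + session.start.minute * 60
                                       + session.start.second)
                    if admissible(date2, start2, session):
                        return MCRecord(
                            matched_pc=pc.conflict_id,
                            window=Window(date=date2, start_s=start2,
                                          condition=session.condition),
                            day_offset=day_off,
                            clock_offset_min=sign * abs_min,
                        )
    return MCRecord(matched_pc=pc.conflict_id, window=None)


# ---------------------------------------------------------------------------
# latency coding and classification
# ---------------------------------------------------------------------------


class _AffiliationIndex:
    """Per-date sorted affiliation index for fast window queries."""

    def __init__(self, affiliations: Sequence[AffiliationEvent]):
        self._by_date: dict[dt.date, tuple[list[float], list[AffiliationEvent]]] = {}
        for ev in sorted(affiliations, key=lambda e: (e.date, e.onset_s, e.event_id)):
            onsets, evs = self._by_date.setdefault(ev.date, ([], []))
            onsets.append(ev.onset_s)
            evs.append(ev)

    def in_window(self, window: Window) -> list[AffiliationEvent]:
        entry = self._by_date.get(window.date)
        if entry is None:
            return []
        onsets, evs = entry
        lo = bisect.bisect_left(onsets, window.start_s)
        hi = bisect.bisect_right(onsets, window.start_s + window.length_s)
        return evs[lo:hi]


def _interval_of(latency_s: float) -> int:
    """1-minute interval index: interval k covers (60(k-1), 60k] seconds,
    with a contact at exactly the window start assigned to interval 1."""
    return max(1, math.ceil(latency_s / 60.0 - 1e-9))


def first_affiliation_latency(
    affiliations,
    window: Window,
    focal: str,
    opponent: str,
    partner_filter: Target,
) -> Latency:
    """Interval (1..10) of the focal's first qualifying contact in the
    window, ``None`` if there is none, or :data:`UNSPECIFIABLE` when the
    earliest candidate could not be coded due to limited visibility."""
    index = (affiliations if isinstance(affiliations, _AffiliationIndex)
             else _AffiliationIndex(affiliations))
    for ev in index.in_window(window):
        if not ev.involves(focal):
            continue
        partner = ev.participant_b if ev.participant_a == focal else ev.participant_a
        if partner_filter == "opponent" and partner != opponent:
            continue
        if partner_filter == "third_party" and partner == opponent:
            continue
        if not ev.visibility_ok:
            return UNSPECIFIABLE
        return _interval_of(ev.onset_s - window.start_s)
    return None


def classify_pair(pc_interval: Latency, mc_interval: Latency) -> Classification:
    """Attracted / dispersed / neutral classification of one PC-MC pair.

    Attracted: contact earlier in PC (or PC only); dispersed: earlier in
    MC (or MC only); neutral: same interval in both, or no contact in
    either.  Unspecifiable input signals exclusion."""
    if pc_interval == UNSPECIFIABLE or mc_interval == UNSPECIFIABLE:
        return "excluded"
    if pc_interval is None and mc_interval is None:
        return "neutral"
    if mc_interval is None:
        return "attracted"
    if pc_interval is None:
        return "dispersed"
    if pc_interval < mc_interval:
        return "attracted"
    if pc_interval > mc_interval:
        return "dispersed"
    return "neutral"


# ---------------------------------------------------------------------------
# per-victim proportions and the paired test
# ---------------------------------------------------------------------------


def victim_proportions(
    pairs: Sequence[PCMCPair], target: Target = "opponent", min_received: int = 3
) -> pd.DataFrame:
    """Per-victim proportions of attracted / dispersed / neutral pairs.

    Victims contributing fewer than ``min_received`` analysable pairs are
    excluded (the minimum-three-aggressions inclusion rule)."""
    rows = []
    by_victim: dict[str, list[PCMCPair]] = {}
    for p in pairs:
        if p.analysable(target):
            by_victim.setdefault(p.focal, []).append(p)
    for victim in sorted(by_victim):
        ps = by_victim[victim]
        n = len(ps)
        counts = {c: sum(1 for p in ps if p.classification(target) == c)
                  for c in ("attracted", "dispersed", "neutral")}
        rows.append(dict(
            victim=victim, n_pairs=n,
            attracted=counts["attracted"] / n,
            dispersed=counts["dispersed"] / n,
            neutral=counts["neutral"] / n,
            included=n >= min_received,
        ))
    return pd.DataFrame(
        rows, columns=["victim", "n_pairs", "attracted", "dispersed",
                       "neutral", "included"],
    )


def reconciliation_test(
    proportions: pd.DataFrame, alternative: str = "greater"
) -> SignedRankResult:
    """Exact signed-rank test of attracted vs dispersed proportions across
    the included victims.  A significant excess of attracted pairs
    demonstrates reconciliation (opponent target) or post-conflict
    third-party affiliation (third-party target)."""
    inc = proportions[proportions.included]
    diffs = (inc.attracted - inc.dispersed).tolist()
    return exact_signed_rank_test(diffs, alternative=alternative)


# ---------------------------------------------------------------------------
# whole-log orchestration
# ---------------------------------------------------------------------------


@dataclass
class PCMCAnalysis:
    """All PC-MC pairs of one conflict subset, plus exclusion records."""

    pairs: list[PCMCPair] = field(default_factory=list)
    excluded_conflicts: list[tuple[str, str]] = field(default_factory=list)

    def analysable(self, target: Target) -> list[PCMCPair]:
        return [p for p in self.pairs if p.analysable(target)]

    def counts(self, target: Target) -> dict[str, int]:
        out = {"attracted": 0, "dispersed": 0, "neutral": 0}
        for p in self.analysable(target):
            out[p.classification(target)] += 1
        return out

    def proportions(self, target: Target = "opponent",
                    min_received: int = 3) -> pd.DataFrame:
        return victim_proportions(self.pairs, target, min_received)

    def test(self, target: Target = "opponent",
             min_received: int = 3) -> SignedRankResult:
        return reconciliation_test(self.proportions(target, min_received))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            rows.append(dict(
                conflict_id=p.conflict_id, victim=p.focal,
                opponent=p.pc.opponent, condition=p.condition,
                pc_opponent=p.pc.opponent_latency,
                mc_opponent=p.mc.opponent_latency,
                pc_third_party=p.pc.third_party_latency,
                mc_third_party=p.mc.third_party_latency,
                classification_opponent=p.classification_opponent,
                classification_third_party=p.classification_third_party,
                exclusion_reason=p.exclusion_reason or "",
            ))
        return pd.DataFrame(rows, columns=[
            "conflict_id", "victim", "opponent", "condition", "pc_opponent",
            "mc_opponent", "pc_third_party", "mc_third_party",
            "classification_opponent", "classification_third_party",
            "exclusion_reason",
        ])


def build_pairs(log: EventLog) -> tuple[PCMCAnalysis, PCMCAnalysis]:
    """Run the full PC/MC stage on an event log.

    Returns two analyses: conflicts outside male sexual coercion, and the
    male-coercion episodes (analysed with identical machinery, reported
    separately).  Chains are built over the whole log so that a resumed
    conflict never yields two PC windows.
    """
    chains = build_chains(log.aggressions)
    index = _AffiliationIndex(log.affiliations)
    general = PCMCAnalysis()
    coercion = PCMCAnalysis()
    for chain in chains:
        head = chain[0]
        analysis = coercion if is_male_coercion(head, log.setup) else general
        for member in chain[1:]:
            analysis.excluded_conflicts.append((member.event_id, "resumed"))
        pc = extract_pc(chain, log.setup)
        if not pc.available:
            analysis.excluded_conflicts.append((head.event_id, "pc_unavailable"))
            analysis.pairs.append(PCMCPair(
                pc=pc, mc=MCRecord(matched_pc=pc.conflict_id, window=None),
                exclusion_reason="pc_unavailable", condition=head.condition,
            ))
            continue
        mc = select_mc(pc, log.aggressions, log.setup)
        if not mc.available:
            analysis.excluded_conflicts.append((head.event_id, "mc_unavailable"))
            analysis.pairs.append(PCMCPair(
                pc=pc, mc=mc, exclusion_reason="mc_unavailable",
                condition=head.condition,
            ))
            continue
        pc.opponent_latency = first_affiliation_latency(
            index, pc.window, pc.focal, pc.opponent, "opponent")
        pc.third_party_latency = first_affiliation_latency(
            index, pc.window, pc.focal, pc.opponent, "third_party")
        mc.opponent_latency = first_affiliation_latency(
            index, mc.window, pc.focal, pc.opponent, "opponent")
        mc.third_party_latency = first_affiliation_latency(
            index, mc.window, pc.focal, pc.opponent, "third_party")
        pair = PCMCPair(pc=pc, mc=mc, condition=head.condition)
        pair.classification_opponent = classify_pair(
            pc.opponent_latency, mc.opponent_latency)
        pair.classification_third_party = classify_pair(
            pc.third_party_latency, mc.third_party_latency)
        reasons = []
        if pair.classification_opponent == "excluded":
            reasons.append("unspecifiable_opponent")
        if pair.classification_third_party == "excluded":
            reasons.append("unspecifiable_third_party")
        pair.exclusion_reason = ",".join(reasons) or None
        analysis.pairs.append(pair)
    return general, coercion
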