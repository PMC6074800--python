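"""Descriptive and condition-contrast analyses of the aggression log.

Covers the first analysis stage: chaining aggressions into causally
connected conflict sequences, tabulating context and intensity, comparing
per-individual hourly aggression rates between housing conditions with
the exact signed-rank test, Fisher contrasts for intensity and for the
mesh separating indoor subgroups, and the directed weighted aggression
network.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .ethogram_model import (
    CONDITIONS, INTENSITIES, CONTEXTS, AggressionEvent, StudySetup,
)
from .stats_core import (
    FisherResult, RxCResult, SignedRankResult, UndefinedTestError,
    exact_signed_rank_test, fisher_exact_2x2, fisher_exact_rxc,
)

__all__ = [
    "ConflictSequence", "RateTable", "segment_conflicts",
    "aggression_intensity", "summarize_contexts", "aggression_rates",
    "condition_intensity_test", "mesh_effect_test", "aggression_network",
    "DEFAULT_ETHOGRAM_INTENSITY",
]

#: default mapping from ethogram behaviour elements to intensity ranks
DEFAULT_ETHOGRAM_INTENSITY = {
    "stare": "low", "gentle_push": "low", "displace": "low",
    "withhold": "low", "push": "medium", "grab": "medium",
    "pull": "medium", "hit": "medium", "chase": "medium",
    "wrestle": "medium", "bite": "high", "bite_attempt": "high",
    "forced_copulation": "high",
}

_RANK = {"low": 0, "medium": 1, "high": 2}


@dataclass(frozen=True)
class ConflictSequence:
    member_event_ids: tuple[str, ...]

    @property
    def is_distinct(self) -> bool:
        return len(self.member_event_ids) == 1

    @property
    def size(self) -> int:
        return len(self.member_event_ids)


def _abs_time(ev: AggressionEvent, s: float) -> dt.datetime:
    return dt.datetime.combine(ev.date, dt.time()) + dt.timedelta(seconds=s)


def segment_conflicts(
    aggressions: Sequence[AggressionEvent], gap_s: float = 240.0
) -> list[ConflictSequence]:
    """Chain aggressions into conflict sequences.

    An event joins the open sequence when it begins within ``gap_s``
    seconds of the previous event's end (default 4 min); events on
    different dates never chain.  The sequences partition the input.
    """
    events = sorted(aggressions, key=lambda e: (e.date, e.onset_s, e.event_id))
    out: list[ConflictSequence] = []
    current: list[AggressionEvent] = []
    for ev in events:
        if current:
            prev = current[-1]
            gap = (_abs_time(ev, ev.onset_s) - _abs_time(prev, prev.offset_s)).total_seconds()
            if prev.date == ev.date and gap < gap_s:
                current.append(ev)
                continue
            out.append(ConflictSequence(tuple(e.event_id for e in current)))
            current = []
        current.append(ev)
    if current:
        out.append(ConflictSequence(tuple(e.event_id for e in current)))
    return out


def aggression_intensity(
    behaviour_elements: Iterable[str],
    ethogram_intensity_map: Optional[dict[str, str]] = None,
) -> str:
    """Intensity of a composite aggression: the rank of its most intense
    constituent, or ``'undetermined'`` if the element list is empty or
    contains an unmapped element."""
    elements = list(behaviour_elements)
    m = DEFAULT_ETHOGRAM_INTENSITY if ethogram_intensity_map is None else ethogram_intensity_map
    if not elements or any(e not in m for e in elements):
        return "undetermined"
    return max((m[e] for e in elements), key=_RANK.__getitem__)


def summarize_contexts(aggressions: Sequence[AggressionEvent]) -> pd.DataFrame:
    """Context x intensity count table with margins and proportions."""
    tab = pd.DataFrame(0, index=list(CONTEXTS), columns=list(INTENSITIES))
    for ev in aggressions:
        tab.loc[ev.context, ev.intensity] += 1
    tab["total"] = tab.sum(axis=1)
    n = len(aggressions)
    tab["proportion"] = tab["total"] / n if n else 0.0
    return tab


@dataclass
class RateTable:
    """Per-individual, per-condition aggression rates (as aggressor)."""

    table: pd.DataFrame  # columns: individual, condition, count, hours, rate

    def rate(self, individual: str, condition: str) -> float:
        sel = self.table[
            (self.table.individual == individual) & (self.table.condition == condition)
        ]
        return float(sel.rate.iloc[0])

    def median_rate(self, condition: str) -> float:
        return float(self.table[self.table.condition == condition].rate.median())


def aggression_rates(
    aggressions: Sequence[AggressionEvent], setup: StudySetup
) -> tuple[RateTable, SignedRankResult]:
    """Hourly aggression rates per individual and condition, plus the
    one-tailed exact signed-rank test of indoor > outdoor.

    Every roster member uses the full condition observation hours as the
    denominator (the whole group was on camera throughout).  Individuals
    with identical rates in both conditions drop out of the test through
    the zero rule.
    """
    for c in CONDITIONS:
        if setup.hours_by_condition.get(c, 0.0) <= 0:
            raise ValueError(f"no observation hours for condition {c!r}")
    rows = []
    counts: dict[tuple[str, str], int] = {}
    for ev in aggressions:
        counts[(ev.aggressor_id, ev.condition)] = counts.get(
            (ev.aggressor_id, ev.condition), 0) + 1
    for ind in setup.roster:
        for c in CONDITIONS:
            h = setup.hours_by_condition[c]
            k = counts.get((ind.id, c), 0)
            rows.append(dict(individual=ind.id, condition=c, count=k,
                             hours=h, rate=k / h))
    table = pd.DataFrame(rows)
    diffs = [
        table[(table.individual == i.id) & (table.condition == "indoor")].rate.iloc[0]
        - table[(table.individual == i.id) & (table.condition == "outdoor")].rate.iloc[0]
        for i in setup.roster
    ]
    test = exact_signed_rank_test(diffs, alternative="greater")
    return RateTable(table), test


def condition_intensity_test(
    aggressions: Sequence[AggressionEvent],
) -> tuple[FisherResult, RxCResult]:
    """Is high-intensity aggression over-represented indoors?

    Pooled 2x2 (high vs not-high x indoor vs outdoor; undetermined
    intensities excluded) plus an influence control: an exact r x 2 test
    of aggressor identity x condition among the high-intensity events, to
    show the pooled effect is not driven by single individuals.
    """
    det = [e for e in aggressions if e.intensity != "undetermined"]
    if not {e.condition for e in det} >= set(CONDITIONS):
        return (
            FisherResult(p=1.0, or_cmle=float("nan"),
                         table=((0, 0), (0, 0)), degenerate=True),
            RxCResult(p=1.0, method="exact"),
        )
    def cell(cond, high):
        return sum(1 for e in det
                   if e.condition == cond and (e.intensity == "high") == high)
    pooled = fisher_exact_2x2(
        [[cell("indoor", True), cell("indoor", False)],
         [cell("outdoor", True), cell("outdoor", False)]]
    )
    high = [e for e in det if e.intensity == "high"]
    aggressors = sorted({e.aggressor_id for e in high})
    ctrl_tab = [
        [sum(1 for e in high if e.aggressor_id == a and e.condition == "indoor"),
         sum(1 for e in high if e.aggressor_id == a and e.condition == "outdoor")]
        for a in aggressors
    ]
    control = fisher_exact_rxc(ctrl_tab) if ctrl_tab else RxCResult(p=1.0, method="exact")
    return pooled, control


def mesh_effect_test(
    aggressions: Sequence[AggressionEvent], subgroups: dict[str, str]
) -> FisherResult:
    """Pooled 2x2 test for a mesh effect on aggression frequency.

    A dyad is "separated" when its members belong to different indoor
    subgroups (a dyad property, applied in both conditions); the table is
    condition x separated over all events whose dyads have known
    subgroups."""
    def separated(ev: AggressionEvent) -> Optional[bool]:
        sa = subgroups.get(ev.aggressor_id, "none")
        sv = subgroups.get(ev.victim_id, "none")
        if ev.condition == "indoor" and ("none" in (sa, sv)):
            raise ValueError(
                f"indoor event {ev.event_id}: subgroup unknown for dyad"
            )
        if "none" in (sa, sv):
            return None
        return sa != sv

    cells = {(c, s): 0 for c in CONDITIONS for s in (True, False)}
    for ev in aggressions:
        s = separated(ev)
        if s is not None:
            cells[(ev.condition, s)] += 1
    return fisher_exact_2x2(
        [[cells[("indoor", True)], cells[("indoor", False)]],
         [cells[("outdoor", True)], cells[("outdoor", False)]]]
    )


def aggression_network(
    aggressions: Sequence[AggressionEvent],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Directed weighted aggression network.

    Returns an edge list (source, target, condition, weight) and a
    per-aggressor totals table with each aggressor's share of all events.
    """
    edges: dict[tuple[str, str, str], int] = {}
    for ev in aggressions:
        key = (ev.aggressor_id, ev.victim_id, ev.condition)
        edges[key] = edges.get(key, 0) + 1
    edge_df = pd.DataFrame(
        [dict(source=s, target=t, condition=c, weight=w)
         for (s, t, c), w in sorted(edges.items())]
    )
    if edge_df.empty:
        edge_df = pd.DataFrame(columns=["source", "target", "condition", "weight"])
        totals = pd.DataFrame(columns=["aggressor", "total", "share"])
        return edge_df, totals
    totals = (
        edge_df.groupby("source").weight.sum().rename("total").reset_index()
        .rename(columns={"source": "aggressor"})
        .sort_values("total", ascending=False, ignore_index=True)
    )
    totals["share"] = totals.total / totals.total.sum()
    return edge_df, totals
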