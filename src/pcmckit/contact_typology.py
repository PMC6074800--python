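"""Behaviour-type composition of post-conflict vs control affiliations.

Compares which affiliative behaviours (contact sitting, touching,
embracing, play, ...) victims and third parties exchanged during the PC
windows against the matched-control windows.  A contact may combine two
behaviour types, each counted once per contact, so type proportions may
sum to more than 100%.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .ethogram_model import AffiliationEvent, EventLog
from .pcmc import PCMCPair, _AffiliationIndex
from .stats_core import (
    FisherResult, RxCResult, fisher_exact_2x2, fisher_exact_rxc,
)

__all__ = [
    "gather_window_contacts", "behaviour_type_table", "type_association_test",
]


def gather_window_contacts(
    pairs: Sequence[PCMCPair], log: EventLog
) -> tuple[list[AffiliationEvent], list[AffiliationEvent]]:
    """All codable victim-third-party contacts inside the PC and MC
    windows of the third-party-analysable pairs (not only the first)."""
    index = _AffiliationIndex(log.affiliations)
    pc_contacts: list[AffiliationEvent] = []
    mc_contacts: list[AffiliationEvent] = []
    for p in pairs:
        if not p.analysable("third_party"):
            continue
        for window, bucket in ((p.pc.window, pc_contacts),
                               (p.mc.window, mc_contacts)):
            if window is None:
                continue
            for ev in index.in_window(window):
                if not ev.involves(p.focal) or ev.involves(p.pc.opponent):
                    continue
                if ev.visibility_ok:
                    bucket.append(ev)
    return pc_contacts, mc_contacts


def behaviour_type_table(
    pc_contacts: Sequence[AffiliationEvent],
    mc_contacts: Sequence[AffiliationEvent],
) -> pd.DataFrame:
    """Absolute and relative frequency of each behaviour type per
    condition; proportions are relative to the number of contacts (not
    type tokens) in that condition."""
    types: list[str] = []
    for ev in list(pc_contacts) + list(mc_contacts):
        for t in ev.behaviour_types:
            if t not in types:
                types.append(t)
    n_pc, n_mc = len(pc_contacts), len(mc_contacts)
    rows = []
    for t in types:
        pc_n = sum(1 for ev in pc_contacts if t in ev.behaviour_types)
        mc_n = sum(1 for ev in mc_contacts if t in ev.behaviour_types)
        rows.append(dict(
            behaviour=t, pc_n=pc_n,
            pc_prop=pc_n / n_pc if n_pc else 0.0,
            mc_n=mc_n,
            mc_prop=mc_n / n_mc if n_mc else 0.0,
        ))
    df = pd.DataFrame(rows, columns=["behaviour", "pc_n", "pc_prop",
                                     "mc_n", "mc_prop"])
    df.attrs["n_pc"] = n_pc
    df.attrs["n_mc"] = n_mc
    return df.sort_values("pc_n", ascending=False, ignore_index=True)


def type_association_test(
    table: pd.DataFrame,
    behaviour: str,
    pc_contacts: Optional[Sequence[AffiliationEvent]] = None,
    mc_contacts: Optional[Sequence[AffiliationEvent]] = None,
) -> tuple[FisherResult, Optional[RxCResult]]:
    """Is a behaviour type over-represented after conflicts?

    Pooled 2x2 over contacts ([with vs without the behaviour] x [PC vs
    MC]).  When the underlying contacts are supplied, adds a dyad
    influence control (dyad x condition among contacts showing the
    behaviour) to check the effect is not carried by single dyads.
    """
    sel = table[table.behaviour == behaviour]
    if sel.empty:
        raise KeyError(f"behaviour {behaviour!r} not in table")
    n_pc = table.attrs.get("n_pc", int(table.pc_n.sum()))
    n_mc = table.attrs.get("n_mc", int(table.mc_n.sum()))
    pc_n = int(sel.pc_n.iloc[0])
    mc_n = int(sel.mc_n.iloc[0])
    pooled = fisher_exact_2x2([[pc_n, n_pc - pc_n], [mc_n, n_mc - mc_n]])
    control: Optional[RxCResult] = None
    if pc_contacts is not None and mc_contacts is not None:
        dyads = sorted({
            tuple(sorted(ev.dyad))
            for evs in (pc_contacts, mc_contacts)
            for ev in evs if behaviour in ev.behaviour_types
        })
        rows = []
        for d in dyads:
            rows.append([
                sum(1 for ev in pc_contacts
                    if behaviour in ev.behaviour_types and tuple(sorted(ev.dyad)) == d),
                sum(1 for ev in mc_contacts
                    if behaviour in ev.behaviour_types and tuple(sorted(ev.dyad)) == d),
            ])
        if rows:
            control = fisher_exact_rxc(rows)
    return pooled, control
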