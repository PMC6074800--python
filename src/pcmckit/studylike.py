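"""Synthetic study-mimic event log (deterministic, no randomness).

This module constructs a fully synthetic coding sheet whose pipeline
output reproduces the headline counts of the orangutan study the
package's analyses are designed for: 114 aggressive interactions (85
distinct, 29 in sequences of two to four), 93 conflicts outside male
sexual coercion, 70 analysable opponent PC-MC pairs (31 attracted / 16
dispersed / 23 neutral), 72 third-party pairs (29/26/17), a 2-minute
cumulative-gap maximum of 0.243, 29/70 conflicts reconciled, 22/93
conflicts with third-party intervention (odds ratio ~4.3 indoor vs
outdoor), indoor median aggression rate 0.144/h vs 0.020/h outdoor, 13
analysable coercion PCs, and the Table-2-shaped behaviour typology of
post-conflict third-party contacts (53 PC vs 54 MC contacts).

The log is synthetic: event times sit on a regular slot grid chosen so
that post-conflict windows, matched-control windows and planted
affiliative contacts never interfere, and all latencies are placed by
construction.  It exists so that every stage of the pipeline can be
exercised end-to-end against known printed totals without any external
data file.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .ethogram_model import (
    AffiliationEvent, AggressionEvent, EventLog, InterventionRecord,
    StudySetup,
)
from .pcmc import build_chains, extract_pc, select_mc, Window
from .synthetic_data import default_calendar, study_roster

__all__ = ["study_mimic_log"]

# short ids used throughout the tables below
WA, TO, TA, EI, SU, DM = "Walter", "Toba", "Tao", "Eirina", "Suma", "Djamuna"

# outcome encoding: ("A", pc_interval) attracted with PC first contact in
# that interval; ("D", mc_interval) dispersed; ("N",) neutral (no contact
# in either window); ("U",) latency unspecifiable (visibility-masked
# earliest contact).  None: conflict without an analysable pair.
A = lambda k: ("A", k)
D = lambda k: ("D", k)
N = ("N",)
U = ("U",)


@dataclass
class _Group:
    """One slot-group of aggression events (a conflict or a chain)."""

    kind: str                      # plain | chain | pair200 | unavail | coercion
    condition: str
    events: list[tuple[str, str]]  # (aggressor, victim) per event
    contexts: list[str]
    intensities: list[str]
    opp: Optional[tuple] = None
    tp: Optional[tuple] = None
    opp2: Optional[tuple] = None   # second conflict of a pair200 group
    tp2: Optional[tuple] = None
    interventions: tuple[InterventionRecord, ...] = ()
    undetermined: bool = False
    coercion_opp_contact: bool = False


def _p(mode: str, who: str, supported: str,
       successful: bool = True) -> InterventionRecord:
    return InterventionRecord(who, mode, supported, successful)


def _build_groups() -> list[_Group]:
    g: list[_Group] = []

    def add(kind, cond, events, ctxs, intens, **kw):
        g.append(_Group(kind, cond, events, ctxs, intens, **kw))

    sp, wn, fd, ob, pu, uk, sc = ("spontaneous", "weaning", "food", "object",
                                  "punishment", "unknown", "sexual_coercion")

    # ---- outdoor, victim Djamuna --------------------------------------
    add("chain", "outdoor", [(TO, DM)] * 4, [sp] * 4, ["medium"] * 4,
        opp=A(1), tp=A(1))
    add("chain", "outdoor", [(TO, DM)] * 4, [sp] * 4, ["medium"] * 4,
        opp=A(1), tp=A(1))
    # plain outdoor pairs P1..P8 (To->Dm x7, Ta->Dm x1)
    p_specs = [
        ((TO, DM), fd, "high", A(2), A(1), (_p("peaceful", SU, DM),)),
        ((TO, DM), ob, "medium", A(3), A(1), (_p("peaceful", SU, DM),)),
        ((TO, DM), sp, "high", D(1), A(2),
         (_p("peaceful", TA, DM, successful=False),)),
        ((TO, DM), sc, "medium", D(3), A(3), ()),
        ((TO, DM), sc, "medium", N, D(1), ()),
        ((TO, DM), sc, "medium", N, D(1), ()),
        ((TO, DM), sc, "medium", N, U, ()),
        ((TA, DM), sp, "medium", N, U, ()),
    ]
    for (ev, ctx, inten, opp, tp, ivs) in p_specs:
        add("plain", "outdoor", [ev], [ctx], [inten], opp=opp, tp=tp,
            interventions=ivs)
    # opponent-unspecifiable conflicts U1..U3 (To->Dm)
    for ctx, tp in ((sc, A(1)), (uk, D(1)), (uk, N)):
        add("plain", "outdoor", [(TO, DM)], [ctx],
            ["medium" if ctx == sc else "undetermined"], opp=U, tp=tp)
    # PC-unavailable conflicts (recording ends inside the window)
    add("unavail", "outdoor", [(TO, DM)], [sp], ["medium"])
    add("unavail", "outdoor", [(TO, DM)], [sp], ["medium"])
    add("unavail", "outdoor", [(TO, TA)], [wn], ["low"])

    # ---- outdoor, victim Tao ------------------------------------------
    add("chain", "outdoor", [(TO, TA)] * 4, [wn] * 4, ["low"] * 4,
        opp=A(1), tp=A(1))
    add("plain", "outdoor", [(TO, TA)], [wn], ["low"], opp=U, tp=D(1))

    # ---- outdoor, victims Toba / Suma ---------------------------------
    add("plain", "outdoor", [(SU, TO)], [sp], ["medium"], opp=A(2), tp=A(1))
    add("plain", "outdoor", [(SU, TO)], [sp], ["medium"], opp=N, tp=A(1))
    add("plain", "outdoor", [(DM, TO)], [sp], ["medium"], opp=U, tp=D(1))
    add("plain", "outdoor", [(TO, SU)], [sp], ["medium"], opp=N, tp=A(1))
    add("plain", "outdoor", [(TO, SU)], [sp], ["medium"], opp=N, tp=D(1))

    # ---- outdoor male coercion (singletons) ---------------------------
    for _ in range(3):
        add("coercion", "outdoor", [(WA, TO)], [sc], ["high"],
            interventions=(_p("aggressive", EI, TO, successful=False),))

    # ---- indoor, victim Djamuna ---------------------------------------
    add("chain", "indoor", [(SU, DM)] * 4, [sp] * 4, ["medium"] * 4,
        opp=A(1), tp=A(1))
    # two same-dyad conflicts 200 s apart: one 4-min sequence, no restart
    add("pair200", "indoor", [(TO, DM), (TO, DM)], [sp, ob],
        ["medium", "medium"], opp=A(1), tp=N, opp2=A(1), tp2=N)
    q_specs = [  # Q1..Q5 To->Dm, Q6..Q9 Su->Dm
        ((TO, DM), sp, "medium", A(1), A(1),
         (_p("aggressive", SU, DM), _p("aggressive", WA, DM))),
        ((TO, DM), sp, "medium", A(1), A(1),
         (_p("peaceful", SU, DM), _p("peaceful", WA, DM))),
        ((TO, DM), sp, "high", A(2), D(1),
         (_p("aggressive", SU, DM),)),
        ((TO, DM), sp, "high", D(1), D(2), (_p("peaceful", SU, DM),)),
        ((TO, DM), sp, "high", D(1), D(3), ()),
        ((SU, DM), fd, "medium", D(2), N, (_p("peaceful", TO, DM),)),
        ((SU, DM), fd, "medium", N, N, (_p("peaceful", TO, DM),)),
        ((SU, DM), ob, "medium", N, N, (_p("peaceful", TO, DM),)),
        ((SU, DM), uk, "undetermined", N, A(1), (_p("peaceful", TO, DM),)),
    ]
    for (ev, ctx, inten, opp, tp, ivs) in q_specs:
        add("plain", "indoor", [ev], [ctx], [inten], opp=opp, tp=tp,
            interventions=ivs)

    # ---- indoor, victim Tao (To->Ta) ----------------------------------
    r_specs = [
        (wn, "low", A(1), A(1), (_p("peaceful", SU, TA), _p("peaceful", EI, TA))),
        (wn, "low", A(1), A(1), (_p("peaceful", SU, TA),)),
        (wn, "low", A(1), D(1), (_p("peaceful", WA, TA),)),
        (wn, "low", A(1), D(1), ()),
        (wn, "low", A(1), U, ()),
        (wn, "medium", A(2), U, ()),
        (wn, "medium", A(2), D(1), ()),
        (wn, "medium", D(1), D(1), ()),
        (wn, "medium", D(1), D(2), ()),
        (wn, "high", D(2), D(2), ()),
        (wn, "low", D(4), D(2), ()),
        (sp, "high", N, D(4), ()),
        (sp, "high", N, N, (), True),       # intervention undeterminable
        (sp, "high", N, N, ()),
        (sp, "high", N, N, ()),
        (sp, "high", N, A(1), ()),
    ]
    for spec in r_specs:
        ctx, inten, opp, tp, ivs = spec[:5]
        add("plain", "indoor", [(TO, TA)], [ctx], [inten], opp=opp, tp=tp,
            interventions=ivs, undetermined=len(spec) > 5 and spec[5])
    add("plain", "indoor", [(TO, TA)], [sp], ["high"], opp=U, tp=A(1))
    add("plain", "indoor", [(TO, TA)], [sp], ["high"], opp=U, tp=D(1))

    # ---- indoor, victim Toba ------------------------------------------
    to_specs = [
        ((SU, TO), sp, "high", A(1), A(1)),
        ((SU, TO), sp, "medium", A(1), U),
        ((SU, TO), fd, "medium", A(1), D(1)),
        ((SU, TO), ob, "high", D(1), D(2)),
        ((DM, TO), sp, "medium", D(2), N),
        ((DM, TO), sp, "high", N, A(1)),
        ((DM, TO), sp, "medium", N, N),
        ((DM, TO), fd, "high", N, N),
    ]
    for (ev, ctx, inten, opp, tp) in to_specs:
        add("plain", "indoor", [ev], [ctx], [inten], opp=opp, tp=tp)

    # ---- indoor, victim Suma (To->Su) ---------------------------------
    su_specs = [
        (sp, "high", A(1), A(1)), (ob, "medium", A(1), A(1)),
        (fd, "medium", A(1), U), (fd, "medium", A(1), D(1)),
        (fd, "high", A(2), D(3)), (uk, "undetermined", D(1), N),
        (pu, "medium", D(5), N), (sp, "medium", N, A(1)),
    ]
    for (ctx, inten, opp, tp) in su_specs:
        add("plain", "indoor", [(TO, SU)], [ctx], [inten], opp=opp, tp=tp)

    # ---- indoor, victim Eirina ----------------------------------------
    t_specs = [  # T1..T10 Ta->Ei
        (sp, "medium", A(1), A(1), (_p("aggressive", TO, EI),)),
        (sp, "medium", A(1), A(1), (_p("aggressive", TO, EI),)),
        (sp, "medium", A(2), D(1), (_p("aggressive", TO, EI),)),
        (sp, "medium", A(4), D(1), (_p("aggressive", TO, EI),)),
        (sp, "medium", D(1), A(1), (_p("aggressive", TO, EI),)),
        (sp, "medium", D(2), A(2), (_p("peaceful", TO, EI),)),
        (fd, "high", D(6), A(5), (_p("peaceful", TO, EI),)),
        (uk, "undetermined", N, D(2), (_p("peaceful", TO, EI),)),
        (uk, "undetermined", N, D(6), ()),
        (ob, "high", N, N, ()),
    ]
    for (ctx, inten, opp, tp, ivs) in t_specs:
        add("plain", "indoor", [(TA, EI)], [ctx], [inten], opp=opp, tp=tp,
            interventions=ivs)
    add("plain", "indoor", [(TO, EI)], [sp], ["low"], opp=U, tp=N)

    # ---- indoor, victim Walter ----------------------------------------
    add("plain", "indoor", [(TA, WA)], [sp], ["low"], opp=N, tp=N)

    # ---- indoor male coercion -----------------------------------------
    for i in range(7):
        add("coercion", "indoor", [(WA, TO)], [sc], ["high"],
            interventions=(
                (_p("aggressive", EI, TO, successful=False),
                 _p("aggressive", TA, TO, successful=False)) if i < 4 else
                (_p("aggressive", EI, TO, successful=False),)),
            coercion_opp_contact=(i == 0))
    # two copulation/counter chains of four (dyad Walter-Toba)
    for _ in range(2):
        add("coercion", "indoor",
            [(WA, TO), (TO, WA), (WA, TO), (TO, WA)],
            [sc] * 4, ["high", "medium", "high", "medium"],
            interventions=(_p("aggressive", EI, TO, successful=False),))
    # copulation/counter/copulation chain of three (dyad Walter-Tao)
    add("coercion", "indoor", [(WA, TA), (TA, WA), (WA, TA)],
        [sc] * 3, ["high", "medium", "high"],
        interventions=(_p("aggressive", TO, TA),))
    return g


# Table-2 behaviour-type allocations for victim/third-party contacts.
_CS, _TB, _EM, _PL = "contact_sitting", "touch_body", "embrace", "play"
_FO, _SF, _NU, _GR = "food_object_transfer", "suck_fur", "nursing", "grooming"
_SX, _CU, _CW, _PR = "sexual_interaction", "cuddling", "contact_walking", "sit_in_proximity"
_BG, _CF = "begging", "cofeeding"

_PC_TYPE_SETS: list[tuple[str, ...]] = (
    [(_CS, _TB)] * 6 + [(_CS, _EM)] * 3 + [(_CS, _PL)] * 2 + [(_CS, _FO)] * 2
    + [(_CS,)] * 11 + [(_TB,)] * 7 + [(_EM,)] * 3 + [(_PL,)] * 4
    + [(_FO,)] * 2 + [(_SF,)] * 3 + [(_NU,)] * 2 + [(_GR,)] * 2
    + [(_SX,)] * 2 + [(_CU,)] + [(_CW,)] + [(_PR,)] + [(_BG,)]
)  # 53 contacts, 66 type tokens (13 two-behaviour combinations)

_MC_TYPE_SETS: list[tuple[str, ...]] = (
    [(_PL, _TB)] * 8
    + [(_PL,)] * 15 + [(_TB,)] * 6 + [(_CS,)] * 8 + [(_SF,)] * 7
    + [(_CU,)] * 3 + [(_FO,)] * 3 + [(_EM,)] * 2 + [(_CW,)] + [(_CF,)]
)  # 54 contacts, 62 type tokens

#: third-party contact partner preference (first not involved in the conflict)
_TP_PRIORITY = [EI, SU, TO, TA, DM, WA]

_EVENT_DUR = 30.0
_COP_DUR = 60.0
_CHAIN_GAP = 100.0
_SLOT_MINUTES = [10 + 30 * i for i in range(10)]


def _tp_partner(focal: str, opponent: str) -> str:
    for cand in _TP_PRIORITY:
        if cand not in (focal, opponent):
            return cand
    raise RuntimeError("unreachable")


def study_mimic_log() -> EventLog:
    """Build the deterministic study-mimic event log."""
    setup = StudySetup(roster=study_roster(), session_calendar=default_calendar())
    groups = _build_groups()

    sessions = {c: [s for s in setup.session_calendar if s.condition == c]
                for c in ("outdoor", "indoor")}
    # last day of each block stays conflict-free so every matched control
    # resolves to the next recorded day
    usable = {c: ss[:-1] for c, ss in sessions.items()}
    cursor = {c: 0 for c in ("outdoor", "indoor")}  # round-robin day pointer
    used_slots: dict[dt.date, set[int]] = {}

    log = EventLog(setup=setup)
    n_agg = 0
    n_aff = 0

    def next_slot(cond: str, need_s: float) -> tuple:
        days = usable[cond]
        for _ in range(len(days) * 10):
            i = cursor[cond] % len(days)
            cursor[cond] += 1
            session = days[i]
            parity = i % 2
            nxt = setup.session_on(session.date + dt.timedelta(days=1))
            for idx in range(parity, 10, 2):
                if idx in used_slots.get(session.date, set()):
                    continue
                start = _SLOT_MINUTES[idx] * 60.0
                if start + need_s > session.duration_s:
                    continue
                if nxt is not None and start + need_s > nxt.duration_s:
                    continue  # keep the matched window realisable next day
                used_slots.setdefault(session.date, set()).add(idx)
                return session, start
        raise RuntimeError("slot grid exhausted")

    def new_agg(session, onset, dur, aggressor, victim, ctx, inten,
                ivs=(), undet=False) -> AggressionEvent:
        nonlocal n_agg
        n_agg += 1
        elements = {"low": ("gentle_push",), "medium": ("grab", "pull"),
                    "high": ("bite",), "undetermined": ()}[inten]
        if ctx == "sexual_coercion" and aggressor == WA:
            elements = ("forced_copulation", "grab")
        reaction = frozenset({"counter_aggression"} if ctx == "sexual_coercion"
                             and aggressor == WA else {"avoidance"})
        ev = AggressionEvent(
            event_id=f"c{n_agg:03d}", date=session.date, onset_s=onset,
            offset_s=onset + dur, condition=session.condition,
            aggressor_id=aggressor, victim_id=victim, intensity=inten,
            context=ctx, behaviour_elements=elements,
            through_mesh=(session.condition == "indoor"
                          and {aggressor, victim} & {SU, DM} != set()
                          and not {aggressor, victim} <= {SU, DM}),
            reaction=reaction, interventions=tuple(ivs),
            intervention_undetermined=undet,
        )
        log.aggressions.append(ev)
        return ev

    def new_aff(window: Window, offset: float, a: str, b: str,
                types: tuple[str, ...], visible: bool = True) -> None:
        nonlocal n_aff
        n_aff += 1
        session = setup.session_on(window.date)
        log.affiliations.append(AffiliationEvent(
            event_id=f"f{n_aff:03d}", date=window.date,
            onset_s=window.start_s + offset, condition=session.condition,
            participant_a=a, participant_b=b, behaviour_types=types,
            initiator_id=a, visibility_ok=visible,
        ))

    # ---- pass 1: place aggression events ------------------------------
    conflict_specs: list[tuple[str, _Group, int]] = []  # (head id, group, sub)
    coercion_plants: list[tuple[str, str, str, float, bool]] = []
    for grp in groups:
        if grp.kind == "unavail":
            session = usable[grp.condition][cursor[grp.condition] % len(usable[grp.condition])]
            cursor[grp.condition] += 1
            onset = session.duration_s - 330.0
            (a, v), = grp.events
            new_agg(session, onset, _EVENT_DUR, a, v, grp.contexts[0],
                    grp.intensities[0])
            continue
        if grp.kind == "pair200":
            session, start = next_slot(grp.condition, 230 + _EVENT_DUR + 600 + 60)
            e1 = new_agg(session, start, _EVENT_DUR, *grp.events[0],
                         grp.contexts[0], grp.intensities[0])
            e2 = new_agg(session, start + 230.0, _EVENT_DUR, *grp.events[1],
                         grp.contexts[1], grp.intensities[1])
            conflict_specs.append((e1.event_id, grp, 0))
            conflict_specs.append((e2.event_id, grp, 1))
            continue
        # plain / chain / coercion groups
        n_ev = len(grp.events)
        durs = [(_COP_DUR if grp.kind == "coercion" and ag == WA else _EVENT_DUR)
                for ag, _ in grp.events]
        span = sum(durs) + _CHAIN_GAP * (n_ev - 1) + 600 + 60
        session, start = next_slot(grp.condition, span)
        t = start
        head = None
        for k, ((a, v), dur) in enumerate(zip(grp.events, durs)):
            ivs = grp.interventions if (grp.kind != "coercion" and k == 0) else ()
            if grp.kind == "coercion" and a == WA:
                ivs = grp.interventions
            ev = new_agg(session, t, dur, a, v, grp.contexts[k],
                         grp.intensities[k], ivs,
                         grp.undetermined if k == 0 else False)
            if k == 0:
                head = ev
            if grp.kind == "coercion" and a == WA:
                # post-copulation mother/offspring affiliation (PCTA)
                focal = v
                partner = TO if v == TA else EI
                coercion_plants.append(
                    (head.event_id, focal, partner, t + dur + 5.0, True))
            t += dur + _CHAIN_GAP
        conflict_specs.append((head.event_id, grp, 0))

    log.sort()

    # ---- pass 2: compute PC and MC windows with the real machinery -----
    chains = build_chains(log.aggressions)
    windows: dict[str, tuple[Optional[Window], Optional[Window]]] = {}
    for chain in chains:
        pc = extract_pc(chain, setup)
        mc = select_mc(pc, log.aggressions, setup) if pc.available else None
        windows[chain[0].event_id] = (
            pc.window, mc.window if mc is not None else None)

    # ---- pass 3: plant affiliative contacts ----------------------------
    pc_type = iter(_PC_TYPE_SETS)
    mc_type = iter(_MC_TYPE_SETS)
    tp_attracted_windows: list[tuple[Window, str, str]] = []
    tp_dispersed_windows: list[tuple[Window, str, str]] = []

    for head_id, grp, sub in conflict_specs:
        if grp.kind == "coercion":
            continue
        pc_win, mc_win = windows[head_id]
        assert pc_win is not None and mc_win is not None, head_id
        opp, tp = (grp.opp2, grp.tp2) if sub == 1 else (grp.opp, grp.tp)
        victim = grp.events[0][1]
        opponent = grp.events[0][0]
        partner = _tp_partner(victim, opponent)
        if opp[0] == "A":
            new_aff(pc_win, (opp[1] - 1) * 60 + 30.0, victim, opponent, (_TB,))
        elif opp[0] == "D":
            new_aff(mc_win, (opp[1] - 1) * 60 + 30.0, victim, opponent, (_TB,))
        elif opp[0] == "U":
            new_aff(pc_win, 12.0, victim, opponent, (_TB,), visible=False)
        if tp[0] == "A":
            new_aff(pc_win, (tp[1] - 1) * 60 + 35.0, victim, partner,
                    next(pc_type))
            tp_attracted_windows.append((pc_win, victim, partner))
        elif tp[0] == "D":
            new_aff(mc_win, (tp[1] - 1) * 60 + 35.0, victim, partner,
                    next(mc_type))
            tp_dispersed_windows.append((mc_win, victim, partner))
        elif tp[0] == "U":
            new_aff(pc_win, 17.0, victim, partner, (_TB,), visible=False)

    # extra (non-first) contacts filling the Table-2 totals: 24 more in
    # PC windows of third-party-attracted pairs, 28 more in MC windows of
    # dispersed pairs (two windows host a second extra)
    for win, victim, partner in tp_attracted_windows[:24]:
        new_aff(win, 555.0, victim, partner, next(pc_type))
    for win, victim, partner in tp_dispersed_windows:
        new_aff(win, 550.0, victim, partner, next(mc_type))
    for win, victim, partner in tp_dispersed_windows[:2]:
        new_aff(win, 585.0, victim, partner, next(mc_type))
    assert next(pc_type, None) is None and next(mc_type, None) is None

    # coercion-window plants: consolation contacts after each copulation,
    # plus a single opponent reunion in one coercion PC
    for head_id, focal, partner, onset, _ in coercion_plants:
        pc_win, _mc = windows[head_id]
        if pc_win is None:
            continue
        date = pc_win.date
        new_aff(Window(date, onset - 5.0, 600.0), 5.0, focal, partner, (_CS, _TB))
    for head_id, grp, sub in conflict_specs:
        if grp.kind == "coercion" and grp.coercion_opp_contact:
            pc_win, _mc = windows[head_id]
            new_aff(pc_win, 50.0, grp.events[0][1], grp.events[0][0], (_TB,))

    return log.sort()
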