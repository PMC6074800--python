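"""PC extraction, matched-control selection and pair classification."""

import pytest
from hypothesis import given, settings, strategies as st

from pcmckit.pcmc import (
    UNSPECIFIABLE, build_chains, build_pairs, classify_pair, extract_pc,
    first_affiliation_latency, select_mc, victim_proportions,
    reconciliation_test, Window,
)
from pcmckit.stats_core import UndefinedTestError
from tests.conftest import agg, aff


# ---------------------------------------------------------------------------
# restart rule and PC windows
# ---------------------------------------------------------------------------


def test_pc_restarts_after_same_dyad_resumption(toy_setup):
    events = [
        agg(toy_setup, "e1", 0, 1000.0, "a", "b"),          # ends 1030
        agg(toy_setup, "e2", 0, 1130.0, "a", "b"),          # resumes at +100
    ]
    chains = build_chains(events)
    assert len(chains) == 1
    pc = extract_pc(chains[0], toy_setup)
    assert pc.window.start_s == 1160.0                      # after e2 ends
    assert pc.restarted_from == ("e2",)
    assert pc.focal == "b" and pc.opponent == "a"


def test_other_dyad_aggression_does_not_restart(toy_setup):
    events = [
        agg(toy_setup, "e1", 0, 1000.0, "a", "b"),
        agg(toy_setup, "e2", 0, 1100.0, "a", "c"),          # different dyad
    ]
    chains = build_chains(events)
    assert [c[0].event_id for c in chains] == ["e1", "e2"]


def test_resumption_boundary_at_three_minutes(toy_setup):
    # onset exactly 180 s after the PC anchor does not abort
    events = [agg(toy_setup, "e1", 0, 1000.0, "a", "b"),
              agg(toy_setup, "e2", 0, 1210.0, "a", "b")]
    assert len(build_chains(events)) == 2


def test_pc_unavailable_when_recording_ends(toy_setup):
    ev = agg(toy_setup, "e1", 0, 6900.0, "a", "b")          # 300 s left
    pc = extract_pc([ev], toy_setup)
    assert not pc.available


# ---------------------------------------------------------------------------
# matched-control selection
# ---------------------------------------------------------------------------


def test_mc_first_rung_next_day_same_time(toy_setup):
    events = [agg(toy_setup, "e1", 0, 1000.0, "a", "b")]
    pc = extract_pc([events[0]], toy_setup)
    mc = select_mc(pc, events, toy_setup)
    assert (mc.day_offset, mc.clock_offset_min) == (1, 0)
    assert mc.window.date == toy_setup.session_calendar[1].date
    assert mc.window.start_s == pc.window.start_s


def test_mc_shifts_clock_when_conflict_precedes_window(toy_setup):
    events = [
        agg(toy_setup, "e1", 0, 3600.0, "a", "b"),
        # next-day conflict ~10 min before the matched window start
        agg(toy_setup, "e2", 1, 3050.0, "a", "c"),
    ]
    pc = extract_pc([events[0]], toy_setup)
    mc = select_mc(pc, events, toy_setup)
    assert mc.day_offset == 1
    # nearest admissible interval: +1 min clears the 10-min pre-window rule
    assert mc.clock_offset_min == 1
    start = mc.window.start_s
    assert all(not (o < start and e > start - 600.0)
               for o, e in [(3050.0, 3080.0)])


def test_mc_prefers_future_day_then_falls_back(toy_setup):
    # conflict on the last recorded day: only earlier days available
    events = [agg(toy_setup, "e1", 4, 1000.0, "a", "b")]
    pc = extract_pc([events[0]], toy_setup)
    mc = select_mc(pc, events, toy_setup)
    assert mc.day_offset == -1 and mc.clock_offset_min == 0


def test_mc_unavailable_without_nearby_recording(toy_setup):
    setup = toy_setup
    setup.session_calendar[:] = setup.session_calendar[:1]
    events = [agg(setup, "e1", 0, 1000.0, "a", "b")]
    pc = extract_pc([events[0]], setup)
    assert not select_mc(pc, events, setup).available


def test_mc_selection_deterministic(toy_setup):
    events = [agg(toy_setup, "e1", 1, 2000.0, "a", "b"),
              agg(toy_setup, "e2", 2, 1500.0, "b", "c")]
    pc = extract_pc([events[0]], toy_setup)
    first = select_mc(pc, events, toy_setup)
    second = select_mc(pc, events, toy_setup)
    assert (first.window, first.day_offset) == (second.window, second.day_offset)


# ---------------------------------------------------------------------------
# first-affiliation latency coding
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("onset_in_window, expected", [
    (0.0, 1), (30.0, 1), (60.0, 1), (61.0, 2), (120.0, 2), (121.0, 3),
    (599.0, 10), (600.0, 10),
])
def test_latency_interval_boundaries(toy_setup, onset_in_window, expected):
    win = Window(toy_setup.session_calendar[0].date, 1000.0)
    contacts = [aff(toy_setup, "f1", 0, 1000.0 + onset_in_window, "b", "a")]
    assert first_affiliation_latency(contacts, win, "b", "a",
                                     "opponent") == expected


def test_latency_none_and_partner_filters(toy_setup):
    win = Window(toy_setup.session_calendar[0].date, 1000.0)
    contacts = [aff(toy_setup, "f1", 0, 1100.0, "b", "c")]
    assert first_affiliation_latency(contacts, win, "b", "a",
                                     "opponent") is None
    assert first_affiliation_latency(contacts, win, "b", "a",
                                     "third_party") == 2
    assert first_affiliation_latency([], win, "b", "a", "opponent") is None


def test_latency_unspecifiable_on_masked_earliest_contact(toy_setup):
    win = Window(toy_setup.session_calendar[0].date, 1000.0)
    contacts = [
        aff(toy_setup, "f1", 0, 1050.0, "b", "a", visibility_ok=False),
        aff(toy_setup, "f2", 0, 1200.0, "b", "a"),
    ]
    assert first_affiliation_latency(contacts, win, "b", "a",
                                     "opponent") == UNSPECIFIABLE


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("pc, mc, expected", [
    (1, None, "attracted"), (None, 2, "dispersed"), (4, 4, "neutral"),
    (None, None, "neutral"), (2, 5, "attracted"), (7, 3, "dispersed"),
    (UNSPECIFIABLE, 1, "excluded"), (3, UNSPECIFIABLE, "excluded"),
])
def test_classification_definition(pc, mc, expected):
    assert classify_pair(pc, mc) == expected


_latency = st.one_of(st.none(), st.integers(1, 10),
                     st.just(UNSPECIFIABLE))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(_latency, _latency)
def test_classification_total_and_antisymmetric(pc, mc):
    cls = classify_pair(pc, mc)
    specifiable = UNSPECIFIABLE not in (pc, mc)
    assert (cls == "excluded") != specifiable
    swapped = classify_pair(mc, pc)
    mirror = {"attracted": "dispersed", "dispersed": "attracted",
              "neutral": "neutral", "excluded": "excluded"}
    assert swapped == mirror[cls]


# ---------------------------------------------------------------------------
# proportions and the paired test
# ---------------------------------------------------------------------------


class _FakePair:
    def __init__(self, victim, cls):
        self.focal = victim
        self._cls = cls

    def analysable(self, target):
        return self._cls != "excluded"

    def classification(self, target):
        return self._cls


def test_victim_proportions_arithmetic_and_threshold():
    pairs = [_FakePair("v", c) for c in
             ("attracted", "attracted", "dispersed", "neutral")]
    pairs += [_FakePair("w", "attracted"), _FakePair("w", "dispersed")]
    props = victim_proportions(pairs, "opponent", min_received=3)
    v = props[props.victim == "v"].iloc[0]
    assert (v.attracted, v.dispersed, v.neutral) == (0.5, 0.25, 0.25)
    assert not props[props.victim == "w"].included.iloc[0]


def test_reconciliation_test_known_configurations():
    def props_for(diffs):
        pairs = []
        for i, d in enumerate(diffs):
            n_a = round((0.5 + d / 2) * 20)
            pairs += [_FakePair(f"v{i}", "attracted")] * n_a
            pairs += [_FakePair(f"v{i}", "dispersed")] * (20 - n_a)
        return victim_proportions(pairs, "opponent")

    res = reconciliation_test(props_for([0.1, 0.2, 0.3, 0.4, 0.5]))
    assert (res.T, res.p) == (0.0, pytest.approx(1 / 32))
    res = reconciliation_test(props_for([0.1, -0.2, -0.3, 0.4, 0.5]))
    assert (res.T, res.p) == (5.0, pytest.approx(10 / 32))
    res = reconciliation_test(props_for([0.4]))
    assert res.p == pytest.approx(0.5)
    with pytest.raises(UndefinedTestError):
        reconciliation_test(props_for([0.0, 0.0]))


# ---------------------------------------------------------------------------
# whole-log orchestration invariants
# ---------------------------------------------------------------------------


def test_classification_counts_partition_analysable_pairs(mimic_log):
    general, coercion = build_pairs(mimic_log)
    for analysis in (general, coercion):
        for target in ("opponent", "third_party"):
            counts = analysis.counts(target)
            assert sum(counts.values()) == len(analysis.analysable(target))


def test_no_conflict_yields_two_pc_windows(mimic_log):
    general, coercion = build_pairs(mimic_log)
    seen = set()
    for analysis in (general, coercion):
        for p in analysis.pairs:
            assert p.conflict_id not in seen
            seen.add(p.conflict_id)
        for cid, reason in analysis.excluded_conflicts:
            if reason == "resumed":
                assert cid not in seen
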