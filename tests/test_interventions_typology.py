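"""Third-party intervention summaries and the contact typology."""

import pytest

from pcmckit.contact_typology import behaviour_type_table, type_association_test
from pcmckit.ethogram_model import InterventionRecord
from pcmckit.interventions import (
    coercion_summary, intervention_condition_test, tabulate_interventions,
)
from tests.conftest import aff, agg


def test_zero_interventions_summary(toy_setup):
    events = [agg(toy_setup, "e1", 0, 10.0, "a", "b")]
    s = tabulate_interventions(events, toy_setup)
    assert (s.n_intervened, s.n_interventions) == (0, 0)
    assert s.matrix.empty


def test_summary_counts_multiple_interveners_per_conflict(toy_setup):
    iv = lambda who: InterventionRecord(who, "peaceful", "b")
    events = [
        agg(toy_setup, "e1", 0, 10.0, "a", "b", interventions=(iv("c"),)),
        agg(toy_setup, "e2", 0, 700.0, "a", "b", interventions=(iv("c"),)),
        agg(toy_setup, "e3", 0, 1400.0, "a", "b"),
        agg(toy_setup, "e4", 0, 2100.0, "a", "b",
            intervention_undetermined=True),
    ]
    s = tabulate_interventions(events, toy_setup)
    assert s.n_conflicts_considered == 4
    assert (s.n_intervened, s.n_interventions, s.n_undetermined) == (2, 2, 1)
    assert s.proportion_intervened == pytest.approx(0.5)
    assert int(s.matrix.values.sum()) == s.n_interventions
    dropped = tabulate_interventions(events, toy_setup, drop_undetermined=True)
    assert dropped.n_conflicts_considered == 3


def test_summary_order_invariant(toy_setup):
    iv = InterventionRecord("c", "aggressive", "b")
    events = [agg(toy_setup, "e1", 0, 10.0, "a", "b", interventions=(iv,)),
              agg(toy_setup, "e2", 1, 10.0, "b", "a")]
    fwd = tabulate_interventions(events, toy_setup)
    rev = tabulate_interventions(list(reversed(events)), toy_setup)
    assert fwd.n_intervened == rev.n_intervened
    assert fwd.matrix.equals(rev.matrix)


def test_condition_test_equal_rates_or_one(toy_setup):
    toy_setup.session_calendar[0] = type(toy_setup.session_calendar[0])(
        toy_setup.session_calendar[0].date,
        toy_setup.session_calendar[0].start, 7200.0, "outdoor")
    iv = (InterventionRecord("c", "peaceful", "b"),)
    events = []
    for day, cond in ((0, "outdoor"), (1, "indoor")):
        events.append(agg(toy_setup, f"h{day}", day, 10.0, "a", "b",
                          condition=cond, interventions=iv))
        events.append(agg(toy_setup, f"m{day}", day, 900.0, "a", "b",
                          condition=cond))
    pooled, control = intervention_condition_test(events, toy_setup)
    assert pooled.or_cmle == pytest.approx(1.0, abs=1e-6)
    assert control.p == 1.0


def test_coercion_separated_from_general_tabulation(toy_setup):
    coercion = agg(toy_setup, "e1", 0, 10.0, "c", "a",
                   context="sexual_coercion",
                   interventions=(InterventionRecord("b", "aggressive", "a",
                                                     successful=False),))
    counter = agg(toy_setup, "e2", 0, 100.0, "a", "c",
                  context="sexual_coercion")
    female_female = agg(toy_setup, "e3", 0, 900.0, "a", "b",
                        context="sexual_coercion")
    plain = agg(toy_setup, "e4", 0, 1600.0, "a", "b")
    events = [coercion, counter, female_female, plain]
    s = tabulate_interventions(events, toy_setup)
    # male-coercion events drop out; the female-female case stays
    assert s.n_conflicts_considered == 2
    summary = coercion_summary(events, toy_setup)
    assert len(summary) == 1
    assert summary.iloc[0].interveners == "b"
    assert not summary.iloc[0].any_successful


def test_behaviour_table_counts_each_type_once_per_contact(toy_setup):
    pc = [aff(toy_setup, "f1", 0, 10.0, "a", "b",
              behaviour_types=("contact_sitting", "touch_body")),
          aff(toy_setup, "f2", 0, 20.0, "a", "b",
              behaviour_types=("contact_sitting",))]
    mc = [aff(toy_setup, "f3", 1, 10.0, "a", "b", behaviour_types=("play",))]
    tab = behaviour_type_table(pc, mc)
    cs = tab[tab.behaviour == "contact_sitting"].iloc[0]
    assert (cs.pc_n, cs.pc_prop) == (2, 1.0)
    # two-type contacts can push the proportion total over 100%
    assert tab.pc_prop.sum() > 1.0
    assert tab.attrs["n_pc"] == 2 and tab.attrs["n_mc"] == 1


def test_behaviour_table_order_invariant(toy_setup):
    pc = [aff(toy_setup, f"f{i}", 0, 10.0 * i, "a", "b",
              behaviour_types=t)
          for i, t in enumerate([("play",), ("embrace",), ("play",)])]
    tab1 = behaviour_type_table(pc, [])
    tab2 = behaviour_type_table(list(reversed(pc)), [])
    assert tab1.set_index("behaviour").pc_n.equals(
        tab2.set_index("behaviour").pc_n)


def test_type_association_balanced_and_zero_cell(toy_setup):
    pc = [aff(toy_setup, f"p{i}", 0, 10.0 * i, "a", "b",
              behaviour_types=("play",) if i < 3 else ("embrace",))
          for i in range(6)]
    mc = [aff(toy_setup, f"m{i}", 1, 10.0 * i, "a", "b",
              behaviour_types=("play",) if i < 3 else ("embrace",))
          for i in range(6)]
    tab = behaviour_type_table(pc, mc)
    pooled, control = type_association_test(tab, "play", pc, mc)
    assert pooled.or_cmle == pytest.approx(1.0, abs=1e-6)
    only_pc = behaviour_type_table(pc, mc[3:])
    pooled, _ = type_association_test(only_pc, "play")
    assert pooled.unbounded  # behaviour absent from MC entirely
    with pytest.raises(KeyError):
        type_association_test(tab, "grooming")
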