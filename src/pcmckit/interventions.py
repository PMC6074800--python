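"""Third-party intervention tabulation and condition contrasts.

Interventions — attempts by an initially uninvolved individual to cease
an ongoing conflict, peacefully or aggressively — are summarised per
conflict subset.  Male sexual coercion is handled separately: in the
study system every forced copulation provoked at least one (aggressive)
intervention, so its summary is descriptive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .ethogram_model import AggressionEvent, StudySetup
from .pcmc import is_male_coercion
from .stats_core import (
    FisherResult, RxCResult, fisher_exact_2x2, fisher_exact_rxc,
)

__all__ = [
    "InterventionSummary", "tabulate_interventions",
    "intervention_condition_test", "coercion_summary",
]


@dataclass
class InterventionSummary:
    n_conflicts_considered: int
    n_undetermined: int
    n_intervened: int
    n_interventions: int
    mode_counts: dict[str, int]
    success_counts: dict[bool, int]
    matrix: pd.DataFrame  # intervener x victim counts

    @property
    def proportion_intervened(self) -> float:
        return (self.n_intervened / self.n_conflicts_considered
                if self.n_conflicts_considered else float("nan"))


def _check_interveners(conflicts: Sequence[AggressionEvent]) -> None:
    for ev in conflicts:
        for rec in ev.interventions:
            if rec.intervener_id in (ev.aggressor_id, ev.victim_id):
                raise ValueError(
                    f"conflict {ev.event_id}: intervener is a party to the conflict"
                )


def tabulate_interventions(
    conflicts: Sequence[AggressionEvent],
    setup: Optional[StudySetup] = None,
    exclude_male_coercion: bool = True,
    drop_undetermined: bool = False,
) -> InterventionSummary:
    """Summarise third-party interventions over a conflict set.

    The denominator is all considered conflicts, following the study's
    printed arithmetic; conflicts whose intervention status could not be
    determined are counted (and reported) unless ``drop_undetermined``.
    One conflict can carry several interventions by different individuals.
    """
    if exclude_male_coercion:
        if setup is None:
            raise ValueError("setup required to identify male-coercion events")
        conflicts = [e for e in conflicts if not is_male_coercion(e, setup)]
    _check_interveners(conflicts)
    undet = [e for e in conflicts if e.intervention_undetermined]
    considered = [e for e in conflicts if not (drop_undetermined and
                                               e.intervention_undetermined)]
    intervened = [e for e in considered if e.interventions]
    recs = [(ev, r) for ev in intervened for r in ev.interventions]
    interveners = sorted({r.intervener_id for _, r in recs})
    victims = sorted({ev.victim_id for ev, _ in recs})
    matrix = pd.DataFrame(0, index=interveners, columns=victims)
    for ev, r in recs:
        matrix.loc[r.intervener_id, ev.victim_id] += 1
    return InterventionSummary(
        n_conflicts_considered=len(considered),
        n_undetermined=len(undet),
        n_intervened=len(intervened),
        n_interventions=len(recs),
        mode_counts={m: sum(1 for _, r in recs if r.mode == m)
                     for m in ("peaceful", "aggressive")},
        success_counts={s: sum(1 for _, r in recs if r.successful is s)
                        for s in (True, False)},
        matrix=matrix,
    )


def intervention_condition_test(
    conflicts: Sequence[AggressionEvent],
    setup: Optional[StudySetup] = None,
    exclude_male_coercion: bool = True,
) -> tuple[FisherResult, RxCResult]:
    """Did the less spacious indoor condition raise the probability that a
    conflict provoked an intervention?

    Pooled 2x2 (intervened yes/no x indoor/outdoor) counting conflicts as
    units, plus an influence control: intervener identity x condition over
    the individual intervention records.
    """
    if exclude_male_coercion:
        if setup is None:
            raise ValueError("setup required to identify male-coercion events")
        conflicts = [e for e in conflicts if not is_male_coercion(e, setup)]

    def cell(cond: str, hit: bool) -> int:
        return sum(1 for e in conflicts
                   if e.condition == cond and bool(e.interventions) == hit)

    pooled = fisher_exact_2x2(
        [[cell("indoor", True), cell("indoor", False)],
         [cell("outdoor", True), cell("outdoor", False)]]
    )
    recs = [(ev, r) for ev in conflicts for r in ev.interventions]
    who = sorted({r.intervener_id for _, r in recs})
    ctrl = [
        [sum(1 for ev, r in recs
             if r.intervener_id == w and ev.condition == "indoor"),
         sum(1 for ev, r in recs
             if r.intervener_id == w and ev.condition == "outdoor")]
        for w in who
    ]
    control = fisher_exact_rxc(ctrl) if ctrl else RxCResult(p=1.0, method="exact")
    return pooled, control


def coercion_summary(
    conflicts: Sequence[AggressionEvent], setup: StudySetup
) -> pd.DataFrame:
    """Descriptive summary of interventions in male sexual-coercion
    episodes: one row per coercion event initiated by the male, with its
    interveners, their modes and success."""
    rows = []
    for ev in conflicts:
        if not is_male_coercion(ev, setup):
            continue
        if setup.individual(ev.aggressor_id).sex != "male":
            continue  # counter-aggressions within the episode
        rows.append(dict(
            event_id=ev.event_id, victim=ev.victim_id,
            condition=ev.condition,
            n_interventions=len(ev.interventions),
            interveners=";".join(r.intervener_id for r in ev.interventions),
            modes=";".join(r.mode for r in ev.interventions),
            any_successful=any(r.successful for r in ev.interventions),
        ))
    return pd.DataFrame(rows, columns=[
        "event_id", "victim", "condition", "n_interventions",
        "interveners", "modes", "any_successful",
    ])
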