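"""Whole-log orchestration: run every analysis stage and assemble a report.

The pipeline executes the stages in method order — descriptive conflict
catalogue, PC/MC matching and classification, time-rule analysis for both
contact targets, intervention tabulation, and the post-conflict contact
typology — and collects every result in a :class:`PipelineReport` that
can be written out as a set of CSV artefacts plus a human-readable
summary.  Report generation is pure: the same log (and seed, where Monte
Carlo enters) produces an identical report.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .conflict_catalog import (
    aggression_network, aggression_rates, condition_intensity_test,
    mesh_effect_test, segment_conflicts, summarize_contexts,
)
from .contact_typology import (
    behaviour_type_table, gather_window_contacts, type_association_test,
)
from .ethogram_model import EventLog, write_coding_sheet
from .interventions import (
    coercion_summary, intervention_condition_test, tabulate_interventions,
)
from .pcmc import PCMCAnalysis, build_pairs
from .stats_core import UndefinedTestError
from . import time_rule

__all__ = ["PipelineReport", "run_pipeline"]


def _log_digest(log: EventLog) -> str:
    buf = io.StringIO()
    write_coding_sheet(log, buf)
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    log: EventLog
    sequences: list = field(default_factory=list)
    contexts: Optional[pd.DataFrame] = None
    rates: Optional[pd.DataFrame] = None
    rate_test: Optional[object] = None
    intensity_test: Optional[object] = None
    intensity_control: Optional[object] = None
    mesh_test: Optional[object] = None
    network_edges: Optional[pd.DataFrame] = None
    network_totals: Optional[pd.DataFrame] = None
    general: Optional[PCMCAnalysis] = None
    coercion: Optional[PCMCAnalysis] = None
    tests: dict = field(default_factory=dict)
    curves: dict = field(default_factory=dict)
    critical: dict = field(default_factory=dict)
    labels: dict = field(default_factory=dict)
    reconciled_proportion: dict = field(default_factory=dict)
    interventions: Optional[object] = None
    intervention_test: Optional[object] = None
    intervention_control: Optional[object] = None
    coercion_interventions: Optional[pd.DataFrame] = None
    typology: Optional[pd.DataFrame] = None
    typology_tests: dict = field(default_factory=dict)
    notices: list[str] = field(default_factory=list)
    digest: str = ""

    def summary_text(self) -> str:
        out = [f"pcmckit {__version__} pipeline report  (input sha256 {self.digest})", ""]
        n = len(self.log.aggressions)
        out.append(f"aggressive interactions: {n}")
        if self.sequences:
            distinct = sum(1 for s in self.sequences if s.is_distinct)
            out.append(f"  distinct events: {distinct}; in sequences: "
                       f"{sum(s.size for s in self.sequences if not s.is_distinct)}")
        if self.rates is not None:
            med = {c: self.rates[self.rates.condition == c].rate.median()
                   for c in ("indoor", "outdoor")}
            out.append(f"  median rate/h indoor {med['indoor']:.3f} "
                       f"vs outdoor {med['outdoor']:.3f}")
            if self.rate_test is not None:
                t = self.rate_test
                out.append(f"  signed-rank indoor>outdoor: n={t.n_used} "
                           f"T={t.T:g} p={t.p:.4g}")
        if self.general is not None:
            for target in ("opponent", "third_party"):
                c = self.general.counts(target)
                total = sum(c.values())
                out.append(f"{target} PC-MC pairs: {total} "
                           f"(attracted {c['attracted']} / dispersed "
                           f"{c['dispersed']} / neutral {c['neutral']})")
                t = self.tests.get(target)
                if t is not None:
                    out.append(f"  signed-rank attracted>dispersed: "
                               f"n={t.n_used} T={t.T:g} p={t.p:.4g}")
                cw = self.critical.get(target)
                if cw is not None:
                    out.append(f"  critical interval: minute {cw.t_star} "
                               f"(max delta {cw.max_delta:.3f}; "
                               f"max OR at minute {cw.t_max_or})")
                if target in self.reconciled_proportion:
                    lab = self.labels[target]
                    out.append(f"  contacts within critical interval: "
                               f"{int(lab.reconciled.sum())}/{len(lab)} "
                               f"({self.reconciled_proportion[target]:.0%})")
        if self.interventions is not None:
            s = self.interventions
            out.append(f"third-party interventions: {s.n_intervened}/"
                       f"{s.n_conflicts_considered} conflicts "
                       f"({s.proportion_intervened:.0%}), "
                       f"{s.n_interventions} interventions "
                       f"({s.mode_counts['peaceful']} peaceful)")
            if self.intervention_test is not None:
                out.append(f"  indoor vs outdoor: OR="
                           f"{self.intervention_test.or_cmle:.3g} "
                           f"p={self.intervention_test.p:.4g}")
        for notice in self.notices:
            out.append(f"NOTE: {notice}")
        return "\n".join(out) + "\n"

    def write(self, out_dir: str) -> None:
        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        if self.network_edges is not None:
            self.network_edges.to_csv(d / "network.csv", index=False)
        if self.contexts is not None:
            self.contexts.to_csv(d / "contexts.csv")
        if self.rates is not None:
            self.rates.to_csv(d / "rates.csv", index=False)
        if self.general is not None:
            self.general.to_frame().to_csv(d / "pairs.csv", index=False)
        for target, curves in self.curves.items():
            tab = curves.table.copy()
            tests = self.critical[target].interval_tests
            tab["or_cmle"] = [t.or_cmle for t in tests]
            tab["p"] = [t.p for t in tests]
            tab.to_csv(d / f"curves_{target}.csv", index=False)
        for target, labels in self.labels.items():
            labels.to_csv(d / f"labels_{target}.csv", index=False)
        if self.interventions is not None:
            self.interventions.matrix.to_csv(d / "interventions.csv")
        if self.typology is not None:
            self.typology.to_csv(d / "typology.csv", index=False)
        (d / "summary.txt").write_text(self.summary_text())


def run_pipeline(log: EventLog, min_received: int = 3) -> PipelineReport:
    """Execute the complete analysis on one event log."""
    rep = PipelineReport(log=log, digest=_log_digest(log))
    rep.sequences = segment_conflicts(log.aggressions)
    rep.contexts = summarize_contexts(log.aggressions)
    if log.aggressions:
        rates, rate_test = None, None
        try:
            rates_tab, rate_test = aggression_rates(log.aggressions, log.setup)
            rates = rates_tab.table
        except (ValueError, UndefinedTestError) as exc:
            rep.notices.append(f"aggression-rate test unavailable: {exc}")
            try:
                rates = aggression_rates(log.aggressions, log.setup)[0].table
            except Exception:
                rates = None
        rep.rates, rep.rate_test = rates, rate_test
        try:
            rep.intensity_test, rep.intensity_control = \
                condition_intensity_test(log.aggressions)
        except ValueError as exc:
            rep.notices.append(f"intensity contrast unavailable: {exc}")
        try:
            rep.mesh_test = mesh_effect_test(
                log.aggressions, {i.id: i.subgroup for i in log.setup.roster})
        except ValueError as exc:
            rep.notices.append(f"mesh test unavailable: {exc}")
    rep.network_edges, rep.network_totals = aggression_network(log.aggressions)

    rep.general, rep.coercion = build_pairs(log)
    for target in ("opponent", "third_party"):
        pairs = rep.general.analysable(target)
        if not pairs:
            rep.notices.append(f"no analysable {target} pairs")
            continue
        try:
            rep.tests[target] = rep.general.test(target, min_received)
        except UndefinedTestError as exc:
            rep.notices.append(f"{target} signed-rank test undefined: {exc}")
        curves = time_rule.cumulative_curves(rep.general.pairs, target)
        tests = [time_rule.interval_association(rep.general.pairs, target, t)
                 for t in range(1, time_rule.N_INTERVALS + 1)]
        cw = time_rule.critical_interval(curves, tests)
        labels, prop = time_rule.label_reconciled(
            rep.general.pairs, cw.t_star, target)
        rep.curves[target] = curves
        rep.critical[target] = cw
        rep.labels[target] = labels
        rep.reconciled_proportion[target] = prop

    rep.interventions = tabulate_interventions(log.aggressions, log.setup)
    try:
        rep.intervention_test, rep.intervention_control = \
            intervention_condition_test(log.aggressions, log.setup)
    except ValueError as exc:
        rep.notices.append(f"intervention contrast unavailable: {exc}")
    rep.coercion_interventions = coercion_summary(log.aggressions, log.setup)

    if rep.general.pairs:
        pc_c, mc_c = gather_window_contacts(rep.general.pairs, log)
        if pc_c or mc_c:
            rep.typology = behaviour_type_table(pc_c, mc_c)
            for beh in ("contact_sitting",):
                if beh in set(rep.typology.behaviour):
                    rep.typology_tests[beh] = type_association_test(
                        rep.typology, beh, pc_c, mc_c)
    return rep
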