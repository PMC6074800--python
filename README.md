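# pcmckit

Post-conflict / matched-control (PC/MC) and time-rule analysis of
behavioural event logs, built for quantitative ethologists studying
conflict resolution — reconciliation, consolation-like third-party
affiliation, and third-party intervention — in small, continuously
observed animal groups (the motivating system is a zoo-housed group of
six Sumatran orangutans observed across two housing conditions).

## What it computes

Given a coding sheet of aggressive interactions and affiliative contacts:

- **PC/MC method.** Every conflict opens a 10-min post-conflict window
  (PC) on the victim, re-anchored if the opponents resume fighting within
  3 min.  Each PC is paired with a matched-control window (MC) on the
  nearest recorded day at the same clock time (±60 min, ±7 days, no
  conflict in the preceding 10 min).  The victim's first affiliative
  contact with the former opponent (and, separately, with any uninvolved
  third party) is coded into 1-min intervals; a PC-MC pair is
  *attracted* if the contact came earlier in PC (or only in PC),
  *dispersed* if earlier in MC, *neutral* otherwise.  A one-tailed exact
  Wilcoxon signed-rank test on per-victim attracted-vs-dispersed
  proportions (victims with ≥3 analysable pairs) demonstrates
  reconciliation / third-party affiliation.
- **Time-rule method.** Cumulative first-contact distributions over the
  ten intervals; Δ(t) = cumulative PC − MC proportion; interval-wise
  Fisher tests with conditional-MLE odds ratios; the critical interval
  t\* = argmax Δ(t) (the max-OR interval reported alongside) gives the
  operational definition: a conflict is *reconciled* iff its PC first
  contact falls within t\*.
- **Descriptive catalogue.** 4-min conflict sequences, context ×
  intensity tables, per-individual hourly aggression rates by housing
  condition (exact signed-rank contrast), the directed weighted
  aggression network, mesh/separation contrasts.
- **Interventions & typology.** Third-party intervention summaries with
  condition contrasts and influence controls; behaviour-type composition
  of post-conflict vs control contacts (contact sitting, play, …).
- **Exact statistics.** All inference uses in-house exact kernels:
  signed-rank p by full 2^n enumeration with mid-ranks, Fisher 2×2
  (probability-ordering two-sided rule) with the conditional-MLE odds
  ratio, exact r×2 independence tests (Monte-Carlo above an enumeration
  limit), two-sample Kolmogorov–Smirnov, Cohen's κ.
- **Synthetic data.** A seeded generator emulating the study design
  (74.35 h outdoor / 83.15 h indoor, hierarchy-skewed per-dyad aggression
  Poisson processes, affiliation point processes whose hazard is
  multiplied by α for the opponent dyad in a post-conflict window), plus
  a deterministic study-mimic log reproducing the published totals.

## Worked example

```sh
pcmckit simulate --study-mimic --out-dir data
pcmckit run data/events.csv --setup data/setup.yaml --out-dir out
```

prints (and writes to `out/summary.txt` alongside the CSV artefacts):

```
aggressive interactions: 114
  distinct events: 85; in sequences: 29
  median rate/h indoor 0.144 vs outdoor 0.020
  signed-rank indoor>outdoor: n=5 T=0 p=0.03125
opponent PC-MC pairs: 70 (attracted 31 / dispersed 16 / neutral 23)
  signed-rank attracted>dispersed: n=5 T=0 p=0.03125
  critical interval: minute 2 (max delta 0.243; max OR at minute 1)
  contacts within critical interval: 29/70 (41%)
third_party PC-MC pairs: 72 (attracted 29 / dispersed 26 / neutral 17)
  signed-rank attracted>dispersed: n=5 T=5 p=0.3125
  ...
third-party interventions: 22/93 conflicts (24%), 25 interventions (17 peaceful)
  indoor vs outdoor: OR=4.31 p=0.02143
```

Reading: aggression was ~7× more frequent per hour indoors; of the 70
analysable opponent pairs, attracted pairs exceeded dispersed pairs for
all five testable victims (the most extreme outcome of the exact n = 5
test, p = 1/32), so reconciliation occurred; the cumulative PC-MC gap
peaks at minute 2, and 41 % of conflicts were reconciled under that
operational window.  The third-party test (T = 5, p = 0.313) shows no
group-level post-conflict third-party affiliation.

To see the pipeline's detection behaviour on fresh synthetic data:

```sh
pcmckit recover --alphas 1,3,6,10 --reps 60 --seed 7
```

which reports the reconciliation test's rejection rate rising from the
exact null level (~1/32) at α = 1 to ~0.9 at strong attraction.

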