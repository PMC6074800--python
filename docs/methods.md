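# Methods

## The observational design the package models

The analyses assume a small group (here six individuals) under
continuous video observation in daily sessions, across two housing
conditions with known total observation time (defaults: 74.35 h outdoor,
83.15 h indoor, thirty sessions starting 09:00).  Two event classes are
coded from the footage: aggressive interactions (aggressor, victim,
intensity low/medium/high, context, third-party interventions) and
affiliative contacts (dyad, one or two behaviour types, initiator,
visibility).  Times are seconds from session start; all window
arithmetic is in seconds against the session calendar.

## PC/MC matching

A conflict's post-conflict window (PC) is the 600 s following its end,
focused on the victim.  If an aggression between the *same unordered
dyad* begins within the first 180 s, the PC is abandoned and re-anchored
after that aggression ends, recursively; the consumed resumptions never
open windows of their own, so one resumption chain yields exactly one
PC-MC pair (attributed to the chain's first conflict) and the earlier
members are recorded as excluded ("resumed").  Aggression between other
individuals does not abort a PC.  A PC is unavailable when fewer than
600 s of recording remain.

The matched control (MC) is a 600 s window at the same clock time as the
PC onset, on another recorded day.  Admissible candidates lie within ±7
days and ±60 whole minutes, fall entirely inside a session, and have no
conflict overlapping the 600 s before the window.  Selection is the
deterministic total order (|day offset|, |clock offset|, earlier clock
time, future day before past); identical inputs always give identical
matches.  A conflict beginning *inside* a selected MC window does not
invalidate it (only the preceding 10 min are constrained); this is a
deliberate reading of an under-specified rule.

First-contact latencies use the interval convention: interval k covers
(60·(k−1), 60·k] seconds, and a contact at exactly the window onset
belongs to interval 1.  If the earliest qualifying contact could not be
coded (visibility), the latency is *unspecifiable* and the pair is
excluded for that target (opponent and third-party targets are excluded
independently).  Classification: attracted if the PC contact is earlier
(or PC-only), dispersed if the MC contact is earlier (or MC-only),
neutral if same interval or no contact in either window.  Neutral pairs
enter per-victim proportions but not the attracted-vs-dispersed test.

Victims enter the paired test with at least three analysable pairs for
the target (the minimum-three-aggressions inclusion rule, expressed on
pairs since only analysable pairs carry information).

Conflicts in the context of male sexual coercion — coercion events
involving the adult male, including the victim's counter-aggressions
within the episode — run through identical machinery but form a separate
pair set, never pooled with the general analysis.  Female–female
coercion stays in the general set.

## Time rule

Cumulative first-contact curves use *all* analysable pairs as the
denominator (contact-free pairs count in the denominator only), so
Δ(t) = PC−MC cumulative proportion is directly comparable with the
reconciled share.  Per-interval 2×2 Fisher tests ([contact by t yes/no]
× [PC/MC]) supply odds ratios.  The critical interval is the earliest
maximiser of Δ(t); the maximum-OR interval is reported alongside because
the two criteria can disagree (on the study-mimic data the OR peaks at
minute 1 while Δ peaks at minute 2, and Δ decides).  The KS comparison
of latency distributions uses contact-bearing pairs only — it is a test
on latencies, not on contact prevalence — and its p-value is flagged
approximate under the heavy ties that 1-min binning produces.

## Exact statistics

All kernels are exact, small-sample implementations; scipy and sklearn
serve only as independent cross-checks in the tests.

- **Signed-rank:** zeros dropped, absolute differences mid-ranked, T =
  rank sum opposing the alternative; the tail probability comes from the
  full distribution of all 2^n sign assignments conditioned on the
  observed (possibly tied) rank vector, computed as an integer
  convolution over doubled ranks.  No normal approximation at any n.
- **Fisher 2×2:** two-sided p by the probability-ordering rule with a
  1+1e-7 relative tolerance (matching the standard exact-test
  implementations); odds ratio as the conditional MLE solving
  E_ψ[X] = x by bisection on log ψ, with 0/∞ flagged at the support
  boundary.
- **Fisher r×2:** exact enumeration of all margin-preserving tables when
  their number is ≤ 10^6 (default), otherwise Monte-Carlo from the
  multivariate hypergeometric null (default 10^5 draws, explicit seed)
  with a reported standard error.
- **KS:** D evaluated at all pooled points; exact p by lattice-path
  counting for tie-free samples with n·m ≤ 10^4, else the asymptotic
  Kolmogorov series.
- **Cohen's κ:** the standard chance-corrected agreement on the raters'
  cross-tabulation (perfect agreement returns κ = 1 even at p_e = 1).

## Synthetic data generator

`SimulationConfig` encodes the study conditions: the six-member roster
with subgroups and kinship, the two-block calendar summing to
74.35/83.15 h, per-dyad directed aggression rates skewed down the
dominance hierarchy (defaults chosen so expected totals match the
observed ~114 conflicts, with an indoor multiplier of 3), context
probabilities as observed (0.43 spontaneous, 0.23 sexual coercion, 0.15
weaning, …) restricted by eligibility (coercion: male → adult female;
weaning: mother → offspring), and per-context intensity distributions.

Affiliations are per-dyad homogeneous Poisson processes (default 2.0
contacts/h per dyad, a rate at which roughly a quarter of 10-min control
windows contain a contact, matching the scale of the observed control
data).  After each conflict, for `window_s` = 120 s, the opponent dyad's
hazard is multiplied by `attraction_alpha` and every victim–bystander
dyad's by `attraction_beta`; the boost is realised by superposing an
extra Poisson stream at (multiplier − 1) × baseline, which is exact for
piecewise-constant hazards.  α = β = 1 is therefore an exact null.  The
default α = 6, β = 2 represents a clear reconciliation effect with a
weaker bystander effect.  Matched controls arise naturally because
sessions repeat daily at the same clock time.  All draws flow through
one seeded generator; a fixed seed yields a byte-identical coding sheet.

What the generator does *not* emulate: dominance dynamics or contest
escalation, spatial structure (the indoor mesh is only a dyad flag),
context-dependent affiliation repertoires, and observer effects other
than a uniform 3 % visibility-loss probability.  Passing recovery tests
therefore show that the pipeline detects hazard-multiplication
signatures at realistic event counts — not that real post-conflict
behaviour follows this generative model.

The recovery experiment runs the full generator → matching →
classification → exact-test chain.  At α = 1 the rejection rate equals
the attainable level of the exact one-tailed test (1/32 when five
victims are testable, the typical case under the defaults).  Power was
calibrated on pilot grids: ~0.85 at α = 10 and ~0.90 at α = 12 with the
default baseline; the acceptance test uses α = 12.  Problem sizes in the
test suite (200 replicates for the null level, 150 per power point) keep
the Monte-Carlo standard error near 0.01–0.03.

## The study-mimic log

`study_mimic_log()` is a deterministic, fully synthetic event log that
reproduces the published totals end-to-end through the real pipeline
(114 conflicts; 70 opponent pairs 31/16/23; 72 third-party pairs
29/26/17; Δ(2) = 0.243; 29/70 reconciled; 22/93 intervened; rate medians
0.144/0.020; the Table-2-shaped contact typology).  Events sit on a
30-min slot grid with alternating-day parity so PC windows, MC windows
and planted contacts never interfere; the builder computes windows with
the pipeline's own matching code before planting contacts, so the
reproduction is not circular in the latencies it asserts.  Two published
values are *not* matched because they depend on the unpublished
dyad-by-condition composition of the raw data: the mesh-effect p-value
and the exact high-intensity odds ratio (the mimic yields the same
direction and significance, OR 4.12, with an influence-control p of
1.0); similarly the intervention odds ratio is 4.31, the closest value
any 2×2 with the published margins (22 intervened of 93) can attain to
the printed 4.24.

## Numerical conventions and degenerate inputs

Latency interval boundaries are closed on the right with a 1e-9 s guard;
tail probabilities are compared with a 1+1e-7 relative tolerance in the
probability-ordering rules; signed-rank input of all zeros raises an
undefined-test error rather than returning a value; Fisher tables with a
degenerate margin return a flagged result with p = 1 and no odds ratio;
empty conflict logs produce descriptive reports with explicit
"no analysable pairs" notices rather than failures.  Printed p-values in
the acceptance script are rounded half-up to three decimals.

## Known limitations

- The MC search considers whole-minute clock offsets only; sub-minute
  matching is not attempted (the latency resolution is 1 min anyway).
- The r×2 Monte-Carlo fallback reports a standard error but no
  confidence-interval-aware decision; callers needing guarantees should
  raise `exact_limit`.
- Conciliatory tendency (CCT) is intentionally not computed; the
  motivating data could not support it and the quantity is easy to
  derive externally from the pairs table if a dataset allows it.
- The KS p-value under 1-min binning is approximate by construction;
  treat it as descriptive, as the flag indicates.
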