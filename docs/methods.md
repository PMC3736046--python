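# Methods

## Data model

One animal is a record `(subject_id, group, entry_age, event_age, event)`
with ages in months; `event = True` marks an observed death, `False` a
right-censored exit. A cohort is all records of one group with a single
shared entry age. Every age is kept in months end to end — no unit
conversion exists anywhere in the package, which removes a whole class of
silent errors. Animals removed before the observation window (e.g.
procedure-related deaths at treatment time) are simply absent from the
table; censoring support is generality in the data model, not a modelling
claim.

## Kaplan–Meier estimation

Per group the product-limit estimate is computed (via `lifelines`) and
expressed in percent, anchored at 100% at the entry age. The curve is
stored as the distinct death ages with their *post-drop* survival values;
evaluation is right-continuous (the drop happens at the death age). With no
censoring this is identical to brute-force fraction-alive counting, which
the tests assert exactly; with censoring the risk set shrinks without a
drop. Exact recorded ages define step locations; nothing is binned.

## The Gompertz survival law

`F(t) = 100·exp(−P1·exp(P2·t − P3))`, internally on the [0, 1] scale and
converted to percent only at the interface. `F` never reaches 100 at finite
age for valid parameters; the 100% anchor of the empirical curves is a
normalization of the data, not a constraint on the model. The 50%-crossing
is the closed form `t½ = (P3 + ln(ln 2/P1))/P2`; it is the exact analytic
inverse, and increasing `P3` by δ moves `t½` by exactly δ/P2. For extreme
ages the inner exponential is allowed to overflow to `inf`, which gives
survival exactly 0 — the correct limit — rather than an error.

`t½` is used as the summary "mean lifespan" of a fitted curve. For a steep
late-life mortality law median and mean nearly coincide, and the median has
the closed form; the package deliberately reports the 50%-crossing, not a
distributional mean.

## Sequential constrained fitting

The law depends on `(P1, P3)` only through `ln P1 − P3`, so a free
three-parameter fit of one curve lies on a ridge: `P2` and the half-life
are identifiable, `P1` and `P3` individually are not. The staged procedure
resolves this by borrowing strength across groups:

1. **Stage 1** — free fit of `(P1, P2, P3)` per group.
2. **Stage 2** — the first parameter in the fixing order is replaced by its
   unweighted arithmetic mean across groups and held fixed; the remaining
   two are refit per group.
3. **Stage 3** — the second parameter is averaged and fixed; the last one
   is refit per group.

The canonical order is `(P1, P3, P2)`: the groups end up sharing scale and
offset, and the rate of aging `P2` alone distinguishes them. An `auto` mode
derives the order from a sensitivity score — the cross-group relative
spread `|max − min| / mean(|values|)` of each stage-1 parameter, ascending,
with ties broken in the fixed order `(P1, P3, P2)`. The spread of stage-1
`P1` and `P3` is partly an artifact of the ridge, which is one more reason
the canonical order is the default. Group-size weighting of the averages is
available behind a flag but off by default (plain means match the two-group
design).

### Numerical choices

- Fit target: the post-drop step value at each distinct death age,
  unweighted — the convention under which a single death in a cohort of one
  maps to 0% survival.
- Engine: `scipy.optimize.least_squares` (trust-region reflective) with box
  bounds `P1 ∈ (1e-12, 1e6)`, `P2 ∈ (1e-6, 100)`, `P3` unbounded. `P1` and
  `P2` are optimized on the log scale (their bounds span many decades; the
  bounds are mapped through the log, so the constraint set is unchanged).
- Initialization: `P2 = 1` per month, `P3 = P2·t_last`, and `P1` chosen so
  the initial 50%-crossing sits at the median death age. Three seeded,
  jittered restarts guard against local minima; the jitter stream is fixed,
  so refitting identical data is bit-reproducible.
- Constrained stages re-anchor their starting point so the initial curve
  crosses 50% at the median death age. Carrying a previous stage's
  parameters verbatim past newly fixed values can start the optimizer on a
  flat under/overflow plateau (predicted survival 0 everywhere, zero
  gradient); the re-anchoring makes every stage start informative.
- Convergence: relative cost tolerance 1e-10; exhausting the evaluation
  budget without convergence is an error carrying the final residual, never
  a silent result.
- Goodness of fit is the per-group Pearson correlation between observed and
  predicted step values; it is undefined (an error) for fewer than two
  points or constant values.
- Each stage only adds constraints, so the per-group squared residual can
  only grow from stage 1 to stage 3; the tests assert this up to 1e-9.

## Endpoint statistics

`residual = t½ − start_age` per group; `gain = residual_treated −
residual_control`; `% increase (residual) = 100·gain/residual_control`;
`% increase (overall) = 100·gain/t½_control`. The residual percentage is
the figure that reflects the treatment, since the overall ratio dilutes the
effect with the untreated months. All stored values are unrounded; display
formatting rounds months to one decimal and percentages to integers.

Uncertainty: a nonparametric case-resampling bootstrap, stratified by
group, reruns the entire pipeline per replicate and reports percentile 95%
intervals. This is the smallest-assumption option for cohorts of n ≤ 10.
Replicates whose resample cannot be fit (fewer than three distinct death
ages, optimizer failure) are dropped and counted; more than 50% failures is
an error. With such small groups percentile intervals are approximate; the
test suite checks coverage of the design gain only in a scaled-down outer
study (10 outer replicates, B = 100) with a generous threshold, which
demonstrates the machinery, not finite-sample exactness.

## Synthetic cohorts

The generator emulates the study situation: all animals alive at the start
age, death ages drawn from a Gompertz law conditioned on survival to that
age by the exact inverse transform
`t = [P3 + ln(exp(P2·t0 − P3) − ln u / P1)]/P2`, `u ~ U(0,1)`. The default
design is two arms — 9 control and 8 treated animals entering at
21.5 months — with target half-lives 25.1 and 26.5 months. When a group is
given by a target half-life, the law defaults to `P2 = 1.5`/month and
`P3 = P2·t½` (hence `P1 = ln 2`): a steep, mouse-like late-life mortality
at this age scale. One global seed feeds deterministic per-group substreams
(spawn-keyed by group index), so extending a design never perturbs existing
groups. An optional grid-rounding flag mimics coarse observation schedules
and clamps rounded ages to stay past the entry age; it is off by default.

What the generator does *not* emulate: transplantation-related attrition
(excluded animals never enter the table), heterogeneity of frailty within a
group, measurement error in ages, and censoring (all synthetic deaths are
observed). Passing tests on synthetic data therefore show that the
estimator chain is correct under its own model, not that real cohorts
follow a Gompertz law.

## Problem sizes in the tests and acceptance script

Parameter-recovery checks run at n = 500 per group over 50 seeds (the gain
is recovered within ±0.3 months in well over 90% of seeds), the sampler
check at 50,000 draws, the Kaplan–Meier cross-check on 200 random cohorts,
and the closed-form half-life sweep on 1,000 random triples. These sizes
give stable Monte-Carlo margins while keeping a full run in the order of
seconds to minutes.

## Known limitations

- The staged fit assumes the groups genuinely share the fixed parameters;
  if the true laws differ in `P1` or `P3`, the shared values are a
  compromise and per-group `t½` absorbs the difference only approximately.
- With 8–9 animals the half-life estimates are dominated by sampling noise;
  the bootstrap intervals make that visible but cannot remove it.
- No likelihood-based fitting of raw event times, no alternative mortality
  laws (Weibull, logistic, Gompertz–Makeham), no hypothesis tests, and no
  maximal-lifespan (top-decile) statistic — the last is undefined for
  groups this small.
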