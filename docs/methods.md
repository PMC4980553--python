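# Methods

This note documents the analysis pipeline implemented in `emaval`: what is
being estimated, the assumptions behind each stage, what the synthetic
cohort generator does and does not emulate, and the numerical and design
choices made where the method description left room.

## Study structure being analysed

Each participant contributes up to three data streams over a short
monitoring period (default four days):

* **Momentary reports** — brief phone surveys answered on a random,
  interval-contingent schedule: two prompts in each of four daily blocks
  (09–12, 12–15, 15–19, 19–22), eight per day, of which the last is a
  retrospective prompt covering the previous three hours. A report records
  endorsed behaviours, the food groups being eaten (six-group coding) and a
  four-level activity intensity ("strenuous" is treated as a synonym of
  "vigorous" throughout).
* **24-hour dietary recall** — time-stamped eating instances coded to the
  same six food groups, with a day-level energy total, for up to three
  recall days per participant.
* **Accelerometry** — counts summed per 60-second epoch, classified by the
  Freedson cut points: sedentary <100 CPM, light 100–1951, moderate
  1952–5724, vigorous ≥5725.

All timestamps are naive local time at minute resolution; all instruments
are assumed to share the participant's clock, and days are local calendar
days (prompts live between 09:00 and 22:30, so no cross-midnight handling
is needed).

## Exclusion filters

* **Diet arm:** a participant-day enters the analysis only with (1) at
  least one real-time momentary report endorsing a food group and (2) a
  recall day with energy in the **closed** interval [500, 5000] kcal. The
  closed bounds mean a day at exactly 500 kcal is retained; both limits are
  configurable (`FilterThresholds`).
* **Activity arm:** a prompt-occasion is excluded when either 30-minute
  flank around the report is entirely zero counts, when the flanks have no
  epoch coverage at all, or when the day has under 5 hours of wear.
  "Either flank entirely zero" was chosen over "both flanks zero" because
  a fully silent half-hour adjacent to a report indicates the device was
  not worn at the moment that matters; the wording of the source protocol
  admits both readings.
* **Wear time** uses the standard consecutive-zero convention: an epoch is
  non-wear when it sits inside a run of ≥60 consecutive zero-count epochs.
  No wear algorithm was prescribed with the 5-hour rule; the 60-minute
  zero-run is the common epoch-level default and is configurable.

Every filter returns both the kept set and an exclusion ledger with one
reason per excluded unit; the two always partition the input, and the
filters are idempotent and order-independent (property-tested).

## Diet-arm estimands

**Day-level match rate.** For food group g, with m_d momentary endorsements
and r_d recall instances on day d, the rate is
`100 · Σ min(m_d, r_d) / Σ m_d`. A group never endorsed has an undefined
(reported as missing, never zero) rate. Matching is count-based, not
time-based, at this level.

**Window matching.** For half-width w ∈ {6, 12, …, 480} minutes, an
endorsement at time t matches when ≥1 same-group recall instance of the
same participant lies in the **closed** interval [t−w, t+w]; matching is
presence-based (one nearby instance suffices; instances are not consumed by
one-to-one assignment). The window is interpreted as "on either side", so
w = 480 spans 16 hours. The PPV curve is non-decreasing in w by
construction — the implementation computes each endorsement's minimal
|offset| once, which is also how the property is assertable on any input.

**Sensitivity/specificity vs w.** The occasion set is *all* completed
real-time prompts (eating or not): for each group, test = "endorsed in this
report", reference = "same-group recall instance within ±w". Only this
choice yields a full 2×2 at every w; restricting the negatives pool to
eating prompts is available as a switch. A consequence worth knowing (it is
exercised in a test): when recall times are noisy copies of reported eating
times, widening w converts non-endorsed prompts into reference-positives
faster than it adds true positives, so sensitivity *falls* and specificity
*rises* with w. Published descriptions of this trade-off disagree between
sections of the source material; the implementation follows the direction
its own arithmetic produces, which matches the results-section account.

**Subgroup chi-squares** classify every momentary endorsement as
matched/unmatched at the day level (matched = the min-count numerator) and
test the resulting 2×2 against a binary participant attribute with the
uncorrected chi-square; results with any expected cell < 1 are flagged
unreliable rather than suppressed.

**Mixed logistic model.** One occasion per kept participant-day and group:
logit P(momentary endorsement) = β₀ + β₁·(recall-day endorsement) + u_i,
u_i ~ N(0, σ²) per participant; OR = exp(β₁) with Wald 95% CI.

## Activity-arm estimands

**Derived intensity.** The mean CPM over the half-open window [t−5 min, t)
of epoch starts — half-open so the epoch containing the report itself is
excluded — classified by the cut points. Cut-point boundaries go to the
higher band (100 → light, 1952 → moderate, 5725 → vigorous). Occasions with
no epoch in the 5-minute window are dropped with a logged reason.

**Agreement suite.** From the 4×4 reported (rows) × derived (columns)
table, per level L: match rate = diag/row total; sensitivity =
diag/column total and specificity = TN/(TN+FP) with **positives defined by
the derived level** (column-conditioned); LR+ = sens/(1−spec) (undefined at
specificity 1); LR− = (1−sens)/spec (undefined at specificity 0). All
proportions are kept at full precision internally; rounding to the
reporting conventions (match rates one decimal, sens/spec integer percent,
ratios two decimals) happens only at the output layer.

**Mixed OR per level.** Outcome = (derived == L), predictor =
(reported == L), random participant intercepts. The OR is declared
undefined when fewer than two participants contribute to the L×L diagonal
cell — with a single participant the between-person odds are not
estimable in any meaningful sense.

**Distribution comparisons.** All six pairwise two-sample
Kolmogorov–Smirnov tests on the derived 5-minute means grouped by reported
level (asymptotic p-values); pairs with under two observations on either
side are skipped with a notice, but all six rows are always reported.

**Log-count model.** ln(mean CPM + 1) ~ reported level (reference:
sedentary) with random participant intercepts, fitted by maximum
likelihood (not REML) via `statsmodels.MixedLM`; all pairwise contrasts get
Wald 95% intervals from the fixed-effect covariance. The natural log with a
+1 offset handles the residual possibility of a zero 5-minute mean (the
all-zero-flank filter removes most but not all zeros). Each contrast Δ is
back-transformed to a raw-count difference as exp(β₀+Δ) − exp(β₀), i.e.
relative to the model's sedentary mean. When the random-intercept variance
is estimated at the singular boundary the model degenerates to ordinary
least squares, which is then the reported fit (flagged in the log).

**Within-person audit.** Per-participant mean derived counts by reported
level, with an explicit count of ordering inversions (participants whose
average counts are lower at a higher reported level) — population-level
monotonicity does not imply within-person monotonicity, and the audit makes
the paradox visible rather than averaging it away.

## The random-intercept logistic fit

No installed Python library offers a frequentist mixed logit, so the
package implements one: the marginal likelihood integrates the random
intercept by 25-point Gauss–Hermite quadrature, the variance is
parameterised as log σ (bounded in [−10, 5]) and maximised jointly with the
fixed effects by L-BFGS-B from a pooled-logit start; Wald intervals come
from the numerically differentiated observed information. `fit(sigma=0)`
collapses exactly to ordinary logistic regression. Fits with |log-odds|
beyond 10 are flagged as separated and report NA estimates instead of
astronomically inflated ones; non-convergence and singular information are
likewise flagged, never raised. The implementation is cross-checked in the
test suite against `lme4::glmer` with 25-point adaptive quadrature
(agreement to ~1e-3 on a 400-observation fixture).

## Synthetic cohort generator

The generator's defaults are the study conditions the analyses assume:
41 participants × 4 days; eight prompts/day on the random block schedule
with a uniform response latency on [−5, +30] minutes around the SMS;
per-prompt response probability 0.55 (matching the heavy non-response
visible in the source counts); true eating occasions as a Poisson process
(3.7/day, the observed recall-instance density) with a six-group
multinomial; recall days per participant distributed (0.41, 0.40, 0.19)
over 1–3 days; recall omission probability 0.2 and clock-time displacement
SD 45 minutes; 5% of recall days implausible (mostly <500 kcal); a
per-minute true intensity track in 30-minute bouts with marginal level
probabilities (0.54, 0.41, 0.04, 0.01); a row-stochastic misreporting
matrix P(reported | true) derived from the observed agreement pattern
(strong sedentary agreement, heavy sedentary-ward misreporting above it);
and per-level lognormal epoch counts truncated to the level's cut-point
band with a 5% spill-over mass drawn unconstrained. Non-spill draws are
clipped to the integer band after rounding, so a zero-spill configuration
classifies back perfectly. Seven hours of non-wear (all-zero epochs) start
each day.

Eating endorsement follows a traceable rule: each true occasion is credited
to at most one completed real-time prompt (the earliest completed within 30
minutes after the occasion), and a prompt endorses the union of its
credited occasions' groups. This guarantees the conservation and zero-noise
round-trip invariants: momentary day counts never exceed true counts, so a
noise-free bundle yields 100% day-level match for every group present.
`zero_noise_config()` switches off every noise source at once and
additionally makes each participant-day a single constant intensity level,
so every 5-minute pre-prompt window is homogeneous and the cross-tab is
exactly diagonal.

**What the generator does not emulate:** real diurnal activity rhythms and
bout structure (intensity bouts are i.i.d. blocks), autocorrelated
accelerometer noise, informative non-response (response is independent of
behaviour), within-day appetite structure, device non-wear other than the
fixed morning block, and any dependence of misreporting on context. Passing
tests therefore demonstrate that the *statistical machinery* is correct and
recovers known generating parameters under the study's design — not that
the instrument itself is valid, and not that the pipeline is robust to
every failure mode of real field data.

## Determinism and problem sizes

All randomness flows from explicit seeds through `numpy.random.Generator`;
prompt schedules use per-(participant, day) derived streams so they are
reproducible regardless of generation order, and an identical config + seed
produces byte-identical written bundles and report summaries. The
simulation-based checks in the test suite use deliberately small designs —
cohorts of 4–8 participants for invariant sweeps, 50-replicate recovery
studies at 120×12 (logistic OR) and 41×17 (log-count contrasts) — sizes at
which the recovery tolerances (±20% on a median OR, ±0.3 on log-scale
contrasts) are comfortably attributable to the estimator rather than to
Monte Carlo noise.

## Known limitations

* The day-level universe for the diet filter is the union of prompt-days
  and recall-days; participant-level exclusion tallies can be derived from
  the ledger but are not a separate code path.
* The mixed logit fits a single random intercept; random slopes and
  additional covariates (the subgroup attributes, say) are out of scope.
* KS p-values are asymptotic and the derived 5-minute means are discrete at
  low counts; ties are handled as in `scipy.stats.ks_2samp`.
* The retrospective prompt is generated and flagged but excluded from both
  arms by default; including it (`include_retrospective=True`) changes the
  momentary denominator in ways the day-level rule was not designed for.
* No native device formats are parsed (counts arrive as delimited text),
  and no energy-expenditure regression or bout detection is implemented —
  the cut points are applied to epoch counts, nothing more.
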