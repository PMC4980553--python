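# emaval

Validation analysis for **mobile ecological momentary assessment (mEMA)** of
eating and physical activity: does a brief in-the-moment phone survey capture
the same behaviour as the heavier reference instruments — a 24-hour dietary
recall and a hip-worn accelerometer?

`emaval` is aimed at behavioural and nutrition epidemiologists who run (or
review) criterion-validity studies of momentary self-report tools. It
implements the full comparison pipeline as tested, reusable code: the
exclusion filters, the bespoke match-rate definitions, window-based event
matching, level-conditioned diagnostic agreement statistics, and the mixed
models that respect repeated observations within participants. A synthetic
cohort generator with known ground truth makes every stage testable without
access to participant data.

## The statistics at the core

**Diet arm.** Momentary reports endorse food groups (sweets; salty snacks;
fruits/vegetables; entrées; breads/grains; other); the recall yields
time-stamped eating instances coded to the same groups.

* *Day-level match rate*, per food group g:

  match(g) = Σ_days min(m_d, r_d) / Σ_days m_d × 100,

  where m_d and r_d are the day's momentary and recall counts of g. Four
  momentary fruit/vegetable reports against three recall instances score 3
  of 4 (75%); three against four score 3 of 3 (100%).
* *Window match rate (PPV)*: the fraction of momentary endorsements with a
  same-group recall instance within ±w minutes of the report, for w from 6
  minutes to 8 hours in 6-minute steps — non-decreasing in w by
  construction.
* *Sensitivity/specificity vs w* over all completed real-time prompts, with
  the windowed recall as reference, plus chi-square subgroup tests and a
  random-intercept logistic model (momentary endorsement ~ recall-day
  endorsement) per group.

**Activity arm.** Each analysed prompt pairs a reported intensity
(sedentary/light/moderate/vigorous) with a derived one: the mean
accelerometer counts per minute over the 5 minutes before the report,
classified by the Freedson cut points (<100, 100–1951, 1952–5724, ≥5725
CPM). From the 4×4 cross-tab the package computes, per level: match rate
(row-conditioned), sensitivity and specificity (column-conditioned — the
derived level defines the positives), LR+ = sens/(1−spec),
LR− = (1−sens)/spec, and a mixed-logistic odds ratio with participant
random intercepts. Two-sample Kolmogorov–Smirnov tests compare the derived
count distributions between reported levels, and a mixed linear model of
ln(CPM + 1) on reported level yields all pairwise contrasts with raw-CPM
back-transforms.

Exclusion filters mirror the study design: recall days must be biologically
plausible (500–5000 kcal, closed interval), activity prompts need non-zero
accelerometry on both 30-minute flanks and ≥5 hours of wear that day
(non-wear = runs of ≥60 consecutive zero-count epochs).

## Worked example

Simulate a cohort at the default study conditions (41 participants, 4 days,
8 prompts/day, up to three recall days each) and run both arms:

```python
from emaval import (CohortConfig, generate_cohort, load_study,
                    DietValidation, PAValidation)

bundle = generate_cohort(CohortConfig(seed=1))
bundle.write("study/")
tables = load_study("study/")
print(DietValidation.from_tables(tables).fit().summary())
print(PAValidation.from_tables(tables).fit().summary())
```

prints (abridged):

```
Diet-arm validation
===================
Analysed participant-days: 26 (excluded: 138)

Day-level match rates (min-count rule):
food group            mEMA  recall  matched  match %
sweets                   6      22        6    100.0
salty                    6      21        5     83.3
fruits_vegetables        6      22        5     83.3
entree                   2      10        2    100.0
breads_grains            5      13        5    100.0

Activity-arm validation
=======================
Analysed occasions: 630 (excluded prompts: 92)

Agreement by level:
level        match %  sens %  spec %     LR+     LR-                    OR
sedentary       60.6      93      33    1.38    0.21     6.56 (4.00-10.76)
light           65.0      15      94    2.52    0.91      2.79 (1.60-4.88)
moderate        22.2      23      97    6.64    0.80     8.37 (2.94-23.83)
vigorous         6.1      40      95    8.06    0.63   16.91 (1.95-146.32)

Log-count mixed model contrasts (higher minus lower level):
  sedentary vs light: 1.05 (0.66-1.45), p=1.96e-07, raw 190 CPM
  sedentary vs moderate: 1.73 (1.16-2.31), p=3.5e-09, raw 473 CPM
  sedentary vs vigorous: 2.07 (1.54-2.59), p=9.27e-15, raw 701 CPM
  ...
```

Reading the activity table: 60.6% of sedentary reports were confirmed
sedentary by the device; reported sedentary time is a sensitive (93%) but
unspecific (33%) marker of derived sedentary time; and the higher the
reported intensity the worse the match rate — the canonical pattern for
momentary activity self-report. The log-count contrasts say reported
non-sedentary occasions carry clearly higher counts than sedentary ones
(+1.05 to +2.07 on the log scale, i.e. +190 to +701 CPM), while the
non-sedentary levels barely separate from each other.

The same pipeline runs from a shell:

```bash
emaval simulate --seed 1 --out study/
emaval report --config config.yaml --seed 1 --out report/
emaval agreement --crosstab my_crosstab.csv
```

`emaval report` writes delimited-text tables, exclusion ledgers, a run log,
a YAML manifest and a machine-readable `summary.json` that is
byte-identical for a fixed config and seed. `emaval agreement` computes the
six agreement parameters from a pre-tabulated reported-vs-derived
cross-tab.

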