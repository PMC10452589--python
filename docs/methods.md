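# Methods

## Decision problem and model structure

The package evaluates follow-up schedules for patients rendered
disease-free by curative-intent metastasectomy of stage IV colorectal
cancer. Patients start with no evidence of disease (NED) and move monthly
among six states: NED, undetected recurrence, curative-intent treatment,
palliative care for asymptomatic disease, palliative care for symptomatic
disease, and dead (absorbing). The time horizon is 120 one-month cycles.

Within each cycle events resolve in a fixed order: (1) a death draw —
background mortality in NED and curative treatment, post-recurrence
mortality in the undetected and palliative states (mortality follows
disease status, not whether anyone knows about it); (2) in NED, the
scheduled visit if one falls in this cycle (with a possible
false-positive workup), then a recurrence draw; (3) in undetected
recurrence, a symptomatic-conversion draw — symptoms prompt presentation
the same cycle, independent of the schedule — otherwise the scheduled
visit may detect the recurrence; (4) on detection or presentation, a
repeat-resection draw (0.23 if asymptomatic, 0.05 if symptomatic), then
an operative-mortality draw (0.010) if resected, otherwise entry into the
palliative state matching symptom status; (5) curative treatment lasts 6
cycles (hepatic metastasectomy + recovery cost at entry, perioperative
chemotherapy during) and returns the patient to NED with renewed
recurrence risk; the original calendar schedule then resumes. Scheduled
surveillance stops at month 60; symptomatic presentation remains possible
at any cycle. Because colonoscopy is scheduled only at months 12 and 48,
no trajectory can contain more than two colonoscopies.

Consequence of the event order: when the mean undetected-to-symptomatic
time is at its 1-month floor, conversion is certain before any visit can
fire, so surveillance can no longer detect anything and the schedules
differ in cost only. This is the model's own limiting behaviour, exercised
by the deterministic sensitivity analysis.

## Calibration (constant hazards)

The source cohort (n = 257) exists only as printed summaries, so every
transition is an exponential (geometric, in discrete cycles) hazard — the
minimal assumption for a point survival summary:

| monthly probability | anchor | value |
|---|---|---|
| recurrence | 75.1% cumulative by the 76.4-month median follow-up | 0.01803 |
| background death | 81.5% 10-year survival, non-recurred stratum | 0.00170 |
| post-recurrence death | 25.4% 5-year survival, recurred stratum | 0.02258 |
| symptomatic conversion | geometric with mean 4 months | 0.25 |

Conventions worth making explicit: cumulative recurrence is treated as
crude incidence with no competing-risk or censoring correction (no
at-risk table exists); survival of the recurred stratum is measured from
recurrence; the recurred stratum's 10-year survival (3.1%) is *not*
jointly consistent with the 5-year figure under one exponential and is
deliberately not enforced — the 5-year figure anchors the hazard. These
choices are testable: the synthetic-cohort module regenerates
patient-level data under the calibrated hazards and recovers each printed
summary within Monte Carlo error (the parameter-recovery loop).

## Economic accrual

Utilities per state: NED 0.78; undetected recurrence and curative
treatment 0.74 (the generic "recurrence" utility); palliative
asymptomatic 0.68; palliative symptomatic 0.50. QALYs and life-years
accrue per cycle as u/12 and 1/12, discounted at 1.5%/year with the
mid-cycle factor (1+r)^(−(c−0.5)/12); the cycle of death contributes half
a cycle of state membership (half-cycle correction for an
individual-level model). One-off event costs (visits CAD 386.71, plus
colonoscopy 1059.35 when scheduled; metastasectomy 4086.72 + recovery
84.58) are charged in full at the event cycle. A false-positive visit
panel (probability 1 − ∏ specificities ≈ 0.205 per disease-free visit)
triggers one confirmatory CT (300.15), cost only — the minimal
consequential interpretation, switchable off via
`settings.false_positive_workup`.

Chemotherapy charging is genuinely ambiguous in the source material: the
published monthly figure (CAD 6409.77) charged every palliative cycle
would put 10-year totals near CAD 200,000, two orders of magnitude above
every published total (CAD 7,707–19,890), so the default
(`settings.chemo_charging: once_per_episode`) charges it once on entry
into a treated phase, which reproduces the published cost scale almost
exactly (q12 base case: 7,721 simulated vs 7,707 published). The strictly
per-cycle interpretation remains available (`monthly`).

## Randomness and reproducibility

All draws come from one (n_patients × 120 × 7) array of uniforms — one
column per draw type (death, recurrence, conversion, detection,
resection, operative death, false positive) — generated from a seeded
`numpy` `SeedSequence`. Patient *i* always consumes row *i*, so the same
patients are re-simulated under every strategy (common random numbers),
and results are bit-identical for identical seed + config. Two engines
consume the same array — a per-patient reference implementation that
records full trajectories, and a vectorized cohort engine — and the test
suite asserts their outputs agree to the last bit. PSA draw *d* keys its
parameter stream by (seed, d, 1) and its patient array by (seed, d), so
draw 0 of an all-point-mass PSA reproduces the base case exactly.

## Sensitivity analyses

PSA distributions follow the published table: gamma for costs and the
undetected-to-symptomatic time, beta for sensitivities, specificities and
operative mortality; utilities, the CEA test cost and the resection rates
are fixed. Ranges are read as 95% intervals (sd = width/3.92); printed
standard deviations are used directly; moment-matching gives gamma
(shape = (m/sd)², scale = sd²/m) and beta (mean/variance) parameters.
Degenerate rows (no spread, or a boundary mean such as the perfect
colonoscopy specificity) pass through unchanged; an infeasible beta sd is
clamped with a logged warning. Sampled undetected-to-symptomatic means
are floored at 1 month. Note the structural consequence: the 1–28 month
range implies a gamma with shape ≈ 0.34, so nearly half of PSA draws sit
at the 1-month floor where surveillance has cost but no benefit — this
single parameter dominates the acceptability curves, keeping the cheapest
schedule on top at every willingness-to-pay threshold.

The incremental table sorts by cost, removes absolutely dominated
strategies (≥ cost and ≤ effect, one strict), then iteratively removes
strategies whose ICER exceeds that of the next surviving row until ICERs
are non-decreasing; equal consecutive ICERs (collinear strategies) are
retained. Each row also reports the deltas against the adjacent row in
cost order, the convention used in published tables, labelled separately
from the frontier quantities. A brute-force net-monetary-benefit scan
over all candidate thresholds serves as an independent frontier oracle in
the tests. CEAC ties are split equally so curves sum to one.

Deterministic analyses re-calibrate and re-run the engine at fixed seed:
one-way over the undetected-to-symptomatic extremes (1 and 28 months) and
the ±25% opposite-direction repeat-resection scenarios; two-way over any
parameter pair, reporting the NMB-maximizing strategy at CAD 50,000/QALY.

## Problem sizes and defaults

Base case: 10,000 patients per strategy (Monte Carlo SE ≈ CAD 40 on cost,
≈ 0.021 QALY). PSA: 10,000 draws × 1,000 patients by config default; the
test suite exercises a 500 × 500 PSA and 2,000-patient deterministic
scenarios, sizes at which every qualitative conclusion reported here is
stable. The synthetic-cohort recovery checks use 20,000–100,000 patients
(binomial SE ≤ 0.4 percentage points on each recovered summary).

## What the synthetic cohort does and does not emulate

The generator draws patient-level recurrence, conversion, detection,
resection and death from the same hazards as the engine (an independent
inverse-CDF exponential path is kept as a cross-check oracle), so passing
recovery tests demonstrates internal consistency of calibration +
simulation — not fidelity to the real registry cohort, whose individual
data are unavailable. Real-data features deliberately not emulated:
non-constant (e.g. early-peaked) recurrence hazards, loss to follow-up,
site-of-metastasis strata, and any correlation between resectability and
disease burden.

## Known limitations

* Constant hazards spread recurrences uniformly over follow-up; if the
  true recurrence hazard is front-loaded (as clinical series suggest),
  late-schedule visits (q6's months 30–54) are worth less than this model
  estimates, and the frontier between q6 and q3/q12 would shift.
* The published effectiveness scale (≈ 0.9–1.0 LY over 10 years) cannot
  be derived from the published survival inputs (which imply ≈ 6 LY);
  absolute QALY/LY levels here are therefore on the model's own scale,
  and comparisons should be read incrementally.
* Symptomatic disease is a surrogate for unresectability; no molecular
  subtypes, novel systemic agents, liquid biopsy, or non-cancer life-table
  mortality.
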