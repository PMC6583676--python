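# Methods

## Model and assumptions

The pipeline reconstructs what a cost-effectiveness analysis would do with
individual patient data (IPD), using only the aggregates that osteoarthritis
trials actually publish.

**Pseudo-IPD simulation.** For one trial arm at one visit, the clinical
vector x = (WOMAC pain, WOMAC function, WOMAC stiffness, age, years since OA
diagnosis) is modelled as multivariate normal with the published means and
SDs and a correlation matrix (published, or taken from a fallback table when
not).  Vectors outside the permissible clinical ranges — pain [0, 20],
function [0, 68], stiffness [0, 8], age [0, 100], years-since-OA [0, 100] —
are rejected *jointly* and redrawn.  Two deliberate modelling choices:

* whole-vector rejection, never per-coordinate clipping: clipping creates
  probability atoms on the boundaries and biases correlations;
* the published aggregates parameterise the **untruncated** normal.  No
  re-calibration is applied, so the accepted sample's moments differ from
  the inputs wherever a box binds.  The discrepancy is negligible when means
  sit ≳3 SD inside the ranges (the usual case for OA trial populations) and
  is surfaced, not corrected: each run reports acceptance rates and a
  standardised moment diagnostic (`SimulationReport.moment_z`).

**Utility mapping.** u = β₀ + β·x + β_female, female fixed to 1.  The
coefficients are configuration (`--utility-profile`), because the regression
they come from is external to this package.  The bundled `placeholder`
profile is *synthetic* — plausible magnitudes only — and exists so the
machinery is testable; analyses intended for publication must transcribe the
real equation.  Utilities are raw regression outputs, not clamped to [0, 1]
(clamping is an opt-in flag); values outside [−0.5, 1] trigger a diagnostic
warning.  Mean utility change per arm is mean(endpoint u) − mean(baseline u).

**Pooling.** At a grid time t (months), per-study utility changes are pooled
with sample-size weights nᵢ/Σn, where nᵢ is the study's total N (the per-arm
split is not published; only the total enters the weights).  Eligibility:

* *main mode* — studies with duration **equal** to t.  The 6-month pooled
  change therefore uses only 6-month studies; earlier grid points remain in
  the trajectory.
* *sensitivity mode* — studies with duration d **≥** t, each prorated by the
  exact fraction t/d (a 3-year study contributes 3/36 of its full effect at
  month 3).  Studies shorter than t never contribute; at t = d proration
  reduces to main-mode inclusion.

**Interval widths.** Between grid points, elapsed time in years is
(tₖ − tₖ₋₁)/12 **truncated (floored) at two decimals**: 2 months → 0.16,
1 month → 0.08, 3 months → 0.25, 30 months → 2.5.  This convention is the
only one consistent with the published QALY tables this pipeline replicates;
exact twelfths are available with `year_fraction="exact"` for users who
prefer unrounded arithmetic.

**QALY and ICER.** QALY change over horizon h is the trapezoid area under
the pooled utility-change polyline from the origin (t = 0, change 0) —
computed on *changes*, so a deteriorating arm has a negative QALY change.
An absolute-utility AUC exists as a separate non-default function.  No
discounting at any horizon.  ICER = incremental cost / incremental QALY;
a ratio is reported only when both increments share a strict sign, otherwise
a dominance verdict ("Placebo better" when the intervention costs more and
gains no QALYs; indeterminate when both increments are exactly zero).
Classification against a willingness-to-pay threshold (default 30 000 €/QALY,
configurable; a package default, not a replicated quantity) maps dominance
through directly.

**Prices and costs.** A formulation's daily-price list is summarised by the
sample median plus a trimmed band: *high* = mean after dropping prices more
than 50% below the overall mean, *low* = mean after dropping prices more than
50% above it.  The trimming guarantees low ≤ mean ≤ high, but a skewed list's
median can fall outside the band, so only low ≤ high is enforced as an
invariant.  Cumulative cost is daily price × months × days-per-month, default
30 days/month; placebo is €0.

## Replication notes

`replicate-paper` reproduces the four published result tables from the
bundled ten-study table (`data/table1.csv`) and bundled daily price levels
(pCGS 0.65/0.79/0.88 €/day; other formulations 0.45/0.55/0.66 €/day).
Two quirks of the published tables are handled explicitly:

* **Calendar inconsistency.** The published pCGS cost rows imply 59
  days/month (139.83 € = 0.79 × 59 × 3), while every other-formulation cost
  row uses 30 days/month.  The replication applies the per-formulation
  presets (`REPLICATION_DAYS_PER_MONTH`) so the printed cost rows are
  reproduced exactly; everything else defaults to 30 days/month and the
  59-day calendar remains available via `--days-per-month 59`.
* **ICER printing.** The published ICER cells are truncated toward zero at
  the printed decimals (41 869.65 prints as 41 869.6), so the diff layer
  compares with a one-unit-in-the-last-printed-place tolerance.  Stored
  artifacts always keep full double precision.
* **Known discrepancy (4 cells).** In the sensitivity-mode table for the
  other formulations, the printed month-3 QALY cells (0.00056492 active,
  0.00140589 placebo) are not derivable from the study table under the
  pooling rule that reproduces every other table exactly.  Decomposing the
  printed values shows the month-2 column and the 3→6-month *increment*
  both match this pipeline to 8 decimals, isolating the inconsistency to the
  month-3 pooled change (the month-6 cells inherit it by accumulation); an
  exhaustive search over study subsets and proration fractions found no
  combination reproducing both arms.  The four cells are therefore reported
  as documented discrepancies, and all nine verdicts of that table
  ("Placebo better") still reproduce.

## Synthetic-data generator

`synthetic_data` generates complete two-arm, two-visit trials with known
ground truth so every stage is testable offline.  Baseline and endpoint are
drawn jointly from a 10-dimensional normal whose cross-visit block carries a
within-patient correlation (default 0.6) — without it, utility *changes*
would have unrealistically large variance.  Patients with either visit out
of range are redrawn whole.  Default truth: baseline means
(10, 34, 4, 62, 8), SDs (2.5, 9, 1, 8, 2.2), moderate positive correlations
among the WOMAC subscales, symptom improvements of (2.0, 7.0, 0.6) in the
active arm and (0.8, 2.8, 0.25) under placebo — a moderate knee-OA
population with a modest treatment effect, chosen so means sit ≈3 SD inside
every box and truncation is a negligible perturbation (the regime the
pseudo-IPD procedure assumes).  `random_truth_spec` draws replicate truths
from interior ranges around those defaults.

The generator does **not** emulate dropout, floor/ceiling pile-ups at the
scale boundaries, non-normal skew, site effects, or reporting error in the
published aggregates.  Passing recovery tests therefore show the *pipeline*
is correct and well-calibrated under its own distributional assumptions —
not that those assumptions hold for any given real trial.

## Numerical choices

* Covariance assembly diag(SD)·R·diag(SD); a directly published covariance
  can be passed through instead.  PSD is checked with tolerance 1e-8;
  repair (eigenvalue clipping) is opt-in, never silent.
* One root seed; per-study/arm/visit child streams keyed by
  (root, crc32(study id), arm code, visit code), so adding a study never
  perturbs the draws of the others.  Rejection batches are sized adaptively;
  an acceptance rate below 1e-4 after 1e6 draws is an infeasibility error.
* Baseline and endpoint are simulated independently in the reconstruction
  pathway (the published summaries are per-visit); a longitudinal
  correlation exists only in the synthetic generator, where the truth is
  known.
* Pooled values and QALYs are kept at full double precision everywhere;
  rounding happens only in the replication diff layer.
* Degenerate inputs: all-zero SDs yield an exact point mass (mean must be in
  range); zero-variance columns get unit self-correlation and zero
  cross-correlation when aggregating generated data; equal-price lists
  collapse to an exact three-way tie.

## Test problem sizes

Unit and acceptance tests run at the scale the analysis itself uses where
that is cheap (10 000 simulated patients per arm for recovery checks; 100
replicate synthetic trials for the coverage check; 1 000 random trajectories
and price lists for the oracle equivalences; marginal-mean oracles at 1e6
brute-force draws).  The whole suite completes in well under a minute on a
single CPU.

## Limitations

* Only drug costs are modelled — no healthcare-resource, productivity or
  caregiver costs, and no discounting.
* No heterogeneity modelling: pooling is a fixed sample-size-weighted mean
  with no confidence intervals, and no probabilistic sensitivity analysis.
* The utility mapping is a single linear main-effects equation; alternative
  mappings (e.g. EQ-5D crosswalks) are out of scope.
* The validation of the pseudo-IPD procedure against a real trial with
  published individual utilities requires data that are not redistributable;
  the package substitutes replicate synthetic-truth validation (above) and
  exposes the same interfaces for users who hold such data.
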