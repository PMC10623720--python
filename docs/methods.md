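# Methods

## Strain model and feature pipeline

An exam is six radial strain traces, one per mid-ventricular segment
(MAS, MIS, MAL, MIL, MA, MI), sampled over one cardiac cycle of length
`cycle_length_ms`, with the aortic-valve-closure time `avc_time_ms` measured
from cycle start. The pipeline assumes sinus rhythm and a single cycle per
exam; atrial fibrillation, paced rhythms and bundle-branch blocks are outside
the model.

**Normalization.** Time maps to % of the cycle; all six curves are divided by
the single exam-wide maximum strain value. The normalizer is per-exam, not
per-segment: per-segment scaling would erase the inter-segment amplitude
contrasts that the partial-AUC differences are built to detect. Exams with no
strictly positive strain sample are rejected (`DegenerateExam`) since the
max-normalizer is undefined.

**Resampling grid.** All features are computed on curves linearly resampled
to a 101-point uniform grid over [0, 100] % of the cycle. This fixes the
time-to-peak resolution at 1 % of the cycle, matching the integer-percent
scale on which such metrics are reported, and makes exams with different
export sampling rates comparable. Input traces must have ≥ 8 samples; the
exchange format imposes no fixed rate.

**Time-to-peak** is the grid time of the global maximum; exact ties resolve
to the earliest sample, and no smoothing is applied by default (an optional
moving average of configurable width exists but is off — determinism and
transparency beat marginal noise robustness at this grid resolution).

**Partial AUC** integrates the normalized curve over the 33–66 % window by
the trapezoid rule, linearly interpolating the curve at the window edges so
the value does not depend on whether a sample falls exactly on a bound.
Values are reported in arbitrary units scaled so that the unit full-cycle
integral maps to 1000; only within-cohort contrasts and orderings are
meaningful, never absolute values.

**Contrasts.** `d_ttp` and `d_pauc` are computed for the eight
septal/lateral-minus-reference pairs and are exactly antisymmetric under
pair reversal. Features expressed in % cycle are invariant to uniform time
rescaling of the raw exam; all features are invariant to positive rescaling
of the raw strain amplitudes (both properties are tested).

**Grade suggester.** The rule operationalizes the three qualitative
signatures of paradoxical septal motion: grade 2 when the septal/lateral
median of `ttp − AVC` exceeds 2 % cycle *and* the largest septal `d_ttp`
exceeds 2 % cycle; grade 1 when the median septal `d_ttp` exceeds 0.5 %
cycle *or* the median septal `d_pauc` exceeds 50 a.u.; grade 0 otherwise.
The medians (rather than maxima) in the grade-1 rule buy robustness against
single-segment jitter. Cutoffs sit between the grade-stratified medians of
the simulated feature distributions and are configurable. The suggester is
labelled exploratory in its output: the reference grading of septal motion
is human visual consensus, and the rule is a reading aid, not a replacement.

## Synthetic waveforms

Each segment is a raised-cosine systolic bump (half-width 0.18 cycle) peaking
at 0.39 of the cycle — just before AVC at 0.40, a physiologic systole
fraction — with amplitude ~45 % strain. At grade ≥ 1 the four septal/lateral
segments gain a second, narrower raised-cosine (half-width 0.10) centred
after AVC: at grade 1 the delay is ~1 % of the cycle with relative amplitude
1.15, at grade 2 ~4.5 % (clipped to 3–11 %) with relative amplitude 1.5, so
the delayed component carries the segment's global maximum. Reference
segments (MA, MI) never gain the delayed component. Between-exam severity
heterogeneity enters through one per-exam delay draw (sd 0.012 cycle);
between-segment variability through timing jitter (sd 0.005 cycle) and
relative amplitude jitter (10 %); measurement noise is additive white
Gaussian at 0.5 % strain — small, because speckle-tracking output curves are
already heavily smoothed by the vendor software.

Under these defaults, 200 simulated exams per grade give medians of all 16
inter-segment difference metrics strictly increasing with grade, grade-0
`d_ttp` medians at zero on the 1 %-cycle grid, and grade-2 medians of
`d_ttp(MIS−MI)` and `ttp(MAS)−AVC` of about 5 and 4 % cycle — inside the
interquartile envelopes reported for severe paradoxical septal motion
((0, 10) and (−1, 8) % cycle). What the generator does **not** emulate:
beat-to-beat variability, drift of the region of interest, segment dropout,
pericardial effusion or LBBB patterns, or any image-level artifact. Passing
tests therefore certify the feature algebra and the statistics pipeline, not
performance on vendor-exported clinical curves.

## Rater simulation

Two raters report the true grade with probability `q`, otherwise an adjacent
grade (grade 1 errs up or down with equal probability; grades 0 and 2 err to
grade 1). For a given truth vector, the expected two-rater Fleiss kappa is
available in closed form under this model, so `q` is calibrated by bisection
to hit any attainable kappa target; unattainable targets (e.g. a
single-category truth) raise `CalibrationError` instead of silently
saturating.

## Longitudinal cohort generator

Patients are examined on a fixed schedule (default days 0/4/8). The
septal-motion grade evolves by a Markov transition matrix (defaults favour
persistence with gradual progression); the RV/LV end-diastolic area ratio is
drawn consistently with the grade — grade 1 implies ratio ≥ 0.6, grade 2
implies ratio ≥ 1.0 — so severe dilatation is a deterministic consequence of
grade 2, reproducing the strict coupling of high-grade septal motion to
severe RV dilatation (specificity 1.0 by construction). Death and discharge
compete as piecewise-exponential hazards; the death hazard is the baseline
(0.015/day) times `exp` of the current exposure-state log-HR (default HR 6.0
for severe dilatation with grade 2) plus linear covariate effects (age,
SAPS II, cardiomyopathy). Discharge acts as independent censoring
(0.05/day); follow-up is capped at 60 days. The 2D-only grading is derived
from the true grading by a downgrade-only misreading: one step with
probability 0.3 and, for grade 2, a two-step downgrade with probability
0.17 — rates taken from the observed reclassification flows between the two
reading approaches (33/100 grade-1 and 8/48 grade-2 exams read lower on 2D
alone).

## Survival model

Serial exams become `(start, stop]` risk intervals with the exposure state —
RV-dilatation severity crossed with PSM grade, reference "none" — carried
forward from the last usable exam (LOCF, no interpolation, no washout). The
time origin is ICU inclusion; a patient whose first exam is unusable
(missing grade or ratio, or a graded exam with ratio < 0.6, which the
strict grade–dilatation coupling makes inconsistent) enters the risk set at
the first usable exam, with a logged count. Exams falling on the outcome day
contribute no risk time. The Cox partial likelihood is fit on the
counting-process data with Efron tie handling; Wald 95 % CIs per term.
Exposure levels with no person-time, or with all or none of the events,
have no interior partial-likelihood maximum and are reported non-estimable
rather than crashing the fit — under the generator's defaults
`moderate_grade2` is structurally empty (grade 2 forces ratio ≥ 1.0), so it
is always non-estimable there. Discharged-alive patients are censored at
discharge; competing-risk models are out of scope.

## Statistical conventions

- Kruskal–Wallis with tie correction; pairwise Wilcoxon rank-sum post-hocs
  only when the omnibus p ≤ 0.05, BH-adjusted as their own family of three.
  BH adjustment over a metric family mirrors per-table adjusted-p reporting.
- Fleiss kappa CIs: percentile bootstrap over exams (not raters), default
  2000 resamples, mandatory explicit seed; a bootstrap resample that
  collapses to one category counts as perfect agreement (kappa 1).
- ICC: two-way random effects, absolute agreement, single measure —
  ICC(2,1) — with the F-based CI; absolute agreement is what inter-rater
  measurement comparison requires.
- Sensitivity/specificity carry exact Clopper–Pearson CIs.
- Percentages round to the nearest integer over the stated denominator;
  medians are reported with 25th–75th percentiles.
- Missing grades and ratios are preserved as missing and excluded pairwise,
  never imputed.

## Problem sizes and seeds

The test suite and the acceptance script size their simulations for a
single-CPU laptop-scale run: 200 exams per grade for feature-distribution
checks, 300 exams for grading accuracy, cohorts of 300–500 patients with
100–200 replicates for Cox calibration and recovery, 1000 replicates for
rank-test calibration. The null-calibration experiment for the
time-dependent Cox model uses a baseline hazard of 0.04/day so that every
exposure level accrues enough events for Wald asymptotics to be the thing
under test, rather than small-sample artifacts. Every stochastic component
takes an explicit seed; the pipeline derives per-stage seeds from one run
seed via a fixed `SeedSequence` scheme, making full runs byte-reproducible.

## Known limitations

- The exchange format is a package-defined open CSV; vendor raw exports must
  be converted upstream.
- Absolute partial-AUC magnitudes are arbitrary-unit; only contrasts and
  orderings transfer across datasets.
- The grade suggester's cutoffs were chosen on simulated distributions and
  are not clinically validated.
- The Cox model treats discharge as non-informative censoring and carries
  states forward indefinitely; both are simplifications of ICU reality.
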