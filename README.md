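# psmstrain

Quantitative analysis of **paradoxical septal motion (PSM)** from left-ventricular
radial strain curves in ventilated ARDS patients, with the cohort statistics that
go with it: grade-stratified comparisons, inter-rater agreement, diagnostics
against right-ventricular dilatation, and a time-dependent Cox model of ICU
mortality.

## The problem

Acute cor pulmonale — acute RV failure under the elevated afterload of ARDS —
shows on echocardiography as RV dilatation plus paradoxical motion of the
interventricular septum. Visual grading of PSM on two-dimensional loops
(grade 0 = normal, 1 = transient end-systolic septal flattening, 2 = sustained
flattening or inversed septal bulging) is subjective. Segmental LV **radial
strain** curves offer an objective signal: with PSM, the septal segments (and,
mirroring them, the opposite lateral segments) reach peak strain *late*,
at or after aortic valve closure (AVC), and accumulate excess area under the
strain curve in mid-cycle, while the anterior and inferior segments keep a
normal early peak.

## What the package computes

For each exam (six mid-ventricular segments: MAS, MIS, MAL, MIL, MA, MI):

- **Normalization** — time as % of the cardiac cycle; strain divided by the
  single exam-wide maximum.
- **Time-to-peak** `ttp` (% cycle), and `ttp − AVC` per segment: positive
  values mark post-systolic peak strain.
- **Partial AUC** `pauc`: the integral of the normalized curve over the
  33–66 % window of the cycle (arbitrary units), where PSM reshapes the curve.
- **Inter-segment contrasts**: `d_ttp` and `d_pauc` for the eight
  septal/lateral-vs-anterior/inferior pairs (MAS−MA, MAS−MI, MIS−MA, MIS−MI,
  MAL−MA, MAL−MI, MIL−MA, MIL−MI), which cancel between-patient offsets.
- An exploratory **rule-based grade suggester** built on those contrasts.

On cohort tables (one row per exam: grades under 2D-only and 2D+strain
reading, RV/LV end-diastolic area ratio, covariates, ICU outcome):

- Kruskal–Wallis comparisons across grades with Benjamini–Hochberg adjustment
  and rank-sum post-hocs; median/IQR and count/percent summaries.
- Fleiss' kappa with a seeded bootstrap CI; ICC(2,1) for continuous ratings.
- Sensitivity/specificity with exact Clopper–Pearson CIs (e.g. grade-2 PSM
  predicting severe RV dilatation, ratio ≥ 1.0).
- 3×3 reclassification matrix between the two reading approaches.
- Counting-process construction of `(start, stop]` risk intervals from serial
  exams (states carried forward between exams) and a multivariate
  **time-dependent Cox model** with exposure states
  {none, moderate/severe RV dilatation × PSM grade 1/2}, adjusted for age,
  SAPS II and cardiomyopathy history (Efron ties; reference level: none).

A seeded synthetic-data module generates six-segment waveforms per grade,
two-rater panels calibrated to any attainable kappa, and longitudinal cohorts
with grade-dependent death hazards — so the full pipeline is testable without
patient data.

## Worked example

```python
from psmstrain.features import exam_features, grade_heuristic
from psmstrain.synthetic import WaveformParams, simulate_exam
from psmstrain.types import Segment

exam = simulate_exam(2, WaveformParams.noiseless())   # grade-2 archetype
segs, diff = exam_features(exam)
print(round(segs[Segment.MAS].ttp_minus_avc_pct, 1))  # 4.0
print(round(diff.d_ttp[(Segment.MIS, Segment.MI)], 1))  # 5.0
grade, why = grade_heuristic(diff)
print(grade)  # 2
```

The septal peak lands 4 % of the cycle after aortic valve closure and 5 %
later than the mid-inferior segment — the grade-2 signature — so the rule
suggests grade 2.

A full pipeline run over simulated inputs:

```bash
psmstrain simulate cohort --n-patients 120 --seed 7 --out sim/
psmstrain run-all --cohort sim/cohort.csv --out results/run --seed 7
```

writes the feature table, the grade-comparison table, agreement and
diagnostics JSON, the reclassification matrix, the risk-interval table and
the fitted Cox model (hazard ratios with 95 % CIs per exposure state).

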