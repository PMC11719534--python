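# Methods

## Scope and model

`parotid-dx` implements a rule-based diagnostic analysis for parotid gland
tumors on multiparametric MRI. The observable per lesion is a small feature
vector: eight reader-recorded qualitative findings (ghosting sign,
protein-rich cysts, capsule / complete capsule, calcifications,
hemorrhage, T2 and post-contrast homogeneity), two normalized
signal-intensity ratios (lesion-to-masseter on T2 and on late post-contrast
T1), an ADC value, and a dynamic contrast-enhanced (DCE) signal–time curve.
The diagnostic model is a fixed decision tree over three of these features
(ghosting → T1 ratio → T2 ratio) with four output classes (PA, WT, OBT,
MT), of which only MT is malignant.

The tree's test order is a modelling choice: the three tests themselves are
fixed by the source material but their arrangement is reconstructed as the
unique order consistent with the published confusion counts (Warthin
one-vs-rest perfect, 15 predicted PA, 10 predicted MT). Each prediction
logs its `rule_path`, so the topology is auditable per lesion.

## DCE curve model and typing

Curves are sampled at the acquisition grid (default 51 frames × 6.6 s,
injection after frame 4; first post-injection frame time = injection time).
Features: baseline = mean of pre-injection frames; peak = max over
post-injection frames, first occurrence on ties; washout ratio
`100·(peak − end)/(peak − baseline)`, clamped to [0, 100], undefined when
the curve never exceeds baseline. Types: A (peak > 120 s), B (peak ≤ 120 s,
washout ≥ 30 %), C (peak ≤ 120 s, washout < 30 %), D (flat).

Numerical conventions worth stating:

* **Flat cut.** "Flat" has no quantitative definition in the source; type D
  is assigned when relative enhancement (peak − baseline)/baseline is below
  a configurable cut, default 0.2. No type-D curve occurred in the original
  cohort, so this only matters for degenerate inputs.
* **Washout denominator** is peak-minus-baseline (the standard
  washout-ratio convention); the end point is the final acquired frame.
  Whether the original analysis used the final frame or a fixed time point
  is unstated; the final frame is assumed.
* **Multi-ROI aggregation.** Five or six ROI curves per lesion are averaged
  frame-wise before feature extraction; a majority-vote alternative
  (`type_curves_majority`) is provided since the consensus rule used in
  practice is unrecorded.
* **Boundaries.** Peak at exactly 120 s is not type A; washout of exactly
  30 % is type B. Ties and boundaries are tested explicitly.

## Synthetic cohort generator

The generator emulates the published group-level statistics of a 36-patient
cohort (14 PA / 10 WT / 4 OBT / 8 MT). Continuous features are sampled from
normal distributions truncated at a floor of 0.1 (ratios and ADC are
positive; the floor is ≥ 4 SD below every default mean, so truncation bias
is negligible). Defaults (mean ± SD):

| group | T2 ratio | late T1 ratio | ADC (10⁻³ mm²/s) | curve types | washout % |
| --- | --- | --- | --- | --- | --- |
| PA | 5.3 ± 1.1 | 2.6 ± 0.2 | 2.0 ± 0.3 | ½ A, ½ C | 15 ± 8 |
| WT | 2.4 ± 0.4 | 1.5 ± 0.2 | 0.8 ± 0.1 | all B | 64 ± 9 |
| OBT | 3.5 ± 1.2 | 2.2 ± 0.5 | 1.4 ± 0.4 | ¼ A, ½ B, ¼ C | 45 ± 15 |
| MT | 2.3 ± 0.7 | 2.5 ± 0.4 | 1.1 ± 0.4 | ¼ B, ¾ C | 54 ± 6 |

PA/WT/MT quantitative rows and the WT/MT washout statistics are the
published values; the curve-type mixtures are the published per-lesion
counts. The OBT row is **not** constrained by published summaries (the
original analysis excluded the 4-lesion OBT group from group comparisons);
its values are a one-time choice placed between the benign groups, and the
PA washout (only type-C curves, washout unreported) is likewise a one-time
choice well inside the type-C range. Qualitative-finding prevalences are
the published per-group fractions (e.g. ghosting 0/14, 10/10, 0/8).

Findings are independent Bernoulli draws with one exception: *complete
capsule* is drawn only among capsule-positive lesions with conditional
probability prev(complete)/prev(capsule), which preserves both marginal
prevalences exactly while honouring the implication complete ⇒ capsule.

DCE curves use a canonical piecewise-linear shape — flat baseline, linear
rise to peak, linear decay to the end value implied by the requested
washout. The source constrains only peak-time/washout summaries, which this
shape reproduces exactly. Requested peak times are snapped to the frame
grid (the signal only exists at frame times), nudged if needed to stay on
the requested side of the 120 s boundary; noise-free curves therefore
round-trip bit-exactly through feature extraction, and per-type washout
truncation ([30, 100] for B, [0, 30) for C) makes the generated label
always recoverable. Consequence worth knowing: MT type-C washouts
(group center 54 ± 6 truncated below 30) pile up just under 30 %, so with
per-frame noise some MT curves flip C → B — visible as
`curve_type_agreement < 1` in pipeline summaries, and an honest reflection
of how close that group sits to the type boundary.

Truncated normals are sampled by inverse-CDF transform (exact, cheap per
scalar draw). A master seed spawns independent substreams per group and per
pipeline stage, so cohorts are byte-reproducible and adding a group does
not perturb the others.

The 2-D phantom (`PhantomSpec`) is a synthetic stand-in for ROI measurement
on real images: a uniform gland background with an elliptical lesion and a
rectangular masseter patch, optional Gaussian noise, no MR physics. ROI
membership is by pixel-center inclusion without partial-volume weighting;
lesion ROI placement maximizes a local mean within the lesion mask,
approximating the "brightest solid portion" reading convention.

## Evaluation conventions

* **Non-diagnostic results** (FNAC) count in the sensitivity, specificity
  and accuracy denominators but not in PPV/NPV. This is the only convention
  consistent with all five published FNAC fractions (5/8, 18/23, 5/6,
  18/21, 23/31) given 8 malignant truths and 4 non-diagnostic samples among
  benign truths.
* **Rounding** of percents is half-up on the exact fraction (62.5 → 63,
  matching the published FNAC sensitivity), computed with rational
  arithmetic to avoid float ties.
* **Undefined metrics** (zero denominator) are reported as undefined, never
  as 0.
* The published DCE+DWI comparator sensitivity "76 % (6 of 8)" is
  internally inconsistent (6/8 = 75 %); this package always reports the
  exact fraction, hence 75, with the discrepancy documented at
  `REFERENCE_METHOD_CONFUSIONS`.
* **Group tests**: Pearson chi-square without continuity correction for
  contingency rows (the correction choice is unstated in the source;
  uncorrected matches the printed significance bounds), one-way ANOVA for
  continuous features; p-values are reported raw, without multiplicity
  adjustment.
* **Threshold derivation** (`derive_thresholds`) maximizes Youden's J over
  midpoints between consecutive observed values (T1: WT vs rest, rule
  "below"; T2: PA vs rest, rule "at or above"), breaking ties toward the
  midpoint of the class means. The derivation procedure used originally is
  unstated; this is a declared convention, and the shipped defaults remain
  the published cuts 2.0 / 3.5.

## Problem sizes and determinism

Statistical checks use 10,000 lesions per group for moment recovery (3
standard-error tolerance), 2,000 curves for washout recovery, 1,000
noise-free curves for typing round-trips, and 50-seed sweeps for
cohort-level behaviour; these sizes put Monte-Carlo error well below the
tolerances while keeping the whole suite in seconds. All randomness flows
from explicit seeds through `numpy.random.SeedSequence` spawning.

## What passing tests do and do not show

The simulator draws independent truncated normals per feature; real lesions
have correlated features (e.g. T2 signal and ADC both track cellularity),
reader findings are not independent Bernoulli events, and real S(t) curves
are not piecewise linear. Passing tests therefore demonstrate that the
*analysis chain* is correct and that the published tables follow exactly
from their counts — not that the decision tree would achieve these
operating characteristics on new patients. The cohort-level sensitivity
observed across simulated seeds (typically 6–8 of 8 malignant lesions
found) illustrates the sampling variability inherent to an n = 36 cohort.

## Known limitations

* No DICOM/NIfTI input, no segmentation, no detection of qualitative signs
  from images: findings enter as recorded annotations.
* No pharmacokinetic modelling (no Ktrans), no motion correction.
* ADC and curve type are computed and reported but do not enter the
  decision tree, mirroring the published algorithm.
* The OBT group's quantitative defaults are unconstrained by published
  data; treat OBT-level simulation results as illustrative only.
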