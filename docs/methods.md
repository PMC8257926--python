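# Methods

## Measurement model

The processed inner-ear MR image is taken as given: a real-valued signal
grid in which endolymph voxels are negative and perilymph voxels positive,
plus a label mask assigning each voxel to cochlea, vestibule, semicircular
canals (SCC) or background.  Volumetry is voxel counting: total fluid volume
= labelled voxel count × voxel volume, ELS volume counts the negative
voxels, ELS ratio = ELS/total.  Zero-signal voxels — measure-zero in real
data but possible in synthetic input — are classified as perilymph
(conservative toward "no hydrops") and reported in `n_zero_voxels`.
Triplicate measurement averages the volumes and recomputes the ratio from
the averaged volumes (ratio of means, not mean of ratios); on identical
digital input the repeats are deterministic, and an optional label-mask
perturbation (random voxel drop, default off) emulates human re-tracing
variability, which the clinical workflow may or may not have had.
Voxel-centre convention; no interpolation or partial-volume weighting.

## Synthetic cohort

The generator emulates the study design: controls contribute both ears
(47 subjects → 94 ear rows), patients contribute the affected ear only
(86 rows).  Per compartment and group, the ELS ratio (percent) is log-normal
with parameters obtained in closed form from the published median m and
quartiles (q1, q3):

    mu = ln m,    sigma = ln(q3/q1) / (2 z_0.75),   z_0.75 = Phi^-1(0.75).

A two-parameter family can match the median and the quartile *ratio*
exactly, but not also the absolute IQR width; median and spread ratio are
prioritised because the printed summaries are right-skewed.  Ratios are
truncated at 100% by resampling the whole per-ear triple, which preserves
the optional Gaussian-copula correlation between compartments
(`ratio_correlation`, default 0 = independent; the source reports no
dependence estimates).  Note truncation pulls the realised median of
heavy-tailed cells below the calibration target (about −3.6 percentage
points for the uMD vestibule, negligible elsewhere); calibration checks
therefore sample the untruncated marginal, which is what the closed form
parameterises.

Choices the source does not constrain, fixed once as synthetic conventions:

* total fluid volumes (not reported): log-normal with median 75 mm³
  (cochlea), 60 mm³ (vestibule), 60 mm³ (SCC) and 15% coefficient of
  variation — plausible adult inner-ear magnitudes, configurable;
* ordinal grade cutpoints for EHV/EHC (cited grading criteria are not
  restated in the source): vestibule ratio ≥ 1/3 mild, ≥ 1/2 significant;
  cochlea ≥ 0.2 mild, ≥ 1/3 significant; half-open intervals, boundary to
  the higher grade;
* onset interval: log-uniform on [1, 3650] days (the analysis works on
  log10(1 + days), so a flat log-scale prior is the neutral choice);
* sex/age: Bernoulli and normal with the published group compositions
  (25/47 vs 33/86 male; 58.4 ± 16.3 vs 56.9 ± 14.7 years).

One integer seed drives a single `numpy` Generator; the sampling order
(per subject: sex, age, then per ear: totals cochlea/vestibule/SCC, ratio
triple; patients add side and onset) is fixed, so equal config + seed gives
byte-identical tables.

What passing tests on these cohorts do **not** show: the generator draws
compartment ratios independently by default, has no measurement error on
volumes, no rater variability, no intra-subject correlation between a
control's two ears, and grade variables derived deterministically from the
same ratios the 3D model sees — so the advantage of the volumetric model
over the ordinal one is structural (information discarded by coarsening),
and the absolute AUC/AIC values are properties of the synthetic conditions,
not estimates of the clinical ones.

Phantoms realise an ear's six volumes as three cuboid slabs filled in raster
order (`round(volume/voxel volume)` fluid voxels, the first
`round(ELS volume/voxel volume)` of them negative, hence face-connected);
they are counting fixtures, not anatomy.

## Models and predictors

Predictors follow the published definitions exactly; ratio terms enter as
fractions in [0, 1] (the source does not state the scale; only coefficient
magnitudes differ, AUC/AIC are scale-invariant), volumes in mm³
unstandardised, female coded 1 so the reported higher female odds maps to a
positive coefficient.  The two shipped formulas are frozen as printed —
including the 3D model's hierarchy violations (`Sr` only inside `Sr:VCr`;
`Ch`, `Sh` in no main effect) — with no automatic term completion, and
interaction columns are literal products, not re-centred.

Fitting is IRLS with step-halving; convergence when the relative deviance
change drops below 1e-10, cap 100 iterations.  AIC counts the intercept.
Perfect separation (deviance → 0) or divergence at the cap is flagged
`separated` and non-converged; a tiny ridge penalty (1e-8) is available to
stabilise the Hessian on small or separable cohorts without materially
moving the estimates.  Rank-deficient designs raise an error naming the
collinear columns (QR with pivoting).

## Evaluation conventions

* Positive call at threshold t: `prob ≥ t`.
* AUC: Mann–Whitney with half-credit for ties ≡ trapezoidal area under the
  empirical ROC (asserted against an O(n²) pair-counting oracle).
* Operating point: closest top-left, argmin (1−sens)² + (1−spec)²; ties go
  to the higher (more specific) threshold.
* DeLong: structural-components covariance of the paired AUCs; z and
  two-sided normal p; identical predictions give p = 1, flagged degenerate.
* Continuous NRI: any probability increase/decrease counts as movement;
  variance is the independent sum of the event and non-event multinomial
  variances, no continuity correction (the source does not state its
  estimator; these are the cited-literature defaults, surfaced in the
  result object).
* An index with an empty denominator is NaN, never 0.

## Selection

The original search mechanics are undocumented, and the stated goals —
maximise AUC, minimise AIC — are two criteria.  Default: bidirectional
stepwise on AIC from the Sex-only model (Sex forced, as an adjustment
factor), interactions admissible without their main effects; AUC and
LOO-MSE are reported for every visited model rather than merged into a
joint objective.  Exhaustive enumeration is limited to pools of ≤ 15 terms.
Leave-one-out folds hold out one ear (matching the analysis that treats
ears as independent); `unit="subject"` holds out both ears of a control as
a clustering-honest sensitivity analysis.  Fold fits warm-start at the
full-data coefficients; a test verifies warm equals cold to 1e-8.

## Univariate statistics

Fisher's exact test uses the probability-mass two-sided rule (the default
of R, the environment the original analysis used); Mann–Whitney uses
midranks with tie-corrected continuity-corrected normal approximation,
switching to exact enumeration when both samples have n ≤ 8 (the continuity
choice affects the third decimal at these sample sizes); the onset
regression is OLS of ratio (percent) on log10(1 + days).

## Problem sizes

Defaults used by the tests and analysis scripts: cohorts of 180 ears (the
study size), calibration checks at 20,000 draws per cell, oracle suites at
n = 200–300 with 50 seeds or 500 bootstrap replicates, 1,000 randomized
phantoms on small grids, and 20-seed replication of the 2D-vs-3D direction.

## Known limitations

* The generator's independence and noise-free defaults (above) make
  absolute accuracy metrics optimistic relative to clinical data.
* Intra-subject correlation of control ears is ignored in fitting, as in
  the original analysis; only the LOO subject unit addresses it.
* No probit/penalised alternatives, categorical NRI, IDI, or ROC confidence
  bands.
* Phantom geometry is non-anatomical by design; volumetry accuracy claims
  are about counting, not segmentation.
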