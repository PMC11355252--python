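# Methods

`mhpredict` reimplements, as a tested pipeline, a clinical prediction study:
classifying eyes with an idiopathic macular hole (MH) into good and poor
six-month postoperative visual-acuity groups from preoperative clinical
information and handcrafted morphometry of colour-annotated OCT B-scans.
Because the patient data behind the study are not available, the package
ships a calibrated synthetic-cohort and mask generator; every quantitative
claim below is computed by the test suite or by `scripts/acceptance.py`,
never transcribed.

## Outcome definition

The outcome is the decimal best-corrected visual acuity (BCVA) six months
after vitrectomy, dichotomised at decimal 0.7 (0.15 logMAR, the acuity
required to renew a Japanese driver's licence): decimal BCVA >= 0.7 is
Group A (good prognosis), < 0.7 is Group B (poor prognosis). Group B is the
positive class throughout, so positive coefficients mean "pushes toward a
poor outcome". `assign_group` treats the boundary as inclusive for Group A.

## Masks and morphometry (`octfeat`)

The extractor does not segment raw B-scans. Its input is the annotation
layer: a 256x256 indexed label image with palette `0=background, 1=green
(ILM->OPL), 2=yellow (ONL), 3=sky-blue (ELM->EZ), 4=blue (EZ->RPE), 5=red
(IRF)`. The 256-px trim corresponds to 0.98 x 0.98 mm: the source raster is
768x496 px over 9 x 1.9 mm, and the crop is defined in a space resampled to
the axial pitch on both axes, 1900/496 = 3.8306 um/px (the renderer's
default uses the rounded 3.83). The trim subtends 0.98/9 x 30 = 3.27
degrees (3.26 when truncated to two decimals, as conventionally printed).

Measurement conventions (the annotation stores bands, so demarcation lines
are recovered as band-class interfaces):

* **Defect length (DL)** at the OPL (green/yellow), ELM (yellow/sky-blue)
  and EZ (sky-blue/blue) interfaces: the Euclidean distance between the two
  interface endpoints flanking the central gap, measured as the
  *missing-gap* extent — `hypot((col_r - col_l - 1) * pitch_x,
  (row_r - row_l) * pitch_y)`. An unbroken interface has DL = 0. A config
  flag is not needed for horizontal-only measurement; pass masks with flat
  boundaries or compute from the returned endpoints.
* **Shortest defect length (sDL)** per colour band: the minimum
  pixel-centre distance between the two connected components flanking the
  hole (KD-tree query; verified against an exhaustive O(n^2) oracle). For
  the same underlying gap, sDL is one pixel larger than DL; both
  conventions are within the 2-px round-trip tolerance and are applied
  identically by the renderer's ground truth.
* **Hole diameters**: the cavity is the set of background runs containing
  the central column and bounded by retinal classes on both sides, over
  rows above the RPE level (bottom of the blue band). Hole-min (minimum
  linear diameter) is the narrowest horizontal run; BDM (base diameter) is
  the run width at the deepest cavity row, i.e. at the RPE — matching the
  clinical definition of the basal diameter.
* **Areas** are raw pixel counts per class in the 256x256 trim (the
  published magnitudes, e.g. green-band area ~7.3e3, are consistent with
  px^2, not um^2); `in_um2=True` rescales by `pitch_x * pitch_y`.

`compose_features` assembles the canonical 41-feature record: 11 clinical
background items (7 categorical, 4 continuous), 9 lengths, 5 areas, and 16
combinations (8 differences, 8 ratios) computed exactly from the base
features. A zero ratio denominator or any missing value flags the record,
mirroring the study's "no missing data" inclusion criterion; such records
are dropped with a logged warning.

## Synthetic cohorts (`synthgen`)

`sample_feature_table` draws group-conditional cohorts (defaults 32 good /
11 poor) whose 18 base continuous features are calibrated to the published
per-group means and SDs — BCVA in logMAR, axial length in mm, disease
duration in months, lengths in um, areas in px^2. Categorical features use
the published per-group counts; only the peel proportion of the ILM item is
published, so the invert / not-peel split of the remainder (A: 22/8/2,
B: 4/6/1) is a modelling choice.

Within-group correlations are recovered from the published SDs of the
*difference* features via Var(X-Y) = Var(X) + Var(Y) - 2 rho sx sy, giving
eight pinned pairs per group (e.g. OPL-DL ~ ONL-DL: 0.62 in Group A, 0.97
in Group B; ELM-DL ~ ONL-DL: 0.94/0.94). Ratio-feature SDs admit no closed
form and are not used. Unpinned morphometric pairs (lengths and areas)
default to 0.5 — retinal-layer gaps are anatomically coupled — and
clinical-morphometric pairs to 0, there being no printed evidence of
coupling; both defaults are configurable. The assembled matrix is generally
not positive semidefinite (a flat 0.5 background is inconsistent with
near-unit pinned pairs), so it is repaired by alternating projections onto
the PSD cone *with the pinned entries held fixed*: only the default-filled
entries move (by up to ~0.3), the repair is logged, and the calibrated
correlations survive to the sampled data (verified to within 0.03 at
n = 3000 per group).

Lengths and areas must be nonnegative, yet several features have a large
coefficient of variation (IRF area: SD/mean ~ 0.63–0.74), so naive
rejection or clipping of negative Gaussian draws would shift the sample
mean by far more than sampling error. Instead each nonnegative feature uses
a zero-truncated normal marginal whose underlying (mu, sigma) are
moment-matched by root finding so the *truncated* distribution has exactly
the configured mean and SD; the joint is a Gaussian copula over the
repaired correlation matrix. Features with negligible truncation mass are
left untouched. The 16 combination features are always computed from the
sampled base features, never sampled independently. Fixed seeds give
byte-identical tables.

`render_synthetic_mask` rasterises a parametric hole: four stacked bands
(default thicknesses 110/80/25/25 um, vertically centred) carved by a
cavity whose width profile is piecewise linear through anchors at the
retina top, the three boundary rows (OPL/ELM/EZ gaps), each band's mid-row
(per-band waists) and the hole base at the RPE (base diameter, default
724 um). Optional IRF ellipses are painted strictly interior to a single
band, at least one pixel clear of the cavity and the band boundaries, so
they can never alter a length measurement. Ground truth is derived from the
*rasterised* profile with the same conventions as the extractor, so
round-trip recovery is exact up to rasterisation of the configured values
(tested at 2 px x pitch for lengths, 3% for areas, over 50 random
geometries).

What the generator does **not** emulate: OCT speckle or texture (it renders
the annotation layer, not B-scans), skewed or heavy-tailed feature
distributions (marginals are (truncated) Gaussian), annotation error, and
any clinical-morphometric dependence. Passing tests therefore demonstrate
that the *pipeline machinery* is correct and that its behaviour under the
published second-moment conditions is reproducible — not that the synthetic
cohorts are distributionally faithful to the real patients (see
"Reconstruction fidelity" below).

## Variable selection (`select`)

A pure filter method at alpha = 0.05, with no multiplicity correction
(matching the source analysis): two-sample Kolmogorov–Smirnov for
continuous features (exact null when n_a * n_b <= 1e4, asymptotic
otherwise) and Fisher's exact test for categorical ones. For r x c tables
(hole stage and ILM handling have three levels) the Freeman–Halton
extension is computed by exact enumeration of all margin-constrained tables
for n <= 60 and by seeded permutation Monte Carlo (>= 1e5 draws) above; the
enumeration reproduces R's `fisher.test` to seven digits on the published
stage table (p = 0.524). A Wilcoxon signed-rank test (zeros dropped, ties
mid-ranked) is provided for the paired before/after acuity comparison.

Candidates are then pruned for multicollinearity: each candidate is
OLS-regressed on all other remaining candidates (intercept included, the
preoperative acuity participating like any other candidate); while any
auxiliary R^2 exceeds 0.9 (VIF = 1/(1-R^2) > 10), the single worst offender
is dropped — exact ties resolved by dropping the feature later in canonical
order — and the regressions repeat. Dropping one feature per iteration is
the conservative reading of the published flowchart and reproduces its
one-exclusion outcome (the ELM defect length, whose auxiliary R^2 against
the other four published candidates exceeds 0.85 in >= 90% of large
calibrated replicates). On small replicate cohorts the filter can come up
empty; the pipeline then falls back to the single smallest-p feature so the
model stays estimable, with a logged warning.

## Classifier (`model`)

L2-penalised logistic regression on z-scored features (training-fold mean
and n-1 SD), fitted with scikit-learn's lbfgs solver; the objective is the
summed binomial log-likelihood minus ||w||^2 / (2c) with the intercept
unpenalised, verified against a brute-force likelihood-surface oracle to
1e-3. Standardisation before fitting makes the weights standard regression
coefficients, invariant to affine rescaling of the raw features (tested to
1e-6).

The constant c is not tuned per split but *fixed by frequency*: 100 seeded
pre-tests each run stratified 5-fold CV over the grid {0.001, 0.01, 0.1, 1,
10, 100}, score the pooled out-of-fold predictions by AUC (objective ties
to the smaller, i.e. stronger, constant), and the modal winner is frozen
for the final evaluation. On the calibrated 32/11 cohorts the modal fixed
constant is 0.1 in the majority of cohort seeds.

The decision threshold is aligned, on the training folds only, to a
conservative operating point: among candidate thresholds (midpoints of the
sorted unique scores plus all-positive / none-positive sentinels, a
zero-positive cut defining precision = 1 and recall = 0) those with
precision >= recall are feasible, and the feasible threshold maximising the
F-measure is chosen, ties toward the higher threshold. The clinical
rationale is asymmetric costs: a false poor-prognosis call can discourage a
patient from surgery, so high precision on the poor-prognosis class is
preferred over high recall. An `accuracy >= recall` variant is available
(`alignment_rule="accuracy"`). The guarantee precision >= recall holds on
the data the threshold was aligned on; out of fold it holds for the summary
means and for most, but provably not all, individual repeats (with 11
positives a single extra false positive can invert the inequality).

## Evaluation (`evalcv`)

Stratified k-fold assignment deals each shuffled class into k folds whose
per-class counts differ by at most one (32/11 at k=5 gives 7,7,6,6,6 and
3,2,2,2,2). Each of the 100 repetitions reshuffles the folds from a seed
spawned off the master seed; per fold the model is standardised, fitted and
threshold-aligned on the training blocks only, then scored on the held-out
block, and the five held-out blocks are pooled into one per-repeat ROC/AUC
(rank formulation, half credit for ties) and one per-repeat confusion
matrix. The 100 per-repeat values of accuracy, precision (1 when nothing is
predicted positive), recall, F-measure and AUC are summarised by mean,
sample SD and a 95% CI for the mean using the t quantile with n-1 df (z
optional); the t convention reproduces the published AUC and recall
intervals exactly at three decimals. Mean ROC curves average the per-repeat
sweeps on a common false-positive-rate grid. Coefficients are reported over
all fold models with mean, SD, CI and 1.5xIQR box-whisker statistics. The
clinical-information-only control runs the identical pipeline restricted to
the 11 background features; on single-signal cohorts its AUC converges to
the closed-form binormal value Phi(dmu/sqrt(sa^2+sb^2)) ~ 0.80 for the
published acuity moments.

Selection and hyperparameter fixing run once per cohort, before the
evaluation CV — the same (optimistic) design as the source study; only
standardisation, fitting and threshold alignment are nested inside folds.

## Reconstruction fidelity and limitations

With everything above at defaults, the 20-seed reconstruction
(`scripts/acceptance.py`) yields a mean cross-validated AUC of ~0.91
(per-cohort SD ~0.05), higher than the published 0.843. The discrepancy is
informative rather than accidental: the published per-feature p-values are
systematically weaker than Gaussian features with the same moments would
produce (a ~0.9-pooled-SD base-diameter effect prints p = 0.162), implying
skewed or heavy-tailed real distributions. Second-moment-calibrated
Gaussian-copula cohorts are therefore cleaner: the filter passes more
candidates (typically 6–13 versus the published 5) and the linear
classifier separates them better. Matching the published AUC exactly would
require distributional information the source tables do not contain.

Other limitations: standard regression coefficients ignore interactions
among the explanatory variables; hole-height indices (MHI, THI) are out of
scope because the annotation cannot define a hole height when the base is
tilted; the renderer's funnel profile is symmetric about the central
column, so tilted-base or eccentric holes are not modelled; and the
Monte-Carlo Freeman–Halton path is only exercised above n = 60, which the
43-patient design never reaches in practice.

## Problem sizes used by the shipped checks

The test suite and acceptance script were sized for a single CPU: 20
cohorts of 43 patients with the full 100x5 tuning and evaluation CV for the
reconstruction (~5 minutes), 50 random geometries for the mask round trip,
n = 3000 per group for correlation-recovery checks and 3200/1100 for moment
calibration, and 4000 replicates for the signed-rank type-I-error check.
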