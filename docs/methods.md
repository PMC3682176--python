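# Methods

## The longitudinal model

Each subject contributes two grey-matter-density (GMD) volumes on a common
grid. The Step-1 GLM for an N-subject training set stacks the 2N scans
subject-major and fits, at every voxel,

    GMD(i,t,v) = subject_i(v) + a(v)·τ_t + b_V(v)·e_V(i,t) + b_P(v)·e_P(i,t) + ε(i,t,v)

* `subject_i(v)` — N indicator columns absorbing each subject's average
  density, so only within-subject change is informative;
* `τ_t ∈ {−1,+1}` — the shared age/time drift `a(v)`;
* `e_V(i,t1) = −ΔVIQ_i`, `e_V(i,t2) = +ΔVIQ_i` (and likewise `e_P`) — the
  signed-change encoding of the IQ-change covariates. The encoding uses ±Δ
  (not ±Δ/2); the Step-2 prediction regression is invariant to this scale,
  but it means a planted slope `b` appears as `2b` in a regression of the
  difference image on Δ.

With N + 3 columns and 2N rows the residual degrees of freedom are N − 3.
Because τ, e_V and e_P are antisymmetric within subject and the indicators
absorb subject means, the model is algebraically identical to regressing the
within-subject difference images on `[1, ΔVIQ, ΔPIQ]` with the same df: the
coefficient and its standard error both scale by 2, leaving t unchanged. The
package fits the full design in `fit_contrast` and uses the difference-image
reduction inside the permutation loop; the test suite asserts their
agreement to 1e-8 against an independent least-squares oracle.

t maps are converted to Z by pushing the one-sided t p-value through the
standard-normal inverse. Voxels with numerically zero residual (noiseless
simulations) report an infinite-t sentinel with Z capped at 38.

## Multiple-comparison control

Whole-volume correction uses sign-flipping permutation rather than
random-field theory: RFT's smoothness machinery is disproportionate on a
32³ grid and is not what this package exists to study, while permutation is
assumption-light and exact at this scale. Each permutation independently
negates each subject's encoded change covariates (equivalently, flips the
sign of that subject's difference-image/covariate relation; the time effect
stays in the intercept) and records the volume-wise max t plus the max
supra-threshold cluster size at the measure's cluster-forming threshold.
The 95th percentiles of those null distributions give the height and extent
critical values; a cluster survives correction by height **or** extent.
`n_perm ≥ 100` is enforced; the default is 500.

Cluster-forming thresholds default to one-sided p < 0.001 for VIQ and
p < 0.01 for PIQ, both configurable per run (the source material reports
slightly different values in different places, so neither is asserted as
canonical). Connectivity defaults to 26-neighbour, with 6 and 18 available
and recorded in outputs. Cluster peaks break ties to the smallest linear
index with x varying fastest, making extraction independent of traversal
order.

A selected region must additionally show a VIQ-vs-PIQ difference (V−P for
VIQ regions, P−V for PIQ) at p < 0.01 uncorrected. This conjunction is
assessed at the cluster's peak voxel — whether the original analysis
assessed it at the peak or over the whole cluster is not documented, so the
peak-voxel convention is implemented and flagged here.

## Cross-validation schemes

**Leave-One-Out.** Step 1 runs n times on n−1 subjects. Per measure, the
selected cluster with the highest peak t supplies the read-out voxel (peak
by default; cluster-mean optional, recorded in output). The held-out
subject's change is predicted from the training regression
`Δ IQ ~ 1 + Δdensity`; Time-2 IQ from the joint fit `t2 ~ 1 + t1 + Δdensity`
(a residualised two-stage fit would be an alternative; the joint fit is the
simpler convention and is what is implemented). The scheme's R² regresses
measured on predicted values across the n held-out subjects and is asserted
equal to the squared predicted/measured correlation on every run. A fold
whose training density variance at the peak is zero, or which selects
nothing, is flagged and excluded from aggregation with a warning count.

**Stratified split-half.** Subjects are ranked by a full-scale-IQ proxy —
the mean of the four printed scores (VIQ/PIQ at both time points), since no
separate full-scale score is published — and median-split into high/low
strata; each stratum is randomly halved between groups A and B (odd
stratum: coin flip for the extra subject), so a 33-subject cohort always
yields groups of 16 and 17. Each of 25 repeats contributes two analyses
(train A/test B and the reverse). Step 1 on a half-sample rarely survives
whole-brain correction, so selection falls back to the most significant
contiguous supra-threshold cluster inside an anatomical search mask (basis
recorded as `search-space-max`, type-II flag set); if nothing in the mask
reaches the forming threshold the single best voxel in the mask is used.
Step 2 is fitted *within* the test half — matching the asymmetry of the
procedure this package re-examines, in which region selection is
independent of the test subjects but the regression parameters are not —
and records R² for `Δ IQ ~ Δdensity` and the hierarchical pair
`t2 ~ t1` / `t2 ~ t1 + Δdensity` (the increment is non-negative by nesting
and checked on every run). Duplicate partitions across repeats are
permitted; with 25 repeats every subject is observed to appear in at least
one validation set under the default seed (checked, not guaranteed).

All randomness flows from one master seed through named substreams
(splits, permutations, simulation), so runs are bit-reproducible from the
manifest YAML written alongside results.

## Synthetic cohort

The generator emulates already-preprocessed (segmented, normalised,
smoothed) GMD volumes:

    GMD(i,t,v) = baseline_i(v) + a(v)·τ_t + b_V(v)·e_V(i,t) + b_P(v)·e_P(i,t) + ε(i,t,v)

* behavioural tables: per measure, (t1, t2) bivariate normal with the
  reference cohort's marginals (VIQ 113 ± 15.1 / 116 ± 18.0, r = 0.81;
  PIQ 108 ± 12.3 / 107 ± 9.6, r = 0.59), rounded to integer IQ points;
* `baseline_i(v)`: a smooth random field (mean 0.5, SD 0.05 density units)
  drawn once per subject and identical at both time points — it cancels in
  differences exactly as subject indicators cancel it in the GLM;
* `a(v)`: a smooth shared drift field (amplitude 0.005 density units);
* effect regions: two disjoint spheres (radius ≈ 8% of the grid side) with
  constant slopes `b_V`, `b_P` in density units per encoded IQ point;
* `ε`: white Gaussian noise of SD 1.0 smoothed with an 8 mm FWHM kernel
  (periodic boundaries), matching the smoothing applied to the volumes the
  analysis consumes. Smoothing shrinks the per-voxel SD by a kernel factor;
  the effective SD is estimated by noise-only simulation, never assumed.

Default grid: 32³ voxels at 3 mm isotropic. Method validation does not need
the study's ~1.5 mm whole-brain grid; 3 mm keeps the 8 mm kernel at ≈ 2.7
voxels FWHM, so cluster inference still faces substantial spatial
autocorrelation. The planted peak R²,

    R² = Var(2bΔ) / (Var(2bΔ) + 2σ_eff²),

is the yardstick for recovery tests; `calibrate_slope` inverts it so a
target R² (0.8 for the strong-effect cohort, mirroring the strength of the
reported VIQ effect) fixes the slope given the cohort's change variance and
the measured σ_eff.

What the generator does *not* emulate: cortical anatomy and tissue
boundaries, segmentation/normalisation artefacts, non-stationary smoothness,
site or scanner effects, and any dependence between VIQ and PIQ changes
(drawn independently). Passing tests therefore demonstrate the pipeline's
statistical behaviour under its own assumptions, not robustness to the
messiness of real structural MRI.

## Numerical choices and degenerate inputs

* Standard deviations use the n−1 denominator throughout (matches the
  printed cohort SDs).
* Zero-variance columns make correlations undefined (NaN), never silently 0.
* Behavioural tables with printed change columns are cross-checked against
  recomputed differences and rejected on any mismatch.
* A cohort with no IQ change makes the corresponding covariate identically
  zero; the design is flagged degenerate and contrasts touching it error
  out by name.
* Permutation percentiles use the `higher` quantile method (conservative).
* OLS fits use explicit normal equations or `lstsq`; the nested-model
  increment is reported as 0 with a warning when the density column is
  collinear with Time-1 IQ.

## Problem sizes

The packaged test suite runs the full pipelines at reduced scale (grids of
8–16 voxels per side, 100–150 permutations, 6–25 split repeats) so the
whole suite completes in a few minutes; the acceptance script runs the
full-scale condition (32³ grid, 500 permutations per analysis, 25 repeats),
completing in a few minutes more. The family-wise-error and
scheme-comparison studies use 25 null cohorts and 10 matched-seed cohorts
respectively — enough for the binomial tolerance and directional claims
they test.

## Known limitations

* Only peak-voxel and cluster-mean read-outs are provided; multivariate or
  multi-region prediction is out of scope.
* k-fold for 2 < k < n, bootstrap and jack-knife variants are not
  implemented.
* The split-half fallback mask is defined around the planted ground truth
  (the synthetic analogue of an atlas-defined search space); analyses of
  real data would supply their own mask.
* Permutation inference assumes within-subject difference images are
  sign-exchangeable under the null; heavy-tailed or skewed noise is not
  modelled.
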