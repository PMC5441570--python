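# Methods

## Pipeline model

`connstab` treats a multi-site case/control task-fMRI study as a sequence of
three fitted models over one shared data structure, the `FeatureMatrix`
(run samples × features, with typed descriptors and per-sample site / group /
scale metadata):

* `GroupDifference` — mass-univariate pooled-variance two-sample *t*-tests
  with Bonferroni and Benjamini–Hochberg (BH) control;
* `DiagnosisCV` — leave-one-subject-out (LOSO) classification with per-fold
  filter feature selection;
* `SeverityEN` — elastic-net regression of integer 0–5 symptom scales under
  LOSO over patients, with grid-wide multiplicity correction.

Stability analysis (top-k overlap across folds, stable Bonferroni and stable
elastic-net supports) connects the stages.

### Statistical choices

* **t-test variant.** Pooled-variance (Student) rather than Welch: the null
  being ranked is "equal means and variances", and the z-scored features have
  near-equal group variances by construction. Sign convention: positive *t*
  means the patient mean exceeds the control mean. Zero pooled variance gives
  p = 1 when the group means agree, p = 0 otherwise, flagged as degenerate.
* **Samples are runs, not subjects.** A 95-subject, 4-run cohort contributes
  380 rows. Runs of one subject are not independent, so single-dataset
  p-values are optimistic in a way the stability analysis (subject-level
  folds) is designed to expose; this caveat is intrinsic to the design.
* **FDR flavor.** BH step-up (independence assumption), not
  Benjamini–Yekutieli; link features are weakly positively dependent, for
  which BH is the standard practical choice.
* **Bonferroni** uses the strict inequality p < α/m; BH uses p(i) ≤ iα/m.
  Bonferroni survivors are therefore always a subset of BH survivors.
* **Normality QC** is a one-sample Kolmogorov–Smirnov test against a normal
  with the group's *estimated* mean and SD. Estimating the parameters makes
  the test conservative (the Lilliefors effect): on truly Gaussian data the
  flagged fraction falls below the nominal α. The QC is used to confirm that
  features are not grossly non-normal, not as a calibrated test.
* **Residualization** regresses each feature on [1, covariates] by least
  squares (minimum-norm on rank-deficient designs, with a warning); used for
  nuisance controls such as motion summaries.

### Network features

* **Threshold semantics.** The degree graph uses the signed strict rule
  *r* > *c* with *c* = 0.7 by default; an `absolute=True` option thresholds
  |r| instead. After typical preprocessing, negative correlations above such
  cutoffs are rare, and the signed rule keeps "hyperconnectivity" (increased
  positive coupling) interpretable.
* **Degrees never materialize the full voxel-pair matrix**: correlations are
  accumulated tile-by-tile against the standardized series (working set one
  tile), verified against the naive full-matrix oracle on small grids.
* **Supervoxels.** Blocks tile from grid index (0,0,0), half-open
  [origin, origin + block), coordinates 0-based. A supervoxel's series is the
  arithmetic mean of its in-mask member series (order-preserving, standard
  down-sampling); blocks with in-mask fraction < `min_fill` (default 0.5) are
  dropped. Link features are the upper-triangle correlations in lexicographic
  (i, j), i < j order.
* **Constant series** get correlation 0 with everything (flagged) rather than
  NaN propagation.
* **Within-site standardization** z-scores per (site, feature) with sample SD
  (ddof = 1); features constant within a site become 0 and are flagged; a
  site with one sample is an error. Note a real trade-off, visible in the
  synthetic recovery experiments: subtracting the within-site mean removes
  not only scanner offsets but also any *between-site* component of the
  biological signal, slightly attenuating e.g. scale prediction when sites
  hold few subjects. This is inherent to the method, not an implementation
  artifact; the raw `link_weight`/`log_degree` variants remain available.

### Classification

* **Folds.** One fold per subject; all of a subject's runs form the test set.
  Predictions are per run; a fold's error is the fraction of the subject's
  runs misclassified (no majority vote), FP/FN rates take patient as the
  positive class on their own denominators.
* **No leakage.** The t-test ranking is recomputed from each fold's training
  rows; a mutation test asserts that altering held-out rows cannot change a
  fold's selection. `double_dip_comparison` quantifies the alternative
  (ranking once on all rows): on pure-noise features with thousands of
  variables it inflates apparent accuracy by tens of points.
* **Hyperparameters** are fixed, conventional defaults (SVM C = 1, kNN k = 5,
  100 trees, …) exposed as keyword arguments; classifier tuning is outside
  the contract, which is fold construction, per-fold ranking and aggregation.
  The best k is chosen by minimum mean error *after* all folds complete.

### Elastic-net scale prediction

* **Objective.** (1/2n)‖y − Xw‖² + λ₁‖w‖₁ + (λ₂/2)‖w‖², solved by
  scikit-learn coordinate descent. Because implementations scale λ₁
  differently, the interface targets a *support size*: λ₁ is bisected in log
  space between the all-zero point λ₁ᵐᵃˣ = max|Xᵀ(y − ȳ)|/n and a
  near-unpenalized floor (25 iterations), keeping the largest support not
  exceeding the target. Support size is non-increasing in λ₁ up to unit-sized
  path jumps, which the search and tests tolerate.
* **Protocol.** Patients only; train rows standardized per fold (train-set
  column mean/SD), the held-out patient's runs predicted and pooled;
  Spearman ρ, its p, and MAE computed on the pooled run-level predictions
  against the subject's integer score. Constant pooled predictions or
  all-empty supports leave ρ undefined (NaN, p = 1, flagged).
* **Grids.** Default targets {50, 100, 300, 500, 700} and λ₂ ∈
  {0.01, 0.1, 1.0}; with 9 scales this is the 135-configuration grid that the
  joint Bonferroni/BH correction runs over. λ₂ values are a conventional
  log-spaced ridge grid (the exact values matter little once the support size
  is pinned).
* **Parsimonious selection**: among FDR-surviving configurations, those with
  ρ ≥ best − 5%·|best| are candidates; the smallest target support wins, ties
  to the smallest λ₂. The window is written sign-safely so the best entry is
  always a candidate even if only negative correlations are significant.
* **Stable support**: features with nonzero coefficients in every fold of the
  chosen configuration.

### Stability

Top-k selection sorts by p ascending with ties broken by feature index
(stable sort), so intersections are reproducible. The overlap fraction is
|∩ folds' top-k| / k; it is exactly 1 at k = N. The default k grid is powers
of 2 from 2 to 2¹⁴ plus 30 (a highlighted subset size), capped at N.

## Synthetic cohort generator

The generator emulates the *structure* of a multi-site clinical fMRI study,
not its physiology. Per subject:

1. a supervoxel-level correlation matrix: compound-symmetric baseline
   `base_corr` (default 0.1); patients get `delta_r` (default 0.25) added on
   the planted links — the hyperconnectivity direction; plus a per-subject
   N(0, `subject_corr_sd`) perturbation of the planted entries (default
   0.15, clipped to |r| ≤ 0.9), then eigenvalue-clipping PSD repair. The
   group-level constructor rejects configurations whose repair moves any
   entry by more than 0.05.
2. per run, T (default 137) samples of a zero-mean Gaussian process with that
   correlation (Cholesky);
3. voxel series = block latent + N(0, `voxel_noise_sd`² ) voxel noise
   (default 0.5), then the site's affine distortion — per-voxel offset ~
   N(0, `site_offset_sd`), scale ~ exp N(0, `site_scale_sd`) (defaults 0.5,
   0.2), drawn once per site. Offsets/scales leave voxel-level correlations
   invariant but perturb supervoxel aggregation weights per site, and move
   raw feature scales strongly — which is what within-site standardization
   must absorb.
4. patient scales: latent = Σ_L w_L (r̄_L − μ_L) + N(0, `scale_noise_sd`),
   where r̄_L is the subject's mean planted-link correlation across runs
   (computed on the latent series, i.e. upstream of scanner distortion) and
   μ_L the patient-group expectation; binned into 6 equal-width levels over
   ±3 theoretical SDs of the latent (monotone, so Spearman-based recovery is
   well-posed; a zero-width latent maps everyone to the mid score 3). All 9
   scales share the systematic part with independent noise draws, emulating
   a battery of correlated symptom ratings.

**Why subject-level heterogeneity.** Without `subject_corr_sd`, every patient
shares one covariance matrix, so scales generated from empirical link weights
vary only through sampling noise of r̂; run-level predictions could then
correlate with the subject-level scale at most √((σ_e²/4)/σ_e²) = 0.5, and no
regression method could recover the scale well. Between-subject variability
in functional connectivity comparable to or exceeding group effects is also
the realistic regime.

**What the generator does not emulate** — and hence what passing tests do not
establish about real data: no hemodynamic forward model, autocorrelated BOLD
noise, motion, scanner noise spectra, irregular brain masks, spatial
smoothness, or site-by-diagnosis interactions. Recovery results show the
*pipeline machinery* is correct and calibrated, not that real effect sizes
are detectable at these sample sizes.

Determinism: the full cohort is a pure function of `SyntheticConfig`
including its seed (per-site and per-subject child seeds are spawned from a
root `SeedSequence`).

## Problem sizes in the test suite and acceptance script

Chosen as the smallest sizes at which the statistical claims are stable:
null calibration on 2 sites × 20 + 20 subjects with 351 link features
(12×12×9 grid, 4×4×3 blocks); planted-link recovery over 20 seeds at 40
subjects, δr = 0.3, T = 137; double-dipping on 30 subjects × 6000 noise
features over 20 seeds; noiseless-scale recovery at 40 patients, T = 300,
`subject_corr_sd` = 0.2 on raw link weights (the low-noise regime for a
recovery test); the full study layout (95 subjects, 380 runs) is exercised
for design counts with short runs (T = 12). The complete suite and the
acceptance script each run in well under five minutes on one CPU.

## Known limitations

* The run-level testing treats correlated rows as exchangeable; inference at
  the subject level (e.g. mixed models) is out of scope by design — the
  stability machinery is the intended mitigation.
* The λ₁ bisection assumes monotone support along the path; rare multi-step
  jumps can make the achieved support smaller than the largest feasible one.
* KS normality QC is conservative with estimated parameters (no Lilliefors
  table correction is applied).
* The NIfTI I/O path stores synthetic grids with an identity affine; no
  template registration or atlas labeling is provided.
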