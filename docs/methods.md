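# Methods

This note documents what `thalnet` computes, the assumptions behind each
stage, the defaults and why they were chosen, what the synthetic cohort
does and does not emulate, and known limitations.

## Pipeline order

Fixed: batch harmonization → eTIV adjustment (volumes only) → graph
metrics (connectivity) → control-referenced age/sex GLM → hemisphere-wise
Z → ipsi/contra relabeling → group statistics.  Harmonization precedes
everything because scanner effects contaminate both the volume features and
the edge weights that the graph statistic integrates; graph metrics are
computed from harmonized matrices.  `normalize.StagedTable` enforces the
order mechanically.

## Graph construction and node-strength AUC

* **Backbone.** 122 nodes are first connected with 121 edges — a maximum
  spanning tree on |r|.  121 edges on 122 nodes force a spanning tree, and
  the max-|r| tree is the canonical connected backbone; it guarantees every
  thresholded graph is connected.
* **Density sweep.** Remaining node pairs are appended in descending |r|
  with ties broken by ascending (i, j) label order for determinism;
  negative and positive correlations of equal magnitude share a rank and
  keep their sign.  Graphs are materialized at ρ = .05….50 in .01 steps;
  the retained edge count at ρ is round-half-away-from-zero of ρ·7381,
  never below 121.  Rounding (rather than flooring) was chosen as the
  deterministic, monotone option; at ρ=.05 it yields 369 edges.
* **Strength.** Signed sum of retained incident edge weights (the standard
  strengths convention for signed graphs); an absolute-value variant is
  available behind `signed=False`.  Negative edges therefore subtract.
* **AUC.** Trapezoid on the density axis; a constant curve c integrates to
  0.45·c, which the tests use as a closed form.

## ComBat harmonization

Parametric empirical-Bayes location/scale model per feature: batch
locations shrunk toward a normal prior, batch variance ratios toward an
inverse-gamma prior, hyperparameters by method of moments, iterative joint
solution.  Covariates preserved during harmonization: age, sex, and a
patient indicator — the scanner upgrade is confounded with diagnosis
(patients only on the newer system), so omitting the group indicator would
scrub biological signal.  Zero-variance features pass through with a
warning.  Connectivity matrices are harmonized on their 7381 upper-triangle
edges and re-symmetrized; values outside (−1, 1) would be reported, not
clipped.

Two properties worth noting:

* Harmonization is idempotent only *in law*: refitting on harmonized data
  estimates residual batch moments at sampling-noise scale, so a second
  pass moves values by ~1e-3–1e-2 relative at n ≈ 400, not by 1e-6.  The
  tests assert the realistic bound.
* The between-batch variance-fraction diagnostic partials out preserved
  covariates before comparing pre/post, otherwise an age effect with
  imperfect batch balance is wrongly counted as scanner variance.

## Normative scoring

* eTIV adjustment by the residual method (regress on eTIV in controls,
  subtract the predicted component everywhere); the ratio method exists
  behind a switch.  Residual is the standard choice in volumetrics because
  it does not assume strict proportionality.
* The age/sex GLM is fitted on **controls only** and applied to everyone
  (W-score convention): fitting on the pooled sample would absorb disease
  effects into the normative model.  A pooled mode exists behind a switch.
  Age is linear, sex a binary indicator — the minimal GLM basis; a
  pediatric cohort spanning 4–18 years may in truth need nonlinear growth
  terms (out of scope, see Limitations).
* Z is computed strictly within hemisphere-matched features (right-sided
  values scored against right-sided control residuals), then patients are
  relabeled ipsi/contra through their focus side; controls keep L/R and
  never enter ipsi/contra tables.

## Statistical battery

* **Mixed ANOVA.** Within-subject effects via the multivariate approach:
  responses projected on difference contrasts (Kronecker products for
  factorial within designs), multivariate linear hypothesis with
  effect-coded between factor (so the within main effect tests the
  unweighted grand mean, the Type-III convention).  **Pillai's trace is the
  reported statistic**, with Wilks' Λ/Rao's F emitted side by side: the two
  coincide whenever the hypothesis has one degree of freedom, and the
  error-df convention of the reported repeated-measures tables
  ((7, 198) at N=206; (6, 264) for the 3-group × 4-nuclei interaction at
  N=136) matches Pillai exactly, Wilks only approximately (262).
  Between-subject effects use the univariate ANOVA on subject means.
  Partial η² = F·df₁/(F·df₁+df₂) throughout.  The implementation is
  cross-checked in the tests against pingouin (exact agreement on balanced
  2-level designs) and statsmodels MANOVA (exact Pillai/Wilks agreement).
* **Planned tests.** One-sample t of patient Z against zero (the control
  mean), paired t for ipsi vs contra, pooled-variance independent t for
  edgewise maps (Welch behind a switch).  Cohen d is reported as a
  magnitude, the sign carried by the mean.  A degenerate sample exactly at
  the null value returns t=0, p=1 instead of erroring.
* **Bonferroni families.** Defaults m=8 for the one-sample family
  (4 subdivisions × 2 lateralities per measure per group) and m=4 for the
  paired family (4 subdivisions), both config-overridable.  These family
  sizes were inferred by back-calculation from published corrected p-values
  against the printed t statistics; they reproduce the printed corrected
  values within rounding (|Δ| ≤ .005, the slack implied by independently
  rounded t and p).
* **Correlations.** Pearson r with Bonferroni family m=8 by default
  (nuclei × laterality pairs per subgroup); the family is overridable since
  the original correction family is not stated.

### Calibration caveat: one-sample tests against a finite normative sample

The one-sample t on control-referenced Z-scores treats the normative
prediction as exact.  With n₍ctrl₎ controls and n₍pat₎ patients, the shared
estimation error of the control reference inflates Var(mean patient Z) by
≈ 1 + n₍pat₎/n₍ctrl₎; at 70 controls and 136 patients that triples the
variance of the group mean and the nominal 5% test rejects ~24% of true
nulls.  This is a property of the testing convention itself (which the
pipeline reproduces faithfully), not of the implementation.  The null
calibration check therefore verifies the 5% ± 2% property with a large
control reference (n=2000), where the convention is well calibrated; users
comparing small cohorts to small control groups should interpret the
one-sample family accordingly (the paired and ANOVA families are not
affected, as they carry no shared reference error).

## Synthetic cohort generator

The generator defines the study conditions; its defaults are the published
cohort structure and headline effect sizes.

* **Demographics.** Group sizes 81/36/19/70; per-group age means/SDs
  (13.1±3.0, 11.8±3.2, 13.2±3.1, 13.4±3.1), truncated to the pediatric
  range [4, 18]; sex, focus-side, HS, FBTCS, status-epilepticus, etiology
  and surgical-outcome fractions taken from the published per-group counts;
  epilepsy duration per-group normal (6.5±4.1 / 5.8±3.8 / 7.6±4.0 years),
  capped below age.  eTIV ~ N(1.4·10⁶, 1.2·10⁵) mm³.
* **Volumes.** Control means per subdivision and hemisphere (anterior 140,
  lateral 2400, medial 1100, pulvinar 1700 mm³; left 2% larger) scale with
  eTIV and carry a 1%/year age slope and 2% male offset (targets for the
  adjustment stages), plus Gaussian noise with CV 8%.  45% of the noise
  variance is a subject-level factor shared across all 8 features — nuclei
  volumes co-vary strongly in real anatomy beyond eTIV, and without this
  correlation the repeated-measures interaction effect sizes implied by the
  published per-nucleus means are not attainable.  Planted group effects
  are expressed in Cohen d of the downstream Z-score and converted to mm³
  through the known noise SD; laterality is mapped through each subject's
  focus side.  A planted duration association (r=−.29 on ipsilateral
  lateral volume in acquired etiologies) uses the closed-form slope
  β = r/(σ_d·√(1−r²)).
* **Connectivity.** Matrices are generated in Fisher-z space (population
  mean + symmetric N(0, 0.1) subject noise) and back-transformed with tanh,
  so entries lie in (−1, 1) by construction.  The population mean matrix is
  **synthetic**: a block structure with subdivision-specific cortical
  partners (anterior↔amygdala/hippocampus/temporal/frontal,
  pulvinar↔mesial-temporal/occipital/precuneus with weak frontal edges,
  lateral↔inferior-frontal/insula/fusiform/sensorimotor,
  medial↔insula/amygdala/accumbens), homotopic and thalamo-thalamic edges
  strong, plus a small fixed jitter to break rank ties.  It is not an
  empirical group average.
* **Planted strength effects.** Realized as uniform shifts on all edges
  incident to the target node in z-space.  Because thresholding makes the
  AUC response nonlinear in the shift (shifted edges also change rank), the
  shift is calibrated by a deterministic internal Monte-Carlo, seeded from
  the cohort seed: the control AUC SD is estimated from 60 control-like
  matrices and the AUC sensitivity by finite differences in that ensemble,
  evaluated at the operating shift magnitude with one fixed-point
  refinement.  Recovery is unbiased to within ~±0.05 d averaged over seeds.
* **Batch effects.** Injected into the designated batch by scaling
  deviations around the batch's own mean (so means move by exactly the
  offset and SDs by exactly the scale): volumes +0.5 noise-SD and ×1.2,
  edges +0.05 r and ×1.2 by default; controls sit on the 1.5T batch, ~24%
  of patients on 3T, mirroring the scanner-upgrade confound.

What the generator does **not** emulate: fMRI time series, motion or
physiological noise, spatial autocorrelation of edge noise (edges are
independent given the mean), non-Gaussian volume distributions, missing
data, and lesion-driven parcellation failures.  Passing tests therefore
demonstrate the pipeline's correctness and sensitivity under a faithful
statistical emulation, not robustness to raw-imaging artifacts.

## Numerical choices

* Density-rank ties broken by ascending (i, j); MST computed on |r| via
  sparse Kruskal with all-negative shifted weights so zero-weight edges
  remain explicit.
* EB iterations converge at 1e-8 relative change (cap 500).
* Degenerate inputs: zero-variance features pass through harmonization with
  a warning; a planted volume effect that would produce a non-positive
  volume raises an error naming the subject and feature; symmetric-matrix
  and finiteness violations are rejected at entry.
* Determinism: all randomness flows through per-stage child seeds of the
  cohort seed; rerunning a pipeline with the same config yields
  byte-identical statistical tables.
* Problem sizes: recovery checks use 20 independent cohorts at the full
  published sizes; null calibration uses 1000 features / 1000 ANOVA runs at
  N=40; harmonization scenarios use 600 subjects × 60 features with noise
  SD 0.25 so the planted +0.1 offset is a resolvable (0.4 SD) scanner
  effect.

## Limitations

* The atlas's 114 non-thalamic labels are a Harvard-Oxford-style stand-in
  with the correct cardinality and hemisphere structure, not the original
  parcellation list.
* The normative model is linear in age; pediatric growth curves are not.
* The one-sample family inherits the finite-normative-sample
  anticonservatism described above.
* No non-parametric or GAM ComBat variants; no linear mixed-effects or
  permutation inference; no figure rendering.
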