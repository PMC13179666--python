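# thalnet

Thalamic functional-connectivity and volume analysis for pediatric focal
epilepsy cohorts.

## The problem

Children with focal epilepsy (temporal lobe, TLE; frontal lobe, FLE;
posterior quadrant, PQE) show alterations of the thalamus that are specific
to thalamic subdivision (anterior, lateral, medial, pulvinar) and to the
side of the seizure focus.  Quantifying this requires a chain of
well-defined steps: scanner-batch harmonization of features acquired on
different MRI systems, intracranial-volume adjustment of THOMAS-style
nuclei volumes, graph construction from whole-brain Pearson correlation
matrices with a hubness statistic per thalamic node, normative Z-scoring
against a control group, relabeling of hemispheres as ipsi/contralateral to
the seizure focus, and a repeated-measures statistical battery.

`thalnet` implements that chain as a tested, reusable pipeline.  Because
patient imaging cannot be shared, the package ships a first-class
**synthetic cohort generator** that reproduces the cohort structure of the
motivating study (81 TLE / 36 FLE / 19 PQE / 70 controls) with planted,
ground-truth-recorded effects, so every stage is verifiable end to end.

## The core statistic

For a 122-region connectivity matrix *R* (8 thalamic subdivisions + 114
Harvard-Oxford-style regions), a connected backbone is built as the maximum
spanning tree on |r| (121 edges), and edges are added in descending |r|
(sign retained; −.5 ranks with +.5) to form nested graphs at densities
ρ = .05, .06, …, .50.  Node strength is the signed sum of a node's retained
edge weights,

&nbsp;&nbsp;&nbsp;&nbsp;*s<sub>i</sub>*(ρ) = Σ<sub>j∈E(ρ)</sub> *w<sub>ij</sub>*,

and the per-node summary is the trapezoidal area under the curve,
AUC = ∫ *s<sub>i</sub>*(ρ) dρ over [.05, .50].  AUCs (and volumes, after
eTIV adjustment) are ComBat-harmonized, adjusted for age and sex with a
control-fitted GLM, Z-scored per hemisphere against the control residual
SD (W-score convention), and relabeled ipsi/contra to the focus.  Group
inference uses mixed repeated-measures ANOVAs (multivariate approach;
Pillai's trace reported, Wilks' Λ alongside, partial η² =
F·df₁/(F·df₁+df₂)), planned one-sample/paired *t*-tests with Cohen *d* and
Bonferroni correction, Pearson correlations, and edgewise *t*-maps.

## Worked example

```bash
python analysis/01_simulate_cohort.py   # cohort + ground truth
python analysis/02_run_pipeline.py      # full pipeline + stats battery
python analysis/03_effect_recovery.py   # planted-vs-recovered effect sizes
```

`02_run_pipeline.py` prints, among others (seed 1):

```
     measure           effect     F  df1   df2     p  partial_eta_sq
      volume nucleus x cohort 7.086  7.0 198.0 0.000           0.200
strength_auc           cohort 8.167  1.0 204.0 0.005           0.038

     measure  nucleus laterality   mean    sd      t  p_corrected  cohen_d
strength_auc pulvinar       ipsi -0.508 1.072 -5.529        0.000    0.474
      volume anterior       ipsi -0.443 1.063 -4.865        0.000    0.417
```

Reading: on this synthetic cohort the pipeline finds the planted pattern —
a nucleus-specific volume alteration (volume nucleus × group interaction,
partial η² = .20), an overall reduction of thalamic node strength in
patients (group main effect), and the strongest single deficits in
ipsilateral pulvinar strength and ipsilateral anterior volume, each around
half a control SD.  `03_effect_recovery.py` compares such estimates with
the planted Cohen *d* values over several seeds.

The CLI exposes the same functionality (`thalnet simulate|run|validate|stats`,
with `--config config.yaml --seed N --out DIR`).

## Layout

```
src/thalnet/        atlas, cohort (synthetic generator), harmonize (ComBat),
                    network (density graphs, strength AUC), normalize
                    (eTIV, normative GLM, Z, laterality), stats (ANOVA,
                    t-tests, correlations, edge maps), pipeline, cli
analysis/           numbered narrative drivers writing under results/
tests/              unit, property, and acceptance suites
docs/methods.md     model, assumptions, parameter choices, limitations
```
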