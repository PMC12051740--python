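# mechspheroid

Mechano-phenotyping of multicellular spheroids from Brillouin-microscopy
shift maps: synthetic cohort simulation, segmentation, morphological and
mechanical feature extraction, core/periphery zonal statistics, and a
classification study quantifying how much mechanical features improve
normal-vs-cancer discrimination.

## The problem

Confocal Brillouin microscopy maps stiffness without contact: the
frequency shift of inelastically scattered light,

    omega_B = (2 n / lambda) * sqrt(M' / rho) * sin(theta / 2),

grows with the elastic longitudinal modulus `M'`, so a scanned 2D image
of shifts (GHz) is a mechanical image of the sample. For breast-epithelium
spheroids grown in 3D culture (non-tumorigenic MCF10A "normal" vs
metastatic MCF10CA1h "cancer" lines), the mechanical image carries
structure that bright-field morphology misses: normal spheroids stiffen
steadily from Day 2 to Day 8 while cancerous ones stiffen and then
soften; the core (inner 40% of the radius) is stiffer than the
periphery; heterogeneity (SD of shift) and the negative tail of the shift
histogram (skewness, `S_k = m3 / m2^{3/2}` with biased central moments)
concentrate in the periphery, less so for cancer.

This package implements that analysis as a reproducible pipeline for
anyone working with per-pixel elastography maps of cell aggregates. The
raw images of the original assay are not publicly deposited, so a
seeded synthetic-cohort generator with full ground truth stands in for
them and doubles as the validation harness.

## What it computes

Per spheroid (one row of the features table):

| group | features |
|---|---|
| morphological | projection area (um^2), circularity `4*pi*A/P^2`, solidity, aspect ratio, C.V. of convex-hull radii |
| mechanical | mean shift (GHz), SD of shift (GHz), skewness |
| zonal | mean/SD/skewness for core and periphery separately |

Downstream: Welch t-tests (normal vs cancer per day), one-way ANOVA with
Tukey HSD (across days within a line), mean +/- SEM summary tables and
panel plots, and a repeated nested cross-validation study (100 runs x
stratified 10 folds = 1000 RBF-SVM models per experiment, grid-searched
on inner folds) comparing morphology-only against morphology+mechanics
feature sets.

## Worked example

```python
from mechspheroid import (CohortSpec, ExperimentConfig, extract_features,
                          generate_cohort, run_experiment, welch_t_test)

# simulate a Day-8 cohort at the published size and extract all features
spec = CohortSpec(n_normal=83, n_cancer=85, days=(8,), seed=20240601)
features = extract_features(generate_cohort(spec).spheroids)

normal = features[features.line == "normal"]
cancer = features[features.line == "cancer"]
print(f"mean shift  normal {normal.mean_shift.mean():.3f} GHz"
      f"  cancer {cancer.mean_shift.mean():.3f} GHz"
      f"  Welch p = {welch_t_test(normal.mean_shift, cancer.mean_shift).p:.2e}")

for feature_set in ("morphology_only", "combined"):
    cfg = ExperimentConfig(feature_set=feature_set, n_runs=10, seed=0)
    r = run_experiment(features, cfg, day=8)
    print(f"{feature_set:16s} accuracy {r.mean_accuracy:.3f} "
          f"+/- {r.sem_accuracy:.4f} ({r.n_models} models)")
```

prints

```
mean shift  normal 5.312 GHz  cancer 5.192 GHz  Welch p = 4.44e-56
morphology_only  accuracy 0.812 +/- 0.0092 (100 models)
combined         accuracy 0.994 +/- 0.0018 (100 models)
```

The 0.12 GHz group gap is the simulated Day-8 stiffness contrast; adding
the three mechanical features lifts held-out accuracy by ~18 percentage
points over shape alone, the package's analogue of the reported
morphology-to-combined improvement.

## Command line

```sh
mechspheroid pipeline --config config.yaml --out results/ --seed 1
```

runs simulate -> extract -> classify -> report end to end (each stage is
also its own subcommand); one seed controls everything downstream and a
rerun with the same config is byte-identical. Maps travel as float32
TIFF (or CSV grids) with a manifest CSV; all thresholds, fractions and
grids live in the YAML config.

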