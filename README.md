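# hyperfc — brain functional hypernetwork construction and classification

`hyperfc` builds **hypernetworks** from resting-state fMRI ROI time series
and classifies two cohorts (e.g. patients vs. controls) from hypergraph
features. A conventional functional connectivity network links pairs of
regions; a hypernetwork lets one hyperedge connect any number of regions,
so it can express higher-order interactions among brain areas. The package
is aimed at researchers studying functional connectivity who want a fully
scriptable, reproducible implementation of the sparse-regression
hypernetwork pipeline, including a synthetic cohort generator so every
stage can be exercised without access-restricted clinical data.

## Method

For subject *n* and centroid region *m*, the region's time series
x<sub>m</sub> is modelled as a sparse linear combination of all other
regions' series (the centroid's own column of the design matrix A is set
to zero):

    min_α  ½‖x − Aα‖₂² + penalty(α)

with one of three penalties:

| method  | penalty | selection behaviour |
|---------|---------|---------------------|
| lasso   | λ‖α‖₁ | individual regions |
| gLasso  | β Σ_g ‖α_g‖₂ | whole predefined ROI groups |
| sgLasso | λ₁‖α‖₁ + λ₂ Σ_g ‖α_g‖₂ | groups *and* regions within groups |

Regularization strengths are ratios of λ_max (the smallest penalty giving
the all-zero solution), so ratio 1.0 is always the empty model. The
support of each solution plus the centroid forms one hyperedge; sweeping
the ratio over 0.1…0.9 for every centroid gives a binary incidence matrix
H(v, e) of shape n_rois × (n_rois·9) — 90 × 810 at the standard 90-region
atlas. Node degree d(v) and edge degree δ(e) are its row and column sums.
ROI groups for the group penalties come from k-medoids clustering of the
1 − r correlation distance with distance-proportional (k-means++-style)
seeding and restarts.

From each subject's hypergraph the package extracts three single-node
clustering coefficients (HCC¹–³) and five pairwise "mutual" clustering
coefficients (COMHCC¹–⁵, node-averaged), i.e. 270 + 450 attributes at 90
regions. Features differing between cohorts are selected by two-sample
Kolmogorov–Smirnov tests with Benjamini–Hochberg FDR control (q = 0.05,
the two families corrected separately). The two selected families each
yield a centered linear kernel over subjects; their convex combination
a₁k₁ + a₂k₂ (a₁ + a₂ = 1, grid-searched in steps of 0.1) feeds an SVM with
a precomputed kernel, evaluated by leave-one-out cross-validation.
Reported metrics are accuracy, sensitivity, specificity and BAC
(balanced accuracy, the mean of sensitivity and specificity), in percent.

## Worked example

Simulate a two-cohort dataset (30 ROIs in six correlation blocks; one
block decorrelated in cohort B), build sgLasso hypernetworks, extract and
select features, and classify:

```python
import json
import hyperfc as h

cfg = h.PipelineConfig(
    method="sglasso", k=6,
    cohort=h.CohortConfig(
        n_rois=30, n_timepoints=60, n_subjects_a=10, n_subjects_b=10,
        group_sizes=(5,) * 6, within_r=0.4, between_r=0.05,
        perturbed_blocks={0}, perturbed_within_r=0.15, seed=7),
    grid=h.LambdaGrid(ratios=(0.1, 0.3, 0.5, 0.7, 0.9)),
    seed=7, out_dir="example_run")
result = h.run_pipeline(cfg)
print(json.dumps(result["classification"], indent=2))
```

prints

```json
{
  "accuracy": 85.0,
  "sensitivity": 100.0,
  "specificity": 70.0,
  "bac": 85.0,
  "best_weights": [0.015, 0.985],
  "accuracy_sd": 0.0
}
```

Every cohort-B subject is recognized (sensitivity 100%), 7 of 10 controls
are (specificity 70%), and the inner weight search leans almost entirely
on the pairwise-coefficient kernel (a₂ ≈ 0.985). The run directory also
receives the ROI grouping, per-subject incidence matrices, the feature
table (31 selected single-node and 75 pairwise features in this run), the
per-feature selection tables and a provenance file; rerunning with the
same config reproduces all artifacts bit for bit.

The same pipeline is available from the shell:

```sh
hyperfc simulate --seed 7 --out data/
hyperfc run --manifest data/manifest.tsv --method sglasso --k 30 \
    --lambda-grid 0.1:0.9:0.1 --seed 7 --out run/
hyperfc compare --manifest data/manifest.tsv --k 30 --seed 7 --out cmp/
```

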