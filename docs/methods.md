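# Methods

## Overview

`hyperfc` implements a hypergraph ("hypernetwork") model of resting-state
brain functional connectivity and a two-cohort classification pipeline on
top of it. A conventional functional network connects pairs of regions; a
hypernetwork lets one hyperedge connect any number of regions, capturing
higher-order interactions. The pipeline has five stages:

1. **Hyperedge construction by sparse regression.** For subject *n* and
   centroid region *m*, the region's time series x is regressed on the
   matrix A of all other regions' series (the centroid's own column is set
   to zero). The support of the penalized solution α, together with the
   centroid, is one hyperedge. Three penalties are supported:
   * lasso — λ‖α‖₁,
   * group lasso (gLasso) — β Σ_g ‖α_g‖₂ over a predefined ROI partition,
   * sparse group lasso (sgLasso) — λ₁‖α‖₁ + λ₂ Σ_g ‖α_g‖₂, performing
     bi-level selection (groups, and variables within groups).
2. **Multi-level regularization.** The sparsity level is expressed as a
   ratio of λ_max, the smallest penalty at which the solution is identically
   zero, so a ratio of 1.0 is always the empty model. Each centroid is
   solved over the ratio grid 0.1, 0.2, …, 0.9; for sgLasso the group
   ratio is held fixed (default 0.4) while the l1 ratio sweeps the grid.
   With 90 regions and 9 levels the subject's incidence matrix is 90 × 810.
3. **Feature extraction.** Three single-node hypergraph clustering
   coefficients (HCC1–3) and five pairwise "mutual" coefficients
   (COMHCC1–5, node-averaged over neighbors) per region: 270 + 450
   attributes per subject at 90 regions. Definitions are in the
   `hyperfc.metrics` module docstring.
4. **Feature selection.** Two-sample Kolmogorov–Smirnov tests per feature
   column between cohorts, Benjamini–Hochberg FDR at q = 0.05, applied to
   the two feature families separately.
5. **Classification.** One centered linear kernel per family, convex
   combination k = a₁k₁ + a₂k₂ (weights on a 0.1-step grid), SVM with a
   precomputed kernel, leave-one-out cross-validation; accuracy,
   sensitivity, specificity and balanced accuracy (BAC, the mean of
   sensitivity and specificity) are reported in percent.

## Solver

The internal objective is (1/2)‖x − Aα‖₂² + penalty. The squared,
half-scaled loss is the differentiable convention required by proximal
gradient methods and the one under which the closed-form λ_max expressions
hold: λ_max = max_j |A_jᵀx| for the l1 term and max_g ‖A_gᵀx‖₂ for the
unweighted group term. For sgLasso the two ratios scale their respective
λ_max values independently, which is what makes "fix the group ratio,
sweep the l1 ratio" well defined; either ratio at 1.0 yields the zero
solution. Group norms carry no √(group size) weight.

Optimization is FISTA with adaptive restart on objective increase. The
proximal operator of the mixed penalty over non-overlapping groups is soft
thresholding followed by per-group shrinkage, which is exact. The gradient
is computed in Gram form (G = AᵀA, b = Aᵀx), and the step size is 1/L with
L the largest eigenvalue of G obtained by direct symmetric
eigendecomposition — exact and cheap at M ≤ a few hundred columns, with no
iteration tolerance of its own. Convergence is declared when the relative
objective change drops below `tolerance` (default 1e−7, relative to
max(|f|, 1)); `max_iterations` defaults to 5000 and non-convergent solves
return the best iterate with a warning. Coefficients below
`zero_threshold` (default 1e−8) are truncated to exact zeros before the
support is read off, and the centroid coefficient is forced to zero so
numerical noise can never create a self-loop.

Design columns and the response are z-scored per solve (the centroid's
zero column is left alone), which makes penalty ratios comparable across
centroids; the method itself leaves the scaling open and this is the
package's choice.

## ROI grouping

gLasso and sgLasso need a partition of regions. Pairwise similarity is the
Pearson correlation of region time series, turned into the distance 1 − r
(not 1 − |r|: larger correlation means more similar; an absolute-value
variant can be computed by passing transformed data). One shared partition
per dataset is computed from the mean-centered subject series concatenated
along time. k-medoids is run from k-means++-style seeds where each
successive seed is drawn with probability proportional to its distance to
the nearest existing seed (distance itself, not squared distance); the
clustering is restarted 10 times by default and the lowest-cost result
kept, ties broken by earliest restart. Medoid updates break ties toward
the smallest region index so that runs are deterministic given the seed.
Default k is 30 (the value reported to classify best with sgLasso); 48 is
the analogous gLasso value. Both are configuration, not constants.

## Hypergraph assembly and degenerate edges

Columns are ordered centroid-major, ratio-ascending, so features align
across subjects. All-zero solutions still produce (singleton) hyperedge
columns and duplicate supports at adjacent ratios are kept, preserving the
fixed n_rois × (n_rois·n_ratios) shape. The edge-degree distribution is
reported over bins 2–7, 8–13, 14–19, 20+ with edges of degree < 2 excluded
from the denominator (a singleton edge carries no connectivity); the raw
histogram including singletons is also returned.

## Clustering-coefficient conventions

* The HCC3 numerator is read as 2·(Σ_{e∈S(v)}(|e|−1) − |N(v)|): the sum
  counts neighbor slots with multiplicity, subtracting the number of
  distinct neighbors isolates the overlap among v's incident edges, and
  the value is 0 for non-overlapping incident edges. The alternative
  grouping (2·Σ(|e|−1) − |N(v)|) does not vanish there.
* The "facilitated" indicator of HCC2 means a single hyperedge containing
  u, t and v simultaneously.
* COMHCC5 uses the natural logarithm of the hypergeometric upper-tail
  probability of the observed overlap of incident-edge sets, with the
  population equal to the total number of hyperedges in the subject's
  hypergraph (the population the incident-edge sets are drawn from); the
  probability is clamped to [1e−300, 1] before the log.
* Every divide-by-zero guard (isolated node, single incident edge, empty
  neighborhood) returns 0 so that feature matrices stay finite.
* S(v) is a set of edge IDs: duplicate incidence columns count as distinct
  edges.

## Feature selection

The standalone `select_features` defaults to seeded label-permutation
p-values for the KS statistic (10,000 permutations, add-one rule so p ≥
1/(B+1)); permutations are shared across features within a draw, which
preserves the feature correlation structure. The fast mode delegates
p-values to scipy's two-sample KS with its auto policy — the exact
small-sample distribution at the cohort sizes used here, the asymptotic
tail at large n. The asymptotic tail alone is anti-conservative below
roughly 10 subjects per group and would break FDR control. Inside
cross-validation the fast mode is the default, since permutation p-values
per training fold would multiply the statistic count by the fold count
times the permutation count. The two families (single-node, pairwise) are
corrected separately; this matches treating them as two hypothesis
families fused only at the kernel level.

## Classification

The base kernel is linear on z-scored selected features (the minimal
assumption; an RBF variant can be built by substituting the kernel
function). Per LOO fold, feature selection (nested by default), z-scoring
and kernel centering all use training-fold statistics only; the held-out
subject's kernel row is centered with training means. Kernel weights are
chosen by inner LOO accuracy on the training fold; a post-hoc
`weight_mode="outer"` instead picks the weight with the best outer LOO
accuracy, which is optimistically biased and off by default. The SVM cost
is 1 by default. When a training fold selects nothing at q in a family,
nested CV falls back to that family's `min_features_per_family` (default
1) smallest-p features rather than aborting the whole run; with global
selection scope an empty family raises the documented
`NoSignificantFeaturesError`. Repeats (`n_repeats`) re-draw the stochastic
seeds and report mean ± sd; the repeats that matter scientifically are the
pipeline-level ones that re-draw the clustering seed, since the k-means++
initialization is the dominant source of run-to-run variation.

Selection once on all subjects before CV (`selection_scope="global"`) and
outer-LOO weight selection replicate the common but leakage-prone protocol
of the field; the defaults avoid both leaks. The shared ROI partition is
computed once per dataset, not per fold — a known, documented leakage
caveat retained because a per-fold partition would change the feature
space across folds.

## Synthetic cohort generator

Each subject is a zero-mean multivariate Gaussian time series, i.i.d.
across time, with block-constant exchangeable ROI correlation: `within_r`
inside each block, `between_r` across blocks, unit variances. Cohort B
replaces `within_r` by `perturbed_within_r` in the configured blocks. The
default shape is 90 ROIs × 238 time points (mirroring a typical
resting-state acquisition of 248 volumes with the first 10 discarded),
with six blocks of 15 as a neutral default for the unknown true group
structure. Positive definiteness is verified by eigendecomposition at
construction, not assumed from parameter constraints. Per-subject seeds
are spawned deterministically from the cohort seed, so the whole cohort is
a pure function of its configuration.

What the generator does **not** emulate: temporal autocorrelation or
hemodynamics (the method consumes only linear relations among ROI rows),
subject-level heterogeneity of the covariance (all subjects in a cohort
share one covariance, so between-subject feature variability comes from
sampling noise alone), motion or physiological confounds, and site
effects. A consequence worth knowing: at long series and strong
within-block correlation the supports of the penalized regressions
stabilize, every subject's hypergraph becomes identical, and cohort
comparisons degenerate (all KS statistics 0 or 1). Validation experiments
therefore run at moderate correlation and short series (e.g. within 0.4,
60 time points), where subjects vary as real data does; passing them shows
the machinery recovers a planted group-level effect under sampling noise,
not that it would detect clinical effect sizes.

## Problem sizes used in the shipped experiments

The packaged validation experiments and the acceptance script run at a
reduced scale chosen to keep the whole suite runnable on a laptop core:
30 ROIs (six blocks of five), 60 time points, 10 + 10 subjects, five ratio
levels, 20 simulation repeats for the recovery experiment, 2000 simulated
null datasets (16 features, 8 + 8 subjects) for the FDR control check, and
30 permutation repeats for the null-accuracy check. The structural check
(90 × 810 incidence, 270 + 450 attributes) runs at full atlas scale, where
one subject's lasso hypernetwork takes on the order of a second.

## Known limitations

* The regression loss is the squared l2 norm; with an unsquared loss the
  λ_max identities and ratio semantics would differ.
* Group norms are unweighted; comparisons against √(group-size)-weighted
  implementations require rescaling per-group ratios.
* k-medoids optimizes total within-cluster distance greedily; it finds a
  local optimum per restart, which is why restarts are part of the
  protocol.
* LOO accuracy on permuted labels sits slightly below 50% (removing the
  test subject unbalances the training fold against its own class); the
  null-accuracy check accounts for this with the empirical spread over
  permutation repeats.
* The pipeline classifies; it does not estimate effect sizes or provide
  inference on individual connections.
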