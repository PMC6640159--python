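# Methods

This note documents the statistical procedures implemented in `mmstage`, the
defaults they ship with, and the design of the synthetic cohort generator
used to test them.

## Problem setting

The package stratifies multiple-myeloma patients undergoing autologous stem
cell transplantation (ASCT) into high- and low-risk groups from 39 routine
pre-transplant variables (23 numeric, 16 categorical), using two
right-censored endpoints: progression-free survival (PFS) and overall
survival (OS), both in months. It implements both an unsupervised risk
discovery pipeline and the published three-factor staging rule (relapse
after remission, response to induction, glomerular filtration rate).

## Univariate screen

Each numeric covariate is dichotomized at its exact one-dimensional
two-means cutoff: among all contiguous splits of the sorted values, the one
minimizing the within-cluster sum of squares (WCSS) is selected. In one
dimension the optimal 2-means partition is always contiguous in sorted
order, so an exhaustive scan over the n−1 splits (with prefix sums, O(n log
n) total) is exact — no Lloyd iterations, no initialization sensitivity.
Ties in WCSS are broken toward the more balanced split, then the lower
cutoff. The cutoff C defines groups `<= C` and `> C`.

Kaplan–Meier curves use the product-limit estimator (via lifelines); the
reported median is the smallest event time with S(t) <= 0.5, rendered
`> max follow-up` when the curve never reaches 0.5. Group contrasts use the
unweighted log-rank test; multi-level factors get the k-sample test plus
uncorrected pairwise tests.

## Stacked multivariate model

`RiskStratification.fit(seed)` runs, in order:

1. **Imputation** (if any covariate cell is missing) — chained equations:
   numeric columns by Bayesian ridge regression followed by predictive-mean
   matching (5 donors); categorical columns by multinomial logistic
   regression (most probable class); 10 sweeps after a mean/mode
   initialization. Predictors are z-scored inside the sweeps so the ridge
   and logistic penalties treat covariates evenly regardless of measurement
   scale. PMM copies observed donor values, so imputations stay in range
   and preserve each column's marginal variance (mean imputation, by
   contrast, shrinks it); note that a stochastic single imputation is not a
   minimum-RMSE point estimate and is not meant to be.
2. **Binarization** — 36 of the 39 covariates enter the stack (the
   induction-line count and the composite ISS/DSS stages are excluded).
   Numerics are dichotomized at their two-means cutoffs; categoricals are
   one-hot encoded, giving ~59 binary columns.
3. **Hamming distances** — the pairwise count of differing binary
   coordinates between patients.
4. **PCA at 95% eigen energy** — the distance matrix is projected onto the
   smallest set of leading principal components whose cumulative eigenvalue
   fraction reaches 0.95.
5. **Spectral clustering (k = 2)** — a Gaussian affinity over the component
   scores with bandwidth equal to the median pairwise distance, symmetric
   normalized Laplacian, and seeded k-means on the row-normalized leading
   eigenvectors. A symmetrized k-nearest-neighbour affinity is available
   behind `affinity="knn"`; the Gaussian kernel is the default because it
   is markedly more robust when the two groups are well separated (the
   k-NN graph can fragment a tight cluster into components), at a modest
   cost in the weak-signal regime. An off-the-shelf spectral clusterer with
   a fixed `gamma` was rejected empirically: with unit bandwidth it fails
   outright on well-separated binary profiles that the median-bandwidth
   kernel recovers perfectly.
6. **Risk labels** — the cluster with the smaller Kaplan–Meier median PFS
   is labelled high-risk (ties: lower mean observed time).
7. **Fast-and-frugal tree (FFT) induction** — cues are ranked by their best
   marginal balanced accuracy against the cluster labels (numeric cues over
   midpoint thresholds in both directions; categorical cues over level
   subsets); the top 6 then enter a branch-and-bound search over ordered
   cue subsets of depth <= 4, both directions and every exit structure
   (each non-final cue exits high or low; the final cue exits both ways).
   The admissible pruning bound assumes every still-undecided patient is
   classified correctly, so the search returns the same optimum as
   exhaustive enumeration; when the cue pool has at most 6 usable cues the
   search *is* exhaustive. Ties prefer shorter trees.
8. **Re-calibration** — one pass of the trained tree over the cohort; the
   tree's outputs become the final labels, and agreement with the cluster
   labels is reported as the training accuracy.

## Staging rule

The published rule is a three-cue FFT with fixed order: relapse after
remission (yes → high, exit), response to induction (outside {CR, VGPR} →
high, exit), and pre-transplant GFR against 85.6 mL/min/1.73 m² (final cue,
both exits). Only the relapse exit is textually unambiguous in the source
figure; the response and GFR directions follow the survival trends (poor
responders do worse; renal insufficiency is adverse, so GFR at or below the
threshold exits high) and the GFR direction is configurable
(`StagingRule(gfr_high_risk_below=False)`).

## Synthetic cohort generator

Real pre-transplant cohorts of this kind are private, so the generator
produces cohorts with the statistical structure the analysis assumes.

- **Latent structure** — each patient is high-risk with probability 0.34.
- **Survival** — PFS is Weibull (default shape 1, i.e. exponential) with
  per-group medians 24 (high) vs 91 (low) months; scale =
  median / ln2^(1/shape). OS = PFS + an independent Weibull tail whose
  scale is solved numerically (bracketed root-finding on the survival
  function of the sum, computed by quadrature) so that the *marginal* OS
  median of each group equals its configured value (51 / 135 months). A
  naive tail with median `os_median − pfs_median` would inflate the OS
  median of the sum to ~159 months. Administrative censoring at 150
  months; events after the horizon are censored at the horizon.
- **Covariates** — nine variables carry group-conditional distributions:
  relapse after remission (P(yes) 0.55 high / 0.12 low), response to
  induction (P(CR/VGPR) 0.35 / 0.70), and Gaussian shifts of roughly 1–1.4
  within-group standard deviations for albumin (3.2 vs 3.9 g/dL), residual
  and diagnostic M-protein, haemoglobin, beta-2-microglobulin and GFR (71
  vs 93 mL/min/1.73 m²), plus extramedullary disease (0.42 / 0.13) — the
  markers that differ between risk groups in real transplant cohorts. The
  remaining ~30 covariates are group-independent noise with plausible
  pre-transplant marginals. The breadth matters: in a binarized matrix of
  ~59 columns, a planted split carried by only two or three columns sits
  below the random-matrix detectability threshold (the leading sample
  eigenvector decouples from a weak planted signal), and no clustering
  method can recover it; spreading clinically plausible effect sizes across several
  correlated markers puts the structure above that edge, which is also how
  real cohorts behave. The GFR means are placed so that the cohort's own
  two-means cutoff lands at ≈85.6, consistent with the published staging
  threshold.
- **Missingness** — each covariate cell is masked independently with
  probability 0.05 (MCAR); identifiers, endpoints and the latent group are
  never masked.
- **Reproducibility** — all draws come from one `numpy` Generator seeded by
  the config; identical config + seed gives identical cohorts, and the
  pipeline manifest records SHA-256 checksums of every output.

### Known limits of the defaults

Measured over seeded default cohorts (n = 253):

- The two-group spectral split recovers the latent groups with mean ARI
  ≈ 0.3–0.4 against an information ceiling of ≈ 0.47 (the Bayes partition
  of the binarized profiles); the recalibrated groups separate at log-rank
  p < 0.001 in ≈ 74% of runs.
- Relapse after remission leads the induced tree in ≈ 64% of runs: under
  the default effect sizes albumin's marginal balanced accuracy (~0.76)
  slightly exceeds relapse's (~0.72), so the first cue alternates between
  the strongest markers.
- The staged low-risk gate is a three-way conjunction (~30% of patients),
  so single-cohort staging contrasts at n = 253 reach p < 0.05 in only
  ≈ 65% of runs, while the planted effect is unambiguous at n = 2000
  (p <= 1e-8).

## Verification

The test suite checks the implementation against independent naive oracles:
brute-force WCSS enumeration for the cutoff, a hand-coded product-limit
and textbook log-rank implementation (agreement within 1e-8), a
double-loop Hamming oracle, exhaustive enumeration of all fast-and-frugal
trees on small binary cue sets, planted-partition recovery (ARI >= 0.9) for
the spectral step, the full staging truth table, and byte-level manifest
reproducibility. `scripts/acceptance.py --seed <int> --out <path>` recomputes
the headline quantities and writes a JSON report (~10 minutes on one CPU;
the end-to-end batch runs 20 seeded cohorts).
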