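# Methods

## Problem setting

Group studies of brain networks compare small-world parameters — the number
of edges E, the clustering coefficient C and the characteristic path length L
— between two groups of subjects. When each subject contributes a full
connectivity matrix (EEG/MEG coherence, resting fMRI correlations, fibre
tracking), per-subject metrics form a genuine sample and ordinary two-sample
statistics apply. When each subject contributes only one scalar per region
(cortical thickness, FA), connectivity can only be formed on the *group*
level as the inter-subject correlation between regions, leaving exactly one
network per group and nothing to put into a t-test.

A widespread workaround — the **multiple-thresholds approach (MTA)** — is to
threshold each group network at m cutoffs and treat the m per-threshold
metric values as m "subjects" per group in an independent-samples t-test.
This package implements that procedure faithfully, together with the two
statistically sound alternatives (a group-level permutation test and the
per-subject route), and a simulation harness that measures what the MTA does
to the type-I error. The point of the package is methodological: thresholded
networks are nested — every edge surviving a high cutoff also survives every
lower cutoff — so the m values are strongly dependent pseudo-replications,
and m itself is an analyst choice that mechanically scales t while leaving
the standardized effect size untouched.

## Network metrics

Matrices are square, symmetric, zero-diagonal; correlations live in [−1, 1],
coherence in [0, 1]. Thresholding keeps edges with *signed* weight ≥ τ
(an absolute-value mode exists but is off by default; published threshold
grids are entirely positive). Thresholded matrices keep their weights;
binarization is an explicit flag, matching the practice of feeding
thresholded matrices to weighted-network software.

* **Edge count** — unordered node pairs with nonzero weight.
* **Clustering** — default is the weighted triplet formulation used by the
  tnet family of tools: C = (total triplet value of closed triplets) /
  (total triplet value of all triplets), where a triplet centred at i with
  neighbours j, k carries the arithmetic mean of w_ij and w_ik (geometric
  mean, max and min are selectable). With all weights 1 this is exactly
  binary transitivity. The Watts–Strogatz average-local variant (binary
  support, degree<2 nodes contributing 0) is provided as an alternative
  because both conventions circulate in the literature; the configuration
  used is embedded in every result so analyses are self-describing.
* **Path length** — weighted shortest paths minimise the summed edge cost
  (1/w)^α along paths (α = 1 by default, so strong connections are short);
  binary mode uses hop counts. L is the mean distance over unordered pairs.

**Disconnected graphs.** Sparse thresholded networks lose edges and then
whole components. Rather than committing to an infinite-distance convention,
the default policy averages L over *reachable* pairs and reports the
reachable fraction; a harmonic policy and a hard-error policy are available.
A network is **consistent** iff it has ≥1 edge and reachable fraction 1;
inconsistent networks are dropped (and listed) by the MTA pipeline and the
per-subject pipeline, mirroring the field's exclusion of networks that are
"no longer consistent" at extreme thresholds.

**Unthresholded weighted analyses.** A raw correlation matrix contains
negative entries, for which inverse-weight costs and triplet values are
undefined. In unthresholded mode the package drops non-positive edges — the
natural limit τ → 0⁺ of its signed thresholding rule. Because every
unthresholded network then has (essentially) the same support, the
edge-count comparison is meaningless and is omitted in this mode.

## Threshold grids

Published grids mix conventions, so grids are explicit objects recording
bounds, increment and convention. `closed_omit_top` divides [lower, upper]
into `count` steps and drops the top endpoint (the all-but-empty sparsest
network): 10 steps over 0.65–0.99 gives the increment 0.034. `half_open`
enumerates lower, lower+inc, … strictly below upper: 0.01 → 0.91 at 0.001
contains exactly 900 thresholds. `closed_inclusive` keeps both endpoints.
Grid parameters are echoed in every output because they change conclusions.

## Statistics

* **t-test** — two-sided Student with pooled variance, df = n₁ + n₂ − 2
  (25 and 34 subjects give df = 57); Welch's test behind a flag. Degenerate
  inputs are explicit: both samples constant and equal → t = 0, p = 1;
  zero pooled variance with unequal means → signed infinite t with a
  warning — this case genuinely occurs in the MTA (below).
* **Cohen's d** — (mean₁ − mean₂)/pooled SD; location-invariant and free of
  the sample-size dependence that makes MTA p-values manipulable, which is
  why it accompanies every test result.
* **Published MTA df.** Reports of the MTA sometimes subscript t with m − 2
  rather than the two-sample 2m − 2. No standard two-sample statistic on
  2m values has m − 2 degrees of freedom, so this package does not attempt
  to reproduce that convention; it reports the standard pooled df.
  (Per-subject analyses subscripted n₁ + n₂ − 2 are reproduced exactly.)
* **Permutation test** — Edgington-style Monte-Carlo randomisation: subjects
  are reassigned to groups (sizes preserved, sampling with replacement
  across relabelings), the group-level networks and metrics recomputed, and
  the observed difference located in the null difference distribution.
  Two-sided by default on |difference| (the directionless reading of
  "exceeds the extreme 5%"); one-sided modes available. The estimator uses
  the add-the-observed correction p = (1 + #{|null| ≥ |obs|})/(B + 1), so
  p ≥ 1/(B+1) (0.001 at B = 999) and ties count as exceedances
  (conservative). When the relabeling group has ≤ B elements it is
  enumerated exhaustively and p is the exact permutation p. A seed is
  mandatory; identical seed and inputs give bit-identical results. A sweep
  mode reuses one relabeling sequence across a whole grid so per-threshold
  results are comparable. Metrics undefined in more than 5% of permutations
  abort with a diagnostic; below that they are excluded and counted.
* **Regression** — per-subject metric on a continuous covariate by ordinary
  least squares with the usual two-sided slope test.

## Synthetic data

`generate_node_values` draws one independent standard-normal value per
region per subject — the null model for inter-subject correlation networks
(defaults: 84 regions, 30 subjects per group). `generate_subject_networks`
builds one correlation matrix per subject by correlating independent
standard-normal surrogate series across nodes (default length 100). How the
published artificial per-subject networks were generated is not specified
anywhere; surrogate-series correlation was chosen because it guarantees a
mathematically valid correlation matrix (symmetric, unit-bounded, positive
semidefinite) with a single interpretable knob — the series length sets the
off-diagonal spread to ≈ 1/√length. Neither generator attempts realistic
spatial correlation structure, coherence spectra or distance-dependent
connectivity: passing calibration/inflation results demonstrate statistical
properties of the *procedures* under a clean exchangeable null, not
performance on real EEG/MRI data.

Experiments derive per-replicate seeds as `SeedSequence([master, i])`, so
replicate i is re-runnable in isolation. Rejection rules: parametric tests
reject at p < α; the permutation test rejects at p ≤ α because its
attainable p-values are exactly k/(B+1) — with B = 199 and α = 0.05 the
null rejection probability is exactly 10/200.

## Type-I-error experiments and chosen problem sizes

`type1_error_experiment` repeatedly generates null datasets, applies one of
the three approaches, and reports per-metric rejection rates with
Clopper–Pearson 95% intervals. The shipped study sizes are:

* permutation calibration: 500 replicates, 2×15 subjects, 30 nodes, B = 199
  — measured rates sit at the nominal 0.05;
* MTA inflation: 200 replicates, 2×30 subjects, 84 regions, the dense range
  0.01–0.06 with m ∈ {10, 25, 50} — measured rates grow from a few percent
  at m = 10 to tens of percent at m = 50 for edge count and clustering,
  while mean |d| moves by only a few percent and mean |t| roughly doubles.

These sizes were chosen to estimate rates to within ~±2 percentage points
while keeping a full run in minutes on one CPU; the qualitative pattern is
insensitive to them.

**The path-length degeneracy.** In the dense range the weighted path length
is (near-)exactly constant across thresholds: the removed weak edges have
cost 1/w ≳ 16 and never lie on a shortest path. The within-group series
variance is then ~0 (or exactly 0) and the MTA t statistic is astronomically
large or infinite in every replicate — the degenerate extreme of treating
nested networks as independent samples. The inflation experiment reports
this as a rejection rate of 1.0 at every m; the effect-size-stability
analysis is restricted to the two metrics whose series carry real variance
(edge count, clustering). Notably, published low-range MTA results list
t-values only for edges and clustering.

## Numerical choices

* Symmetry tolerance 1e−8 on input matrices; diagonals stored as exactly 0
  and excluded from all statistics.
* Oracle tests require agreement with brute-force enumeration to 1e−10.
* Zero-variance nodes in inter-subject correlation get their correlations
  set to 0 with a warning (rather than NaN propagation).
* Shortest paths via Dijkstra on a sparse representation; distances
  symmetrized before averaging.
* Clustering values clipped to [0, 1] against last-bit float excursions.

## Limitations

* Only two-group designs; no ANOVA, no covariate-adjusted permutation
  schemes, no edge-wise/node-wise (network-based-statistic) inference.
* No small-world index against rewired reference graphs; no efficiency,
  betweenness or modularity measures.
* No reading of neuroimaging container formats (NIfTI, EDF); inputs are
  delimited text.
* The permutation test's p-value floor is 1/(B+1): B must be sized to the
  significance level sought.
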