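# Methods

This note documents the models, numerical choices and limitations behind
`slnet`: the synchronization-likelihood (SL) estimator, the graph metrics and
their surrogate normalization, the group statistics, and the synthetic cohort
generator used for validation.

## Synchronization likelihood

SL treats each regional series as observations of a dynamical system and
asks how often state-space pattern recurrences in one series coincide in
time with recurrences in another. The implementation:

1. **Embedding.** Time-delay embedding with lag `l` and dimension `m`
   produces `M = Tn − (m−1)·l` state vectors per series. Defaults `l = 1`,
   `m = 6` follow common practice for slow BOLD fluctuations sampled at
   TR ≈ 2.85 s.
2. **Candidates.** For time point `i`, recurrence candidates are the vectors
   `j` with `|i − j| > w` (Theiler window, default `w = 6`), removing
   temporally adjacent, autocorrelated samples. No upper time window is
   applied (a single stationary SL value per pair, not a time-resolved one).
3. **Critical distance.** ε<sub>i</sub> is the Euclidean distance of the
   `r`-th nearest candidate, `r = ⌈P_ref · n_candidates⌉` (default
   `P_ref = 0.01`). This rank statistic is deterministic and tie-tolerant,
   and makes SL exactly invariant under per-series affine rescaling — there
   is no radius bisection and no dependence on measurement units.
   A note on the baseline: because `r` is an integer, the realized
   recurrence fraction is `⌈P_ref·n⌉/n` rather than `P_ref` itself; at
   `Tn = 200` (n ≈ 182, r = 2) the independence baseline is ≈ 0.011.
   The discreteness bias shrinks with longer series.
4. **Coincidence counting.** Recurrences are counted with `d ≤ ε` (ties at ε
   all count). The conditional X→Y likelihood at `i` is the fraction of
   X-recurrences that are also Y-recurrences; SL is the average over `i` and
   over both conditional directions, clipped to [0, 1]. Identical series give
   exactly 1; independent series give ≈ P_ref.
5. **Degenerate input.** A constant series has all candidate distances zero
   and is rejected with an error naming the offending region.

The all-pairs matrix computation reuses each region's recurrence structure
(an M × M boolean matrix) so the R(R−1)/2 pairwise values are accumulated
with vectorized boolean algebra; a test asserts exact agreement with
independent per-pair calls, and with a naive double-loop reference on short
series. The matrix diagonal is fixed at 1 by convention and excluded from
the whole-brain mean S and from graph construction.

## Graphs and small-world metrics

* **Thresholding.** Fixed-T graphs use strict exceedance (`SL > T`).
  Fixed-K graphs keep the `round(N·K/2)` strongest off-diagonal pairs, with
  a deterministic tie-break (descending SL, then ascending lexicographic
  pair order), so two subjects binarized at the same K always carry the same
  edge count regardless of their mean SL level.
* **Clustering coefficient.** `C_v` is the fraction of a vertex's neighbor
  pairs that are themselves linked; vertices of degree < 2 contribute
  `C_v = 0` and remain in the global mean over all vertices (the alternative
  — excluding them — would make C undefined on sparse graphs).
* **Path length.** The harmonic form
  `L = n_pairs / Σ 1/d_ij` with disconnected pairs contributing zero keeps L
  finite for any graph with at least one edge; a fully edgeless graph is
  flagged with an infinite marker instead of a number.
* **Surrogate normalization.** γ = C/C_s and λ = L/L_s, where C_s and L_s
  are means over degree-preserving surrogates generated by repeated
  double-edge swaps ((a,b)+(c,d) → (a,d)+(c,b), rejecting self-loops and
  duplicates). The swap budget is 10·E attempted swaps per surrogate, a
  standard mixing heuristic (configurable). Graphs with no admissible swap
  (a star) are returned unchanged. Surrogates with undefined L are excluded
  from L_s and counted. Default 50 surrogates per graph and level.
* **Reference curves.** Ordered: C = 3/4, L = N/2K. Random: C = K/N,
  L = ln N/ln K. The exact ring-lattice clustering 3(K−2)/(4(K−1)) is used
  as a construction oracle in tests. Sampled uniform G(n, m) graphs at
  N = 116, K = 10 agree with the random references within 10%.
* **Level grids.** Defaults T = 0.01…0.05 (step 0.01) and K = 5…15 (step 1),
  endpoints included. The sparse end must respect N > K > ln N > 1; below
  ln N graphs fragment and λ becomes percolation-fragile.

## Group statistics

* **Per-level t-tests.** Pooled-variance Student t (group1 − group2),
  df = n1 + n2 − 2; Welch is available as an option. Zero pooled variance
  yields t = 0 with a warning.
* **Cluster-based permutation test.** Per-level t-values are thresholded at
  the 2.5th/97.5th quantiles of the t sampling distribution; maximal runs of
  same-signed supra-threshold values at adjacent levels form clusters scored
  by their summed t. The two-sided single test statistic is the maximum
  absolute cluster sum, referred to its distribution under random
  repartitions of the pooled subjects into the original group sizes. When
  C(n1+n2, n1) ≤ 20 000 all repartitions are enumerated and p is the exact
  fraction at least as extreme (the observed labeling is one of them);
  otherwise p uses Monte-Carlo repartitions with the (count+1)/(n+1)
  convention. No observed cluster gives p = 1. The max-|sum| combining rule
  is the conservative two-sided reading; the test can be applied to any
  metric column (λ over the K grid by default — path-length differences are
  the analysis' primary endpoint).
* **Regional difference map.** Pairwise two-tailed uncorrected t-tests at
  α = 0.05; by design no multiple-comparison correction is applied, and
  results are aggregated into lobe-block pair counts (increases/decreases)
  for interpretation — individual pair significance is not meaningful at
  this α. A cerebellum-exclusion filter supports the reduced ROI set.

## ROI registry

The bundled registry encodes a 116-region AAL-style parcellation: 54
regions per hemisphere plus 8 midline vermis structures, of which 26
(cerebellar hemispheres + vermis) carry the cerebellum flag; exclusion
leaves 90. Lobe blocks (frontal 32, temporal-L/R 10 + 10, parieto-occipital
28 including precuneus/cuneus/lingual, subcortical 10 including insula,
cerebellar 26) are a documented approximation for block-level summaries —
exact lobe assignment of a handful of regions (mid-cingulate, insula) is
conventional. Because SL is bivariate, the cerebellum-excluded SL matrix is
the row/column submatrix of the full one and is not recomputed.

## Synthetic cohort generator

A latent-factor Gaussian model: one latent signal per lobe block plus one
global signal. The series of region `r` in block `b` is

    x_r(t) = Σ_b' coupling[b, b'] · z_b'(t) + g · z_global(t) + σ · ε_r(t)

followed by a 3-sample moving average that emulates slow BOLD temporal
autocorrelation. Patients use `coupling = base_coupling + ad_effect`.
Per-subject random streams are spawned as `default_rng([seed, subject_idx])`,
so cohorts are bit-reproducible and subjects independent.

**Defaults and why.** SL is insensitive below pairwise correlation ≈ 0.6
(measured on this generator), so realistic couplings are high: within-block
loadings 0.60 (frontal), 0.85 (temporal L/R, cerebellar), 0.90
(parieto-occipital), 0.80 (subcortical); all cross-block loadings 0.25;
global weight 0.65; noise SD 0.35. These place the healthy cohort in the
regime the analysis targets: whole-brain mean S ≈ 0.08, small-world
γ ≈ 3.5–4.5 at K = 10, and a control network dominated by a strong
posterior synchronization cluster with comparatively weak frontal coupling.

**The AD-like effect** (additive deltas on block-pair couplings):
+0.15 frontal↔frontal, −0.20 frontal↔parieto-occipital, −0.15
temporal-L↔parieto-occipital, +0.10 temporal-R↔frontal, and −0.15
parieto-occipital↔parieto-occipital. The within-posterior decrease is part
of the emulated phenotype — posterior cortices lose synchronization
generally, not only their frontal links — and it is what lets the effect
express in network topology: at fixed K, controls concentrate their edges
in the strongest (posterior/temporal/cerebellar) blocks while the patient
deltas flatten the block hierarchy and spread edges across blocks, yielding
less modular, more random-like patient graphs and hence a shorter corrected
path length λ, with the whole-brain mean S nearly unchanged. The magnitudes
are a design choice (the qualitative pattern, not effect sizes, is what the
generator emulates).

**What the generator does not model:** hemodynamics (no balloon model),
head motion, scanner drift, physiological noise spectra, spatial
neighborhood effects or volumes. Consequently, passing tests demonstrate
that the estimators and statistics behave correctly on data with the
designed covariance and dynamics — not that the pipeline is robust to fMRI
artifacts.

**Coupled-map fixture.** Unidirectionally coupled Hénon maps
(a = 1.4, b = 0.3) with the response's quadratic term mixing driver and own
state with weight `c`; after a 5000-step transient the response is
independent at c = 0 (SL ≈ P_ref), identically synchronized at c = 1
(SL = 1 exactly), and SL increases monotonically in between — the classic
validation that SL tracks generalized, not merely linear, coupling.

## Problem sizes used in validation

The test suite runs scaled-down study conditions chosen once:

* **Effect recovery / headline direction:** 20 replicates of 60 regions,
  16 + 16 subjects, 200 timepoints; λ averaged over K ∈ {5, 6} with 16
  surrogates. The K choice keeps the edge budget below the control group's
  strong-block pair count (the regime of the full 116-region design, where
  E = 580 at K = 10) and above the ln N percolation limit.
* **Type-I calibration:** 200 null replicates (zero patient delta) of 12
  regions, 6 + 6 subjects, 80 timepoints, path length over K = 3…6,
  exhaustive permutation test (C(12,6) = 924 repartitions). Observed
  rejection rate at p < 0.05 must lie in [0.02, 0.09].
* **Oracle equivalence:** exact agreement with a naive double-loop SL on
  60-point series, exhaustive triangle counting and Floyd–Warshall path
  lengths on ≤ 12 vertices, and exhaustive-vs-Monte-Carlo permutation
  p-values on 4 + 4 subjects.

## Known limitations

* The raw λ of the synthetic cohorts (≈ 3 at K = 10, 116 regions) is higher
  than values typically reported for real resting-state networks (≈ 1.5–1.7):
  the latent-block model produces crisper modules than real cortex. Group
  *differences* in λ, not its absolute level, are the validated quantity.
* Synthetic patients show a slightly lower whole-brain S than controls
  (≈ 0.077 vs 0.083) because the negative deltas outweigh the positive ones;
  the difference is within ~10% and does not affect fixed-K comparisons,
  which equalize edge counts by construction.
* γ in synthetic patients trends slightly above controls, a side effect of
  the frontal densification; with real data the analysis reports γ
  essentially unchanged. Tests therefore assert nothing about γ differences.
* The independence baseline of SL is `⌈P_ref·n⌉/n`, ≈ 10% above P_ref at
  Tn = 200 (see above).
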