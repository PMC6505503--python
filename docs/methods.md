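# Methods

`immunosig` re-creates, end to end and at desk scale, the statistical
pipeline of a case/control immunosignature study on random-sequence peptide
microarrays: serum antibodies are profiled against ~10⁵ random 12-mer
peptides, candidate peptide signatures separating ME/CFS cases from healthy
controls are discovered on one cohort, validated on geographically distinct
cohorts, and refined peptide-by-peptide. Because the original serum-array
data are not publicly deposited, the package pairs the analysis code with a
synthetic-data generator whose defaults mirror the study design, so every
stage can be exercised against a known planted truth.

## Synthetic data model

Per peptide `p` and subject `s`, on the log2 scale:

    y[p,s] = b_p + delta_p · 1{s is case} + eps[p,s]

* `b_p ~ N(baseline_mean, baseline_sd)` — per-peptide baseline log2
  intensity. Default `(10, 1.5)`: raw medians near 2¹⁰ with a heavy right
  tail, matching a 16-bit fluorescence digitizer whose ceiling (65,535)
  clips the brightest spots.
* `sigma_p = subject_sd · exp(N(0, subject_sd_dispersion))` — per-peptide
  between-subject biological SD. Defaults 0.5 and 0.25: most peptides vary
  by ~1.4-fold between subjects, a minority several-fold, giving the
  spread of per-peptide variances that makes empirical-Bayes moderation
  meaningful.
* `delta_p = sign_p · effect_size · sigma_p` on the
  `n_signature_peptides` planted peptides (default 100), zero elsewhere.
  `effect_size` is therefore an exact standardized mean difference
  (Cohen's d); `effect_sign_mix` (default 0.5) sets the fraction shifted
  downward in cases.
* Signature coherence: antibody titers vary continuously between subjects,
  so signature peptides co-vary rather than fluctuate independently. A
  fraction `signature_coherence` (default 0.5) of each signature peptide's
  biological variance is carried by a common per-subject factor, sign-
  aligned with each peptide's effect direction and variance-preserving
  (the within-group SD stays exactly `sigma_p`). This shared factor is
  what gives the planted signature the rank-one correlation structure
  that unsupervised methods (sparse PCA/IPCA, gene shaving) detect; with
  independent noise a pure mean-shift block at 10,000 × 43 is a
  sub-dominant variance direction and is invisible to them.
* Each physical array adds a per-batch per-peptide shift
  `N(0, batch_shift_sd)` (default 0.3; discovery and validation arrays
  belong to separate assay batches) and technical noise
  `N(0, log2(1 + replicate_cv))` (default CV 0.10, typical of technical
  duplicates). Values are exponentiated, rounded, clipped to [0, 65535].
* Outlier replicates are modeled as an across-peptide permutation of one
  array: the marginal distribution is untouched but within-pair rank
  concordance collapses, giving replicate QC a well-defined target.

The default design realizes the study's partitions: Discovery = 22
Canadian cases + 21 Canadian controls; Validation = 22 Norwegian cases,
6 US controls, 6 Canadian cases, 7 Canadian controls. All non-US samples
are technical duplicates; the US controls are flagged exempt singletons.
Validation-cohort Canadians are simulated as distinct subjects (distinct
serum draws assayed in the validation batch), avoiding any leakage between
partitions.

What the generator does **not** emulate: sequence-dependent binding,
spot-level image artifacts, heavy-tailed or spatially structured noise,
cohort-specific handling effects beyond the batch shift, and any
dependence between baseline brightness and effect size. Passing tests
demonstrate correctness and power of the *analysis machinery* under a
clean factor-plus-noise model, not performance on real serum arrays.

## Preprocessing

Control peptides are averaged per array (reported for QC; not used to
rescale — the downstream use of control summaries is deliberately left
open). Replicate pairs are tested by Spearman rank correlation over log2
analysis values and flagged below `min_concordance` (default 0.8 —
scale-free, robust to saturation, and driven to ~0 by the permutation-style
corruption being modeled). Surviving pairs are averaged; flagged pairs are
dropped whole; singletons are dropped unless exempt. Each merged sample is
then log2-transformed and median-centered. The centering subtracts the
median of the log2 values — identical to dividing by the median intensity
for odd peptide counts, and exactly median-zero (tolerance 1e-9 in tests)
for even counts too, where dividing by the raw median would leave a
residual of order the central gap. Zeros become 0.5 (half the minimum
detectable count) before the log.

## Feature discovery

* **Sparse PCA** — soft-thresholded power iteration on the row-centered,
  successively deflated matrix; at each iteration the threshold is set at
  the (k+1)-th largest loading magnitude so a component carries exactly
  `k_features` (default 100) nonzero loadings. Deflation removes the
  sparse component found, so later lists describe the residual.
* **Sparse IPCA** — FastICA (cubic, kurtosis-seeking contrast) rotation of
  the leading principal subspace of peptide loadings, then hard selection
  of the `k_features` largest-|loading| peptides per rotated component;
  components ordered by projected variance.
* **Gene shaving** — iteratively removes the 10% of peptides least aligned
  (smallest |inner product|) with the current PC1, producing a nested
  sequence of sets down to a single peptide; the retained size maximizes
  the gap statistic, i.e. the cluster R² minus its mean over
  `n_permutations` row-permuted matrices shaved the same way (ties break
  toward the larger size). R² is the between-sample variance of the
  *sign-aligned* mean profile over the mean per-peptide variance: rows are
  flipped by the sign of their PC1 loading first, since with a mixed-sign
  signature an unsigned mean cancels to zero and no such cluster could
  ever be selected. The working matrix is orthogonalized against each
  retained cluster's aligned mean profile before the next cluster.
* **Moderated t ("RL")** — two-sample t with empirical-Bayes variance
  shrinkage. The scaled-F prior `(s0², d0)` is moment-matched on the log
  scale (digamma/trigamma relations; the fit is verified against the
  reference R implementation to ~1e-8 in tests). For robustness the
  variances entering the prior fit are winsorized at their 5th/95th
  percentiles (configurable; `winsor=None` gives the plain fit, `d0=0`
  recovers the ordinary pooled t). Selection: BH-adjusted p ≤ 0.05.
* **Random forest ("RF")** — 1000-tree classifier; peptides kept when
  Mean Decrease Gini importance reaches a threshold. By default the
  threshold is the 99.7th percentile of importances from one refit on
  permuted labels — an empirical null for importance-by-chance.
* **Elastic-net frequency ("EN")** — 100 resampled runs, each dropping 2
  random cases and 2 random controls (39 samples at the default design)
  and fitting an elastic net (mixing 0.5) of the ±1 group indicator with
  3-fold internal cross-validation over a 16-point penalty path spanning
  two decades (the standard path range when features outnumber samples).
  Peptides with nonzero coefficients in ≥ 10% of runs form the list. Note
  a CV-tuned sparse fit at n≈39 keeps only ~40–60 coefficients, so the
  stable core is strongly enriched for, but does not cover, a 100-peptide
  planted block; this is an inherent property of stability selection, not
  a defect (quantified in the test suite).

All per-run randomness derives from a single master seed through named
`SeedSequence` children spawned in a fixed order, so the entire ensemble
is reproducible bit-for-bit.

## Panels, signatures, evaluation, refinement

Each unsupervised method's ten lists are scored by the AUC of their
signature score on the discovery data; the best list and any list within
0.02 AUC of it (at most `max_lists`, default 2) are unioned into the
method's panel — an automated stand-in for the study's by-eye review of
list separability, operationalizing exactly the criterion described
(largest AUCs). Supervised lists pass through unchanged. The seven
candidate signatures are fixed set algebra over the six panels (CPS001 =
GS ∩ (RL ∪ RF ∪ EN), CPS002/3 = union/intersection of unsupervised,
CPS004/5 = union/intersection of supervised, CPS006/7 = union/intersection
of all six); empty signatures are flagged excluded, and the rejected
alternative GS ∩ RL ∩ RF ∩ EN is reported but not carried forward.

A signature score is the mean over signature peptides of `sign_p ·
x[p,s]`, where `x` is the processed matrix and `sign_p` the sign of the
peptide's loading on PC1 of the peptide-standardized signature submatrix
(zero loadings count +1). PC1's inherent sign ambiguity is resolved by a
single global orientation chosen so cases score at least as high as
controls on average — the one place labels enter — hence reported AUCs are
≥ 0.5. AUC is the tie-aware Mann–Whitney statistic (verified against
exhaustive pair counting). The PC1-weight AUC ranks all peptides of the
evaluated partition by |PC1 weight| of the standardized full matrix and
computes the AUC of signature membership against that ranking; it is
computed on the evaluated partition only (configurable). Blinded views use
PCA coordinates and average-linkage hierarchical clustering on correlation
distance over the row-standardized signature submatrix (standard choices
for expression-style heatmaps), with labels consulted only for the
reported Rand index.

Refinement keeps the peptides of the winning signature (CPS001 by default;
falls back to the best validation AUC if that signature is empty) whose
two-sided Welch p-values are below 0.05 in all four comparisons: discovery
cases vs controls (22v21), validation Canadian cases vs controls (6v7),
Norwegian cases vs Canadian controls (22v7), Norwegian cases vs US
controls (22v6). No multiple-testing correction is applied inside
refinement — the four-way conjunction is itself the stringency mechanism
(a BH option exists but is off by default). At a 1.5-SD effect the
conjunction has joint power ≈ 0.52 by normal-theory Monte Carlo (the 6v7
comparison is binding), so refinement trades roughly half the recall for
near-perfect precision; the test suite asserts recall against that oracle
rather than wishful values.

## Numerical choices and degenerate inputs

PC1 computations use the exact n×n eigenproblem of the sample Gram matrix
(n ≤ ~100 throughout), with a deterministic sign convention. Sparse-PCA
ties at the threshold are broken by stable ordering; gene-shaving gap ties
break toward the larger cluster. Rank-deficient inputs truncate the list
set with a warning. Constant peptide rows are dropped (with a warning) in
clustering views and given zero standardized values in scoring. Matrices
are validated on read (duplicate ids, missing or non-numeric cells →
errors with coordinates). Zero abundances: see preprocessing.

## Problem sizes used by the test suite

Tests run the generator at 600–10,000 peptides. The 20-seed full-pipeline
recovery check runs at the default study conditions (10,000 peptides, 100
planted, 1.5 SD) with method-scale knobs chosen for desk-scale runs: 8
gene-shaving permutations, 400 trees, 25 elastic-net runs. The acceptance
script (`scripts/acceptance.py`) runs one full pipeline at the complete
defaults (20 permutations, 1000 trees, 100 runs) plus the full-scale
125,000-peptide library constants.

## Known limitations

* Gene shaving's gap statistic recovers the tight core of a planted
  signature, not its full extent; the refined signature consequently
  favors precision (median 1.0 in the recovery check) over recall
  (median ≈ 0.27 at the default conditions).
* The "review" of unsupervised lists is an automated AUC rule; a human
  analyst could choose differently.
* Replicate QC assumes duplicate arrays; higher replication is rejected
  rather than handled.
* The log-normal intensity model is a stand-in; no claim is made that it
  matches real array intensity distributions.
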