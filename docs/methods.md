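# Methods

## Data model and preprocessing

Expression data are genes x samples matrices over a fixed gene panel, with
per-sample severity labels (CON / INC / MOD / SEV) supplied externally and
never inferred from sample identifiers. Preprocessing transforms are applied
in user order and recorded in the matrix provenance:

* `log2` — base-2 logarithm after an optional nonnegative offset. The default
  offset is 0, so matrices containing zeros require the caller to opt into
  `log_offset=1`; silently shifting data would change low-expression ratios.
* `zscore_by_sample` — each sample column is centered and scaled by its
  population (1/n) standard deviation. The 1/n convention is used throughout
  the package, consistent with the correlation estimator below; Pearson
  correlations are invariant to the 1/n vs 1/(n-1) choice.
* `quantile_normalize` — the between-array step: each column's empirical
  distribution is mapped onto the mean-of-sorted-rows reference, ties
  receiving the average of the reference values their ranks span. This is a
  deliberate, documented stand-in for limma-style between-array
  normalization; exact replication of any specific implementation is a
  non-goal.

Probe-to-symbol collapsing keeps the probe with maximum mean expression per
symbol (the common microarray convention; configurable), and output rows
always follow panel order.

### The gene panel

The packaged default panel holds 41 proteasome subunit genes: PSMA1–7
(alpha), PSMB1–10 (beta), PSMC1–6 (ATPase base), PSMD1–14 (non-ATPase base,
lid, assembly), PSME1–4 (activators). Published subunit rosters vary (some
include PSMA8 or further PSMD symbols), and no unique 41-member list is
canonical, so the panel file documents itself as a best reconstruction and is
fully overridable via a user YAML/JSON file. Marker operations additionally
require the alpha role to be exactly PSMA1–PSMA7.

## Hub screening

Per stage, the Pearson matrix is computed with 1/n moments
(`rho_ij = cov_ij / (sigma_i sigma_j)`, covariance and standard deviations
both 1/n). Genes with zero variance are an error in strict mode (keeping
matrices complete); lenient mode marks their rows/columns undefined (NaN) for
exploratory runs.

Difference matrices `dR = R_stage - R_CON` are screened over the strict
upper-triangle multiset: mean and population sigma of the 820 entries define
the threshold `mean + k*sigma` (default k = 2, upper one-sided, matching the
direction of the disease effect — correlations rise with stage; a two-sided
variant is a flag). Ties exactly at the threshold are not flagged. A gene
enters the per-stage set `dS` when it belongs to at least `min_pair_count`
flagged pairs (default 1); the hub set `Omega` is the three-way intersection
of the stage gene sets. Whether the original procedure intersects pair sets
or gene sets before reporting genes is ambiguous; both are implemented
(`intersection_mode="genes"` default, `"pairs"` stricter).

The 2-sigma cutoff is calibrated by the normal coverage constants
(P(|x-mu| < k*sigma) = 0.6826 / 0.9544 / 0.9974 for k = 1, 2, 3, i.e. an
upper-tail mass of ~2.3% at k = 2), exposed as `gaussian_coverage`. A
standalone one-sample t-test (1/(n-1) sample sd, df = n-1, two-sided p) is
provided as part of the screening toolkit; its precise application point in
the original screening chain is not specified, so it is not hard-wired into
the screen.

No multiple-testing correction is applied across pairs, deliberately
mirroring the source procedure.

## Disorder metrics

For a hub correlation matrix `R` (g genes):

* **System determinant** `det(R)` lies in [0, 1] for any valid correlation
  matrix (Hadamard bound); values within 1e-10 below zero are clipped to 0.
  Geometrically it is the volume spanned by the gene vectors: orthogonal
  genes give 1, a coordinated (singular) network gives 0.
* **System entropy**: eigenvalues are clipped at zero when within 1e-8
  (near-PSD numerical noise; anything more negative raises), squared and
  normalised into the occupancy vector `P_i = lambda_i^2 / sum lambda_j^2`;
  `H(P) = -sum P_i log2 P_i` with `0*log 0 := 0`. H ranges over
  [0, log2 g], attaining the maximum exactly at the identity matrix.
* **Determinant entropy**: all `C(n, dim)` sample subsets of a stage are
  enumerated in lexicographic order; each subset's g x g Pearson matrix
  (same 1/n estimator) yields one determinant. Determinants within 1e-12 of
  zero are snapped to exactly 0 — subsets with `dim <= g` are singular by
  construction (centered rank <= dim - 1) and the snap lets downstream
  histograms see the degenerate multiset for what it is. Subsets containing
  a zero-variance gene are excluded and counted, not imputed. The histogram
  bin width is `a = sigma(pooled multiset of all groups)/10` (population
  sigma, overridable); per group, half-open bins of width `a` span
  [min, max] anchored at the group minimum with the last bin closed (the
  closure convention is not dictated by the procedure's description; this
  choice guarantees every value falls in exactly one bin). Zero-frequency
  bins are dropped before the Shannon entropy. A zero pooled spread returns
  zero entropy per group with a degenerate flag.

Because the bin width derives from the pooled sigma and bin origins from
group minima, the determinant entropy is invariant under any shared positive
affine transform of all groups' values.

**Degenerate dims.** With the default 3-gene hub network, `dim = 3` forces
every subset determinant to 0, so the determinant entropy at that dim is
exactly 0 for every group. The implementation reproduces this mathematics
and flags it rather than guessing an intent; dims are reported per value so
degenerate and informative dims stay distinguishable.

## Composite marker and classifier

* **PC1 marker**: eigendecomposition of the gene-gene covariance (samples as
  observations) of the marker panel (PSMC6 + PSMA1–PSMA7); scores are
  centered projections on the top eigenvector. Orientation is fixed by
  making the loading sum positive (tie: first nonzero loading positive) so
  signs are reproducible across runs and libraries.
* **Clinical fits**: ordinary least squares with Pearson r and two-sided p
  from `t = r sqrt((n-2)/(1-r^2))`, df = n-2. A constant response returns
  r = 0, slope 0 (no association) rather than an error. Samples can be
  excluded by a configurable postmortem-interval rule (`PMI > threshold`);
  no threshold is hard-coded.
* **Classifier**: features are (PSMC6, mean alpha-ring) per sample; a
  soft-margin linear SVM (regularization C = 1.0 by default — the original
  setting is unstated) is evaluated with stratified k-fold cross-validation
  (shuffled, seeded); per-fold AUC comes from decision scores on the held-out
  fold and the reported boundary is refit on all data. Fold counts above the
  smaller class size raise with a suggestion rather than silently shrinking.
* **Rotated band rule**: the x'-axis is the OLS trendline fitted on disease
  samples only, y' the signed orthogonal deviation (an isometry; pairwise
  distances are preserved). The band half-width is the configured quantile
  (default 0.95) of disease |y'| — the original display draws the band but
  never states its width, so a coverage quantile is the package's own
  definition. Reported rates: fraction of disease samples outside the band
  and of controls inside it, on all samples (the within-CV variant of these
  rates is not defined here because the band is a descriptive rule, not a
  cross-validated model). The threshold point O defaults to the decision
  boundary evaluated at the marginal feature medians and is overridable; in
  the source analysis O is a dataset-specific display coordinate.

## Synthetic cohorts

The generator emulates a staged hippocampal microarray cohort on the z-score
scale. Defaults (all overridable):

| parameter | default | meaning |
|---|---|---|
| group sizes | 9/7/8/7 | CON/INC/MOD/SEV samples (31 arrays total) |
| panel | 41 genes | the default proteasome panel |
| hub genes | PSMA2, PSMA4, PSMC6 | planted coupled block |
| baseline correlation | 0.1 | panel-wide equicorrelation |
| stage couplings | 0.2/0.5/0.7/0.9 | hub-block correlation per stage |
| downregulation | -0.5 z per stage step | applied to hub + alpha genes |
| noise sd | 1.0 | marginal expression sd (z scale) |
| MMSE model | 28 - 6*stage + N(0, 2) | clipped to [0, 30] |
| NFT model | 2 + 8*stage + N(0, 2) | clipped at 0 |
| PMI | U(3, 12) hours | for exclusion-rule exercises |

Per stage, samples are drawn from a multivariate normal with the stage mean
vector and a nearest-PSD-repaired stage correlation matrix (eigenvalue floor
1e-6, diagonal rescale; the repair distance is recorded in the returned
truth). A Student-t scale-mixture option provides heavier tails. All
randomness flows from a single seed; regeneration from (config, seed) is
exactly reproducible. The clinical noise sd of 2.0 was chosen once so that
the PC1–MMSE correlation lands around |r| ≈ 0.6–0.8 on default cohorts, a
calibration choice of this package, not a literature value.

What the generator does **not** emulate: probe-level artifacts, batch
effects, brain-region structure, non-Gaussian marginal shapes of raw
intensities, or realistic panel-wide co-expression beyond an equicorrelated
background. Passing tests on synthetic cohorts therefore demonstrate the
pipeline's correctness and its qualitative stage-wise signatures, not
clinical performance on real cohorts.

## Problem sizes and calibration findings

Tests and the acceptance script use 50 default cohorts for the stage-wise
survey, 20 for marker/classifier summaries and 20 permutation repetitions —
sizes at which the reported medians are stable to the displayed precision.

Two honest findings from exercising the method at the default conditions:

* **Screen power.** With 7–9 samples per group, a sample Pearson correlation
  has sd ≈ (1-rho^2)/sqrt(n-1) ≈ 0.35–0.40, so each dR entry carries sd
  ≈ 0.5 while the planted hub increments are 0.3/0.5/0.7. The empirical
  mean + 2*sigma threshold of the 820-entry triangle sits near 1.0, and the
  three-stage intersection compounds the per-stage miss probability: the
  screen recovers the full planted hub triple in well under half of seeded
  cohorts and admits several spurious genes. This is a property of the
  2-sigma screen at these sample sizes, reported as measured.
* **Determinant-entropy group-size sensitivity.** The entropy of a group's
  determinant histogram is capped by its subset count (C(7,5) = 21 for
  INC/SEV vs C(8,5) = 56 for MOD vs C(9,5) = 126 for CON), so the INC vs MOD
  ordering of dim-5 determinant entropy is marginal and can invert across
  seed sets even though the coupling-driven trend is clear at the extremes.

## Known limitations

* The screen applies no multiple-testing correction and its threshold is
  estimated from the same multiset it screens; both mirror the source
  procedure.
* Determinant-based metrics require at least `dim > g` samples per subset to
  be non-degenerate; with a 3-gene hub, dim = 3 is always degenerate.
* The classifier is strictly linear; no probability calibration or nonlinear
  trend modelling is attempted.
* Native GEO SOFT/series-matrix metadata parsing is out of scope; expression
  tables, stage maps and clinical tables are plain TSV/CSV.
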