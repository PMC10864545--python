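# proteocohere

Stage-wise co-expression analysis of the 26S proteasome subunit genes in
Alzheimer's disease (AD) cohorts: screening for hub genes whose intersubunit
correlation rises with disease severity, quantifying the coordination and
disorder of the resulting hub network with determinant- and entropy-based
metrics, and evaluating a two-gene-feature composite marker and linear-margin
classifier. The package is aimed at computational biologists studying
differential co-expression in small, staged expression cohorts (microarray or
RNA-seq on the z-score scale), and ships a synthetic cohort generator with
planted ground truth so every step can be exercised and calibrated without
external data.

## The method

Expression data are a genes x samples matrix `G = (g_ij)` over a 41-gene
proteasome panel (20S alpha/beta rings, 19S base and lid, assembly factors,
activators), with each sample labelled by severity stage
(CON / INC / MOD / SEV). After log2 and per-sample z-scoring:

1. **Hub screen.** Per stage, the Pearson matrix `R` is computed with 1/n
   (population) moments: `rho_ij = cov_ij / (sigma_i sigma_j)`. Difference
   matrices `dR = R_stage - R_CON` are screened over their strict upper
   triangle: entries exceeding `mean + 2*sigma` (justified by the normal
   coverage constants P(|x-mu|<k*sigma) = 0.6826 / 0.9544 / 0.9974 for
   k = 1, 2, 3) flag gene pairs. Per-stage flagged gene sets `dS` intersect
   across the three disease stages to give the hub set `Omega`.
2. **Disorder metrics** on the hub network's correlation matrix `R_hub`:
   * `det(R_hub)` — the volume spanned by the gene vectors; 1 for
     uncorrelated genes, 0 for a fully coordinated (singular) network;
   * system entropy `H(P) = -sum P_i log2 P_i` with
     `P_i = lambda_i^2 / sum lambda_j^2` over the eigenvalues of `R_hub`;
   * determinant entropy — enumerate all `C(n, dim)` sample subsets
     (dim = 3, 4, 5), compute `det(R_hub)` on each, histogram the multiset
     with bin width `a = sigma(pooled multiset)/10`, and take the Shannon
     entropy of the occupied bins.

   All three decline as intersubunit coupling rises with stage.
3. **Composite marker and classifier.** PC1 of the 8-gene marker panel
   (PSMC6 + PSMA1–PSMA7) is regressed against MMSE and NFT; a soft-margin
   linear SVM on the features (PSMC6, mean alpha-ring) is evaluated with
   stratified k-fold cross-validated ROC/AUC, and a rotated frame aligned
   with the disease-group trendline yields a deviation band in which disease
   samples concentrate.

## Worked example

`examples/` contains one narrative script per capability. For instance,
`python examples/03_disorder_metrics.py` generates a default synthetic cohort
(41 genes x 31 samples, groups 9/7/8/7, hub couplings 0.2/0.5/0.7/0.9) and
prints:

```
hub network: ('PSMA2', 'PSMA4', 'PSMC6')
 stage   det(R)     H(P)  H_det(dim=4)  H_det(dim=5)
   CON    0.925    1.428         4.506         4.717
   INC    0.664    1.030         4.072         3.785
   MOD    0.161    0.204         2.289         2.652
   SEV    0.007    0.015         0.187         0.000
```

Reading: at Control the three hub genes are nearly uncorrelated (volume 0.93,
axis entropy close to its log2(3) ≈ 1.58 maximum, widely dispersed subset
determinants), while at Severe the planted coupling of 0.9 collapses the
network onto one axis — determinant and entropies all fall, the stage-wise
signature the method detects.

The full pipeline is also available from the shell:

```bash
proteocohere all --seed 1 --out results/run1     # simulate + screen + metrics + classify
proteocohere simulate --seed 1 --out data/sim    # just write a cohort
```

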