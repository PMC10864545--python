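"""Quantify hub-network coordination and disorder per disease stage.

Three metrics on the hub correlation matrix (PSMA2, PSMA4, PSMC6):
  det(R)         -- spanned volume; 1 = uncorrelated genes, 0 = fully coordinated
  H(P)           -- entropy of the squared-eigenvalue occupancy; low = one
                    dominant correlation axis
  det entropy    -- Shannon entropy of det(R) over all C(n,5) sample subsets,
                    binned at one tenth of the pooled standard deviation
"""
from proteocohere import CohortConfig, STAGES, disorder_summary, generate_cohort

expr, _, truth = generate_cohort(CohortConfig(seed=1))
ds = disorder_summary(expr, truth.hub_genes, dims=(4, 5))

print(f"hub network: {ds.hub_genes}")
print(f"{'stage':>6} {'det(R)':>8} {'H(P)':>8} {'H_det(dim=4)':>13} {'H_det(dim=5)':>13}")
for stage in STAGES:
    print(f"{stage:>6} {ds.determinant[stage]:8.3f} {ds.system_entropy[stage]:8.3f} "
          f"{ds.determinant_entropy[4][stage]:13.3f} "
          f"{ds.determinant_entropy[5][stage]:13.3f}")

print("\nAll three metrics fall from Control to Severe: as intersubunit")
print("coupling rises, the gene vectors collapse toward one axis (volume and")
print("axis-entropy shrink) and subset determinants pile up near zero.")
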