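"""Full synthetic study: landscape -> genotypes -> population graph ->
current map -> buffered covariates -> PCA -> OLS of node connectivity.

The regression models the standardized average inverse edge weight
(gene-flow proxy) against node coordinates, sample size, and the leading
principal components of the 12 buffered cost/current covariates.
"""

from landconnect.pipeline import run_synthetic_study

out = run_synthetic_study(
    habitat_fraction=0.35, drift_scale=0.5, seed=4,
    grid=56, n_sites=20, n_loci=12, n_pairs=24, buffer_cells=6,
    radii_m=(600.0, 1200.0, 2400.0),
)
pca, reg = out["pca"], out["regression"]
print("PCA of the 12 buffered covariates (variance explained):")
for i in range(pca.k):
    print(f"  PC{i+1}: {pca.variance_explained[i]*100:5.1f}%  "
          f"(cumulative {pca.cumulative[i]*100:5.1f}%)")
print(f"\nOLS, full node set (n={reg.n_nodes}): F={reg.f_stat:.2f}, "
      f"p={reg.f_pvalue:.3f}, adj R2={reg.adj_r_squared:.3f}")
print(reg.coef.round(3).to_string())
print("-> slopes are standardized effects; a CI excluding zero flags a")
print("   predictor of node-level gene flow (sample size usually is one).")
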