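"""Characterize the resource gradient by PCA of ten environment variables.

The variables are standardized and the correlation matrix decomposed;
eigenvalues sum to 10 and axes with eigenvalue > 1 are marked retained
(Kaiser criterion). Under the synthetic design, cool/moist/nitrogen-rich
high-north plots separate from hot/dry low-south plots on the leading
axes.
"""
import numpy as np
import traitgrad as tg

env, resource = tg.generate_environment(tg.SyntheticConfig(seed=1),
                                        np.random.default_rng(1))
axes = tg.environment_pca(env)

for k in range(3):
    print(f"PC{k + 1}: eigenvalue {axes.eigenvalues[k]:.2f}, "
          f"{axes.variance_explained[k]:.1%} of variance")
print(f"retained axes (eigenvalue > 1): {axes.retained_axes}\n")
print("PC1 loadings (correlation-scale weights):")
print(axes.loadings["PC1"].round(2).to_string())
rho = np.corrcoef(axes.scores["PC1"], resource.loc[axes.scores.index])[0, 1]
print(f"\n|corr(PC1 score, latent resource score)| = {abs(rho):.2f} - the "
      "leading axis recovers the gradient that generated the data.")
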