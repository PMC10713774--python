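"""Choosing the number of principal components with the corrected AIC.

Draws a 15-feature cohort whose true latent rank is 3, fits the
cohort-wide PCA and prints the AIC curve: the minimum should sit at k=3,
and the sample-size (2^d) bound shows how many components 37 patients can
support in clustering.
"""

import numpy as np

from dmnstrat import fit_pca, formann_max_dims, project

rng = np.random.default_rng(5)
loadings = rng.normal(size=(3, 15))
loadings *= 10 / np.linalg.norm(loadings, axis=1, keepdims=True)
features = rng.normal(size=(134, 3)) @ loadings + rng.normal(size=(134, 15))

model = fit_pca(features)
print("AIC curve (rank k -> criterion, lower is better):")
for k, value in enumerate(model.aic_curve, start=1):
    marker = "  <- selected" if k == model.k_selected else ""
    print(f"  k={k:<2d} {value:12.1f}{marker}")

print(f"\nk selected by AIC: {model.k_selected} (true latent rank: 3)")
print(f"variance explained by those components: "
      f"{model.explained_variance[:model.k_selected].sum() / model.explained_variance.sum():.1%}")

cap = formann_max_dims(37)
print(f"\nclustering-variable cap for 37 patients (largest d with 2^d <= 37): {cap}")
scores = project(model, features)
print(f"patient scores handed to clustering: {scores.shape}")
# With 15 PLI features and ~10^2 participants the AIC typically keeps a
# handful of components; the 2^d rule then caps what 37 patients can
# support in an unsupervised mixture model (5 dimensions).
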