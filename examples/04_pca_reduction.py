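"""Reduce the feature matrix to its principal-component scores.

The wavelet features are hugely redundant; with n subjects the centred
matrix has at most n-1 informative directions.  The retained count is
the smallest k whose cumulative explained variance reaches 90%.
"""

import numpy as np

from adwave import CohortSpec, FeatureConfig, build_feature_matrix_from_arrays
from adwave.pca import fit_pca, select_components, transform
from adwave.synthetic import cohort_arrays

spec = CohortSpec(n_ad=6, n_hc=10, n_slices=8, effect_size=1.5, seed=4)
stacks = [s for _, _, s, _ in cohort_arrays(spec)]
labels = ["AD"] * 6 + ["HC"] * 10
fm = build_feature_matrix_from_arrays(stacks, labels, FeatureConfig(n_slices=8))

model = fit_pca(fm)
k = select_components(model, threshold=0.90)
scores = transform(model, fm, k)

cum = np.cumsum(model.explained_variance_fraction) * 100
print(f"matrix {fm.values.shape} -> {model.k_max} components")
print("cumulative variance (%):", np.round(cum[:k + 2], 2))
print(f"k = {k} components retain {cum[k - 1]:.2f}% >= 90% of the variance")
print("score matrix:", scores.shape)
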