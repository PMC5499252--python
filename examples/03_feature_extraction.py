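"""From slice stacks to the subject feature matrix.

Each subject's 32 centre slices are resized to 256x256 and reduced to
the level-5 DTCWT coefficients: 6 subbands x 8x8 positions x 2 parts =
768 features per slice, 24,576 per subject.  Here a small synthetic
cohort keeps the run short.
"""

from adwave import CohortSpec, FeatureConfig, build_feature_matrix_from_arrays
from adwave.synthetic import cohort_arrays

spec = CohortSpec(n_ad=3, n_hc=5, n_slices=8, effect_size=1.0, seed=1)
stacks, labels = [], []
for sid, label, stack, demo in cohort_arrays(spec):
    stacks.append(stack)
    labels.append(label)
    print(f"{sid}: {stack.shape[0]} slices of {stack.shape[1]}x{stack.shape[2]},"
          f" MMSE {demo['mmse']}")

fm = build_feature_matrix_from_arrays(stacks, labels,
                                      FeatureConfig(n_slices=8))
print("\nfeature matrix:", fm.values.shape, "=",
      f"{fm.n_subjects} subjects x (8 slices x 768 features)")
print("first columns:", fm.feature_names[:2], "...")
print("labels:", [str(l) for l in fm.labels])
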