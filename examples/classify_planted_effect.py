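"""Recover a planted morphometric effect with the full nested-LOOCV pipeline.

Simulates a small two-group cohort with a spherical grey-matter density
increase in the case group (Cohen's d = 4 at the voxel level before
smoothing), runs adaptive regional feature extraction + RBF-SVM
classification under leave-one-out cross-validation, and reports the
diagnostic performance.
"""

from morphosvm import (
    CohortSpec,
    EffectSpec,
    auc,
    best_threshold,
    confusion,
    diagnostic_metrics,
    generate_cohort,
    loocv,
)
from morphosvm.crossval import round_pct

spec = CohortSpec(
    n_per_group={"BD": 5, "HC": 5},
    volume_shape=(8, 8, 8),
    effects=[EffectSpec(region_center=(4, 4, 4), region_radius=2.0,
                        effect_size=4.0, compartment="GM")],
    seed=42,
)
cohort = generate_cohort(spec)
result = loocv(cohort, positive_group="BD", negative_group="HC")

report = diagnostic_metrics(confusion(result.predictions, result.truth))
print(f"held-out accuracy:   {round_pct(report.accuracy)}%")
print(f"pooled AUC:          {auc(result.scores, result.truth):.3f}")
print(f"features per fold:   {result.features_per_fold}")

thr, best = best_threshold(result.scores, result.truth)
print(f"best-threshold accuracy: {round_pct(best.accuracy)}% "
      f"(sens {round_pct(best.sensitivity)}%, spec {round_pct(best.specificity)}%)")

import numpy as np

freq = result.frequency_map.frequency["GM"]
peak = tuple(int(i) for i in np.unravel_index(freq.argmax(), freq.shape))
print(f"GM feature-frequency peak: {freq.max():.2f} at voxel {peak}")
print(f"GM feature frequency at the planted center (4,4,4): {freq[4, 4, 4]:.2f}")
# High frequency means the same region was selected across folds — a stable
# morphological signature.  Note the signature need not sit exactly on the
# planted sphere: total-brain-volume normalization redistributes a focal
# density increase into a diffuse decrease everywhere else, so low-variance
# voxels carrying that echo can be equally discriminative.
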