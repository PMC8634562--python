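"""Fit the 2-level growth model and read off predictions and contrasts.

Generates two overlapping cohorts from a known linear-growth truth with
a +2 kg offset for cohort B, fits the mixed model by REML (child-level
random intercept and slope, separate residual variances below and
above age 2), and prints the mean-trajectory prediction with 95%
intervals plus the cohort contrast at age 3.
"""

import numpy as np

from lifetraj import (
    BasisSpec,
    CohortProfile,
    Level1VarianceSpec,
    ModelSpec,
    contrast,
    default_truth,
    fit,
    generate_multi_cohort,
    predict_mean,
)

basis = BasisSpec(family="FP", powers=(1.0,))
truth = default_truth(basis, cohort_offsets={"B": 2.0})
profiles = [
    CohortProfile(cohort_label="A", age_window=(0, 10),
                  visit_schedule=(0, 1, 2.5, 4, 6, 8, 10),
                  n_children=400, schedule_jitter_sd=0.1),
    CohortProfile(cohort_label="B", age_window=(0, 6),
                  visit_schedule=(0, 0.5, 1.5, 3, 4.5, 6),
                  n_children=300, schedule_jitter_sd=0.1),
]
data = generate_multi_cohort(profiles, truth, seed=2)

spec = ModelSpec(
    trajectory=basis,
    cohort_effects="main",
    level1=Level1VarianceSpec(kind="segmented", cuts=(2.0,)),
)
result = fit(spec, data, method="REML")
print(result.summary().round(3).to_string())
print(f"\nchild-level covariance G:\n{np.round(result.G_hat, 3)}")
print(f"residual variance (<=2y, >2y): {np.round(result.level1_hat, 3)}")

print("\npredicted mean trajectory, cohort A:")
print(predict_mean(result, {"cohort": "A"}, [0.5, 2, 5, 9]).round(2).to_string(index=False))

diff, ci = contrast(result, {"cohort": "B"}, {"cohort": "A"}, age=3.0)
print(f"\nB - A at age 3: {diff:.2f} kg (95% CI {ci[0]:.2f}, {ci[1]:.2f})")
# The contrast recovers the generating +2 kg cohort offset; the wide
# residual variance above age 2 vs below mirrors how weight scatter
# grows with age.
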