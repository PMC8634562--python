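"""Simulate five heterogeneous cohorts with a known growth process.

Builds the five-cohort design (age windows 0-20, 0-5, 0-6, 9-18 and
0-16 years, cohort-specific visit schedules and dropout, one single-sex
cohort, maternal education never measured in the two oldest cohorts) at
1% of the real sample sizes, generates weights from a 5-knot spline
growth process, and prints the pooling audit.
"""

from lifetraj import default_truth, generate_multi_cohort, table1_profiles
from lifetraj.harmonize import audit_pooled

truth = default_truth()  # realistic weight-for-age curve, RCS 5 knots
data = generate_multi_cohort(table1_profiles(scale=0.01), truth, seed=1)

audit = audit_pooled(data)
print(audit.to_frame().to_string(index=False))
print()
per_child = data.measurements.groupby("child_id").size()
med = per_child.groupby(data.children.set_index("child_id")["cohort"]).median()
print("median measurements per child, by cohort:")
print(med.to_string())
# Each cohort contributes its own slice of the life course: the school
# cohort has dozens of closely spaced measurements at ages 9-18 while
# the early-childhood cohorts stop before age 7 — exactly the coverage
# pattern that motivates pooling them into one trajectory model.
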