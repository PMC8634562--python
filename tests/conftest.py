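"""Shared fixtures: small synthetic datasets and the pooled-count
fixture emulating the five real cohorts' published table of counts."""

from __future__ import annotations

import pytest

from lifetraj import (
    BasisSpec,
    CohortProfile,
    Level1VarianceSpec,
    PooledDataset,
    default_truth,
    generate_multi_cohort,
)
from lifetraj.studies import published_counts_tables


@pytest.fixture(scope="session")
def table1_tables():
    return published_counts_tables()


@pytest.fixture(scope="session")
def fp_line_truth():
    """FP(1) truth: straight-line growth, modest random effects."""
    return default_truth(BasisSpec(family="FP", powers=(1.0,)))


def two_cohort_profiles(n_a=120, n_b=100):
    return [
        CohortProfile(
            cohort_label="A",
            age_window=(0.0, 10.0),
            visit_schedule=(0.0, 1.0, 2.5, 4.0, 6.0, 8.0, 10.0),
            n_children=n_a,
            schedule_jitter_sd=0.1,
            dropout_hazard_per_visit=0.05,
        ),
        CohortProfile(
            cohort_label="B",
            age_window=(0.0, 6.0),
            visit_schedule=(0.0, 0.5, 1.5, 3.0, 4.5, 6.0),
            n_children=n_b,
            schedule_jitter_sd=0.1,
            dropout_hazard_per_visit=0.05,
        ),
    ]


@pytest.fixture(scope="session")
def toy_data(fp_line_truth) -> PooledDataset:
    """Two small cohorts generated from the FP(1) truth."""
    return generate_multi_cohort(two_cohort_profiles(), fp_line_truth, seed=11)


@pytest.fixture(scope="session")
def toy_fit(toy_data, fp_line_truth):
    from lifetraj import ModelSpec, fit

    spec = ModelSpec(
        trajectory=fp_line_truth.basis,
        cohort_effects="main",
        level1=Level1VarianceSpec(kind="segmented", cuts=(2.0,)),
    )
    return fit(spec, toy_data, method="REML")
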