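"""Desk-scale simulation studies validating the whole pipeline.

Each function sets up a fixed study design (cohort profiles, generating
truth, missingness mechanism), runs the relevant part of the pipeline
over replicate seeds, and returns summary statistics:

* :func:`likelihood_oracle_deviation` — ML/REML log-likelihoods against
  a naive dense multivariate-normal implementation;
* :func:`recovery_study` — bias of REML estimates of fixed effects,
  random-effect covariances and segmented level-1 variances over
  replicates of a five-cohort design;
* :func:`selection_recovery` — how often stage-1 selection identifies
  the generating trajectory family;
* :func:`mi_mcar_check` and :func:`mi_mar_comparison` — MI validity
  under MCAR and the MI vs complete-covariate head-to-head under
  outcome-dependent missingness.

The designs are deliberately smaller than the motivating multi-cohort
application (thousands rather than tens of thousands of children) so a
full validation run completes on a laptop; the structure — overlapping
age windows, cohort-specific schedules and dropout, systematically and
sporadically missing covariates — mirrors the real setting.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal

from .bases import BasisSpec
from .harmonize import PooledDataset, complete_covariate_filter
from .lmm import (
    Covariate,
    ModelSpec,
    fit,
    marginal_covariance,
)
from .lmm import _build_design  # noqa: F401  (oracle needs the assembled design)
from .mi import MIConfig, mi_analysis
from .selection import SelectionConfig, stage1_select
from .synthetic import (
    CohortProfile,
    MissingnessSpec,
    TruthParams,
    apply_covariate_missingness,
    default_truth,
    generate_multi_cohort,
    table1_profiles,
)
from .variance import Level1VarianceSpec

__all__ = [
    "likelihood_oracle_deviation",
    "recovery_study",
    "selection_recovery",
    "mi_mcar_check",
    "mi_mar_comparison",
]

FP1 = BasisSpec(family="FP", powers=(1.0,))
SEG2 = Level1VarianceSpec(kind="segmented", cuts=(2.0,))

EDUCATION_LEVELS = (
    "left school 15-16",
    "left school 17-18",
    "degree or higher",
)

#: Published per-cohort counts of the motivating five-cohort pooled
#: analysis: (children, weight measurements, maternal education
#: systematically missing).
PUBLISHED_COUNTS = {
    "ALSPAC": (14216, 157000, False),
    "BCG": (951, 12737, True),
    "BiB": (13445, 78110, False),
    "CHS": (1547, 89070, True),
    "PROBIT": (17046, 205864, False),
}

#: Sporadically incomplete children (a covariate individually missing)
#: in the two cohorts with individual-level gaps.
PUBLISHED_SPORADIC_INCOMPLETE = {"ALSPAC": 3000, "BiB": 2734}


def published_counts_tables() -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """Per-cohort (measurements, children) pairs reproducing the
    published count structure exactly.

    Measurement rows are schematic (constant age and weight) — this
    fixture exercises the pooling and discard arithmetic, for which
    only the counts and the missingness pattern matter."""
    out = []
    for cohort, (n_kids, n_meas, sys_missing) in PUBLISHED_COUNTS.items():
        ids = np.arange(n_kids).astype(str)
        kids = pd.DataFrame(
            {
                "child_id": ids,
                "cohort": cohort,
                "sex": "male",
                "ethnicity": "White European",
                "maternal_education": np.nan
                if sys_missing
                else EDUCATION_LEVELS[0],
                "paternal_occupation": "intermediate",
            }
        )
        n_sporadic = PUBLISHED_SPORADIC_INCOMPLETE.get(cohort, 0)
        if n_sporadic:
            kids.loc[: n_sporadic - 1, "paternal_occupation"] = np.nan
        meas = pd.DataFrame(
            {
                "child_id": np.resize(ids, n_meas),
                "cohort": cohort,
                "age_years": 1.0,
                "weight_kg": 10.0,
            }
        )
        out.append((meas, kids))
    return out


# ---------------------------------------------------------------------------
# Likelihood oracle


def _dense_loglik(data, spec, G, vals, method):
    """Independent dense implementation: explicit V_i per child and
    scipy's multivariate-normal density."""
    d = _build_design(data, spec)
    starts = np.cumsum(np.append(0, d.child_sizes))
    blocks = []
    for i in range(len(d.child_sizes)):
        sl = slice(starts[i], starts[i + 1])
        V = marginal_covariance(d.Z[sl], d.ages[sl], G, spec.level1, vals)
        blocks.append((d.X[sl], d.y[sl], V))
    XtVX = sum(X.T @ np.linalg.solve(V, X) for X, _, V in blocks)
    XtVy = sum(X.T @ np.linalg.solve(V, y) for X, y, V in blocks)
    beta = np.linalg.solve(XtVX, XtVy)
    ll = sum(
        multivariate_normal.logpdf(y, mean=X @ beta, cov=V) for X, y, V in blocks
    )
    if method == "REML":
        p = blocks[0][0].shape[1]
        ll += -0.5 * np.linalg.slogdet(XtVX)[1] + 0.5 * p * math.log(2 * math.pi)
    return ll


def likelihood_oracle_deviation(seed: int, n_instances: int = 25) -> float:
    """Max |block-Woodbury - dense oracle| log-likelihood deviation over
    random small instances (<=5 children x <=6 visits), ML and REML."""
    from .lmm import log_likelihood

    rng = np.random.default_rng(seed)
    spec = ModelSpec(trajectory=FP1, cohort_effects="none", level1=SEG2)
    worst = 0.0
    for _ in range(n_instances):
        n_children = int(rng.integers(2, 6))
        rows = []
        for i in range(n_children):
            ages = np.sort(rng.uniform(0, 10, int(rng.integers(1, 7))))
            for a in ages:
                rows.append((f"c{i}", "A", a, rng.normal(10 + 2 * a, 3)))
        meas = pd.DataFrame(
            rows, columns=["child_id", "cohort", "age_years", "weight_kg"]
        )
        kids = pd.DataFrame(
            {"child_id": [f"c{i}" for i in range(n_children)], "cohort": "A"}
        )
        data = PooledDataset(meas, kids)
        A = rng.normal(size=(2, 2)) * 0.7
        G = A @ A.T
        vals = tuple(rng.uniform(0.2, 3.0, 2))
        for method in ("ML", "REML"):
            ours = log_likelihood(data, spec, G, vals, method=method)
            oracle = _dense_loglik(data, spec, G, vals, method)
            worst = max(worst, abs(ours - oracle))
    return worst


# ---------------------------------------------------------------------------
# Parameter recovery


def recovery_truth() -> TruthParams:
    """Linear-growth truth with five-cohort offsets and two-segment
    level-1 variance (tight at infancy, loose later)."""
    return TruthParams(
        basis=FP1,
        beta={
            "intercept": 5.0,
            "basis": np.array([3.0]),
            "cohort": {"BCG": -0.6, "BiB": 0.4, "CHS": -2.0, "PROBIT": 0.9},
        },
        G=np.array([[1.0, 0.05], [0.05, 0.04]]),
        level1=SEG2,
        level1_values=(0.09, 2.25),
    )


def recovery_study(
    seed: int, n_replicates: int = 20, n_children: int = 2000
) -> pd.DataFrame:
    """REML recovery of every model parameter over replicate datasets.

    Five Table-1-like cohorts scaled to ``n_children`` total; returns a
    table with one row per parameter: truth, Monte-Carlo mean and SE of
    the estimates, and the z-score of the bias.
    """
    truth = recovery_truth()
    profiles = table1_profiles(scale=n_children / 47205)
    spec = ModelSpec(trajectory=FP1, cohort_effects="main", level1=SEG2)
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    rows = []
    for s in seeds:
        data = generate_multi_cohort(profiles, truth, seed=int(s))
        fr = fit(spec, data, method="REML")
        rec = {f"beta:{k}": v for k, v in fr.beta.items()}
        rec["G[0,0]"] = fr.G_hat[0, 0]
        rec["G[0,1]"] = fr.G_hat[0, 1]
        rec["G[1,1]"] = fr.G_hat[1, 1]
        rec["sigma2[<=2]"] = fr.level1_hat[0]
        rec["sigma2[>2]"] = fr.level1_hat[1]
        rows.append(rec)
    est = pd.DataFrame(rows)
    truth_map = {
        "beta:const": 5.0,
        "beta:t^1": 3.0,
        **{f"beta:cohort[{c}]": v for c, v in truth.beta["cohort"].items()},
        "G[0,0]": truth.G[0, 0],
        "G[0,1]": truth.G[0, 1],
        "G[1,1]": truth.G[1, 1],
        "sigma2[<=2]": truth.level1_values[0],
        "sigma2[>2]": truth.level1_values[1],
    }
    out = []
    for param, tv in truth_map.items():
        vals = est[param]
        mc_se = vals.std(ddof=1) / math.sqrt(len(vals))
        z = (vals.mean() - tv) / mc_se if mc_se > 0 else 0.0
        out.append(
            {
                "param": param,
                "truth": tv,
                "mean": vals.mean(),
                "mc_se": mc_se,
                "z": z,
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Selection consistency


def selection_profiles() -> list[CohortProfile]:
    """Three cohorts with overlapping windows spanning birth to 20
    years (wide birth cohort, early-childhood cohort, school cohort)."""
    return [
        CohortProfile(
            cohort_label="wide", age_window=(0.0, 20.0),
            visit_schedule=(0.0, 0.5, 1.5, 4.0, 8.0, 12.0, 16.0, 19.5),
            n_children=800, schedule_jitter_sd=0.15,
            dropout_hazard_per_visit=0.03,
        ),
        CohortProfile(
            cohort_label="young", age_window=(0.0, 6.0),
            visit_schedule=(0.0, 0.3, 1.0, 2.5, 4.0, 6.0),
            n_children=700, schedule_jitter_sd=0.1,
            dropout_hazard_per_visit=0.04,
        ),
        CohortProfile(
            cohort_label="school", age_window=(9.0, 18.0),
            visit_schedule=(9.0, 11.0, 13.0, 15.0, 16.5, 18.0),
            n_children=500, schedule_jitter_sd=0.1,
            dropout_hazard_per_visit=0.02,
        ),
    ]


def selection_truth(family: str) -> TruthParams:
    if family == "RCS":
        return default_truth(BasisSpec(family="RCS", knots=(0.5, 2.0, 7.0, 12.0, 17.0)))
    return default_truth(BasisSpec(family="FP", powers=(0.0, 1.0), age_shift=1.0))


def selection_recovery(
    family: str, seed: int, n_seeds: int = 10, n_select: int = 1500
) -> dict:
    """Fraction of replicate seeds in which stage-1 selection picks the
    generating trajectory family (the family is fixed at stage 1; stage
    2 only chooses the level-1 structure)."""
    truth = selection_truth(family)
    profiles = selection_profiles()
    seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    winners = []
    for s in seeds:
        data = generate_multi_cohort(profiles, truth, seed=int(s))
        config = SelectionConfig(
            n_select=n_select, seed=int(s) + 1, criterion="BIC",
            fit_max_iter=30, fit_em_iter=6,
        )
        report, _, _ = stage1_select(data, config)
        winners.append(report.winner.family)
    frac = float(np.mean([w == family for w in winners]))
    return {"family": family, "winners": winners, "recovery_fraction": frac}


# ---------------------------------------------------------------------------
# Multiple imputation


def mi_truth() -> TruthParams:
    """Maternal education shifts the child's intercept by 0/1/2 kg."""
    return default_truth(
        FP1,
        covariate_effects={
            "maternal_education": dict(zip(EDUCATION_LEVELS, (0.0, 1.0, 2.0)))
        },
    )


def mi_profiles(n_children: int = 800) -> list[CohortProfile]:
    n_a = int(round(n_children * 0.56))
    return [
        CohortProfile(
            cohort_label="A", age_window=(0, 10),
            visit_schedule=(0.0, 1.0, 2.5, 4.0, 6.0, 8.0, 10.0),
            n_children=n_a, schedule_jitter_sd=0.1,
        ),
        CohortProfile(
            cohort_label="B", age_window=(0, 6),
            visit_schedule=(0.0, 0.5, 1.5, 3.0, 4.5, 6.0),
            n_children=n_children - n_a, schedule_jitter_sd=0.1,
        ),
    ]


MI_ANALYSIS_SPEC = ModelSpec(
    trajectory=FP1,
    covariates=(Covariate("maternal_education"),),
    cohort_effects="main",
    level1=SEG2,
)

#: Coefficient whose recovery the MI studies track (true value 2.0).
MI_TARGET = "maternal_education[degree or higher]"
MI_TARGET_TRUTH = 2.0


def age_adjusted_proxy(data: PooledDataset, n_bins: int = 25) -> pd.Series:
    """Each child's mean weight deviation from the pooled age profile.

    Ages are cut into quantile bins; the proxy is the child's mean
    residual from the bin means.  Unlike the raw mean weight, this
    reflects how heavy a child runs *for their age*, not which ages
    they happened to be measured at."""
    meas = data.measurements
    bins = pd.qcut(meas["age_years"], q=n_bins, duplicates="drop")
    resid = meas["weight_kg"] - meas.groupby(bins, observed=True)[
        "weight_kg"
    ].transform("mean")
    return resid.groupby(meas["child_id"]).mean()


def _fast_mi_config(seed: int, m: int = 5, n_cycles: int = 3) -> MIConfig:
    return MIConfig(
        m=m, n_cycles=n_cycles, seed=seed,
        imputation_order=("maternal_education",),
        fit_max_iter=60, fit_em_iter=10,
    )


def mi_mcar_check(seed: int, n_children: int = 800, rate: float = 0.2) -> dict:
    """Pooled MI estimates vs the full-data fit under MCAR holes.

    Returns the largest |pooled - full| / SE(full) over the fixed
    effects; MI validity requires it to stay within sampling noise.
    """
    truth = mi_truth()
    full = generate_multi_cohort(mi_profiles(n_children), truth, seed=seed)
    rng = np.random.default_rng(seed + 1)
    kids = full.children.copy()
    holes = rng.random(len(kids)) < rate
    kids.loc[holes, "maternal_education"] = np.nan
    data = PooledDataset(full.measurements, kids)
    full_fit = fit(MI_ANALYSIS_SPEC, full, method="REML")
    pooled, _ = mi_analysis(data, MI_ANALYSIS_SPEC, _fast_mi_config(seed + 2))
    se = np.sqrt(np.clip(np.diag(full_fit.beta_vcov), 1e-12, None))
    z = np.abs(
        (pooled.q_bar.reindex(full_fit.beta.index) - full_fit.beta) / se
    )
    return {"max_z": float(z.max()), "z": z}


def mi_mar_comparison(seed: int, n_seeds: int = 12, n_children: int = 800) -> dict:
    """MI vs complete-covariate analysis under outcome-dependent MAR.

    Missingness in maternal education rises with how heavy a child runs
    for their age (the age-adjusted outcome level), so restricting to
    complete children selectively removes the heaviest children of the
    best-educated mothers and attenuates the education effect.  Returns
    the per-seed absolute biases of both estimators for the
    degree-or-higher coefficient and the fraction of seeds where MI is
    closer to the truth.
    """
    truth = mi_truth()
    profiles = mi_profiles(n_children)
    mech = MissingnessSpec(rates={"maternal_education": (-1.2, 1.8)})
    seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    rows = []
    for s in seeds:
        s = int(s)
        full = generate_multi_cohort(profiles, truth, seed=s)
        proxy = age_adjusted_proxy(PooledDataset(full.measurements, full.children))
        kids = apply_covariate_missingness(
            full.children, mech, proxy, seed=s + 1
        )
        data = PooledDataset(full.measurements, kids)
        cc_data, _ = complete_covariate_filter(data, ["maternal_education"])
        cc_fit = fit(MI_ANALYSIS_SPEC, cc_data, method="REML")
        pooled, _ = mi_analysis(data, MI_ANALYSIS_SPEC, _fast_mi_config(s + 2))
        rows.append(
            {
                "seed": s,
                "cc_bias": abs(cc_fit.beta[MI_TARGET] - MI_TARGET_TRUTH),
                "mi_bias": abs(pooled.q_bar[MI_TARGET] - MI_TARGET_TRUTH),
            }
        )
    table = pd.DataFrame(rows)
    table["mi_wins"] = table["mi_bias"] < table["cc_bias"]
    return {
        "table": table,
        "mi_win_fraction": float(table["mi_wins"].mean()),
        "mean_cc_bias": float(table["cc_bias"].mean()),
        "mean_mi_bias": float(table["mi_bias"].mean()),
    }
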