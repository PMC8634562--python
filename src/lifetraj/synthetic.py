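"""Synthetic multi-cohort longitudinal weight data with known truth.

The real cohorts this package was designed around are access-restricted,
so every downstream stage is exercised on data simulated from the exact
model the analysis assumes: a 2-level linear mixed model (measurements
within children) with a nonlinear age trajectory, child-level random
effects for the intercept and every trajectory term, and heteroscedastic
measurement-level noise.  Cohort heterogeneity is expressed through
per-cohort age windows, visit schedules, dropout hazards, covariate
distributions and systematically missing covariates, emulating the
pattern of five birth/school cohorts spanning birth to age 20.

All generation is deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .bases import BasisSpec, basis_matrix
from .harmonize import (
    ETHNICITY_LEVELS,
    MATERNAL_EDUCATION_LEVELS,
    PATERNAL_OCCUPATION_LEVELS,
    PooledDataset,
)
from .variance import Level1VarianceSpec

__all__ = [
    "CohortProfile",
    "TruthParams",
    "MissingnessSpec",
    "generate_cohort",
    "generate_multi_cohort",
    "apply_covariate_missingness",
    "table1_profiles",
    "default_truth",
    "curve_matched_beta",
    "TARGET_CURVE_AGES",
    "TARGET_CURVE_KG",
]

#: Reference mean weight-for-age curve (kg at integer ages 0-20) used to
#: anchor the generating fixed effects at realistic values: ~3.5 kg at
#: birth, ~18.5 kg at 5 y, ~33 kg at 10 y, ~56 kg at 15 y, plateauing
#: around 65 kg by age 20.
TARGET_CURVE_AGES = np.arange(0.0, 20.5, 0.5)
TARGET_CURVE_KG = np.interp(
    TARGET_CURVE_AGES,
    np.arange(21.0),
    np.array(
        [3.5, 10.0, 12.5, 14.5, 16.5, 18.5, 21.0, 23.5, 26.5, 29.5, 33.0,
         37.0, 42.0, 47.0, 52.0, 56.0, 59.0, 61.5, 63.0, 64.0, 65.0]
    ),
)


def _check_distribution(name: str, dist: dict) -> None:
    probs = np.array(list(dist.values()), dtype=float)
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError(f"{name}: probabilities must lie in [0, 1]")
    if abs(probs.sum() - 1.0) > 1e-12:
        raise ValueError(f"{name}: probabilities must sum to 1")


def _uniform(levels) -> dict[str, float]:
    return {lev: 1.0 / len(levels) for lev in levels}


@dataclass(frozen=True)
class CohortProfile:
    """Design of one synthetic cohort.

    ``visit_schedule`` holds target visit ages (years) inside
    ``age_window``; each child's realized ages are the schedule plus
    Gaussian jitter (sd ``schedule_jitter_sd``), clipped to the window.
    ``dropout_hazard_per_visit`` is the per-visit probability that a
    child exits the study (monotone dropout: the failed visit and all
    later ones are lost; the first visit is always recorded).
    ``entry_age_choices`` optionally delays entry: visits before the
    child's drawn entry age are not recorded (school cohorts).
    ``systematically_missing`` covariates are set to missing for every
    child, emulating variables a cohort never measured.
    """

    cohort_label: str
    age_window: tuple[float, float]
    visit_schedule: tuple[float, ...]
    n_children: int
    schedule_jitter_sd: float = 0.0
    dropout_hazard_per_visit: float = 0.0
    sex_ratio: float = 0.5
    single_sex: bool = False
    ethnicity_distribution: dict[str, float] = field(
        default_factory=lambda: {"White European": 1.0}
    )
    education_distribution: dict[str, float] = field(
        default_factory=lambda: _uniform(MATERNAL_EDUCATION_LEVELS)
    )
    occupation_distribution: dict[str, float] = field(
        default_factory=lambda: _uniform(PATERNAL_OCCUPATION_LEVELS)
    )
    entry_age_choices: tuple[tuple[float, float], ...] = ()
    systematically_missing: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        lo, hi = self.age_window
        if not hi > lo:
            raise ValueError("age_window must be non-degenerate")
        if len(self.visit_schedule) == 0:
            raise ValueError("visit_schedule is empty")
        sched = np.asarray(self.visit_schedule, dtype=float)
        if sched.min() < lo - 1e-9 or sched.max() > hi + 1e-9:
            raise ValueError("visit_schedule ages must lie inside age_window")
        object.__setattr__(
            self, "visit_schedule", tuple(float(a) for a in np.sort(sched))
        )
        for p, nm in [(self.sex_ratio, "sex_ratio"),
                      (self.dropout_hazard_per_visit, "dropout_hazard_per_visit")]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{nm} must lie in [0, 1]")
        _check_distribution("ethnicity_distribution", self.ethnicity_distribution)
        _check_distribution("education_distribution", self.education_distribution)
        _check_distribution("occupation_distribution", self.occupation_distribution)
        if self.entry_age_choices:
            _check_distribution(
                "entry_age_choices", dict(self.entry_age_choices)
            )
        if self.n_children < 1:
            raise ValueError("n_children must be positive")
        object.__setattr__(
            self, "systematically_missing", frozenset(self.systematically_missing)
        )


@dataclass(frozen=True)
class TruthParams:
    """Generating parameters of the 2-level growth model.

    ``beta`` holds the fixed effects on the kg scale:

    * ``"intercept"`` — mean weight when all basis columns are zero;
    * ``"basis"`` — coefficients of the trajectory basis columns;
    * ``"cohort"`` — per-cohort intercept offsets (absent label = 0);
    * ``"cohort_basis"`` — per-cohort offsets to the basis coefficients;
    * per-covariate dicts (``"sex"``, ``"ethnicity"``,
      ``"maternal_education"``, ``"paternal_occupation"``) mapping a
      level to its intercept offset (reference levels = 0);
    * ``"interactions"`` — ``(covariate, level) -> basis-coefficient
      offsets``.

    ``G`` is the child-level random-effect covariance (intercept + all
    basis terms; must be symmetric positive semi-definite) and
    ``level1`` / ``level1_values`` give the measurement-level variance.
    """

    basis: BasisSpec
    beta: dict
    G: np.ndarray
    level1: Level1VarianceSpec
    level1_values: tuple[float, ...]

    def __post_init__(self) -> None:
        q = 1 + self.basis.n_columns
        G = np.asarray(self.G, dtype=float)
        if G.shape != (q, q):
            raise ValueError(f"G must be {q}x{q} (intercept + basis terms)")
        if not np.allclose(G, G.T, atol=1e-10):
            raise ValueError("G must be symmetric")
        eigvals = np.linalg.eigvalsh(G)
        if eigvals.min() < -1e-10:
            raise ValueError("G must be positive semi-definite")
        object.__setattr__(self, "G", G)
        vals = np.asarray(self.level1_values, dtype=float)
        if vals.size != self.level1.n_params or np.any(vals < 0):
            raise ValueError("invalid level-1 variance values")
        object.__setattr__(self, "level1_values", tuple(float(v) for v in vals))
        nb = self.basis.n_columns
        b = np.asarray(self.beta.get("basis", np.zeros(nb)), dtype=float)
        if b.size != nb:
            raise ValueError("beta['basis'] length must match basis columns")

    def mean_weight(self, ages, cohort: str, covariates: dict) -> np.ndarray:
        """Population-mean weight at ``ages`` for one child."""
        B = basis_matrix(ages, self.basis)
        coef = np.asarray(self.beta.get("basis", np.zeros(B.shape[1])), float).copy()
        mu = float(self.beta.get("intercept", 0.0))
        mu += float(self.beta.get("cohort", {}).get(cohort, 0.0))
        cb = self.beta.get("cohort_basis", {}).get(cohort)
        if cb is not None:
            coef = coef + np.asarray(cb, dtype=float)
        for cov, level in covariates.items():
            if level is None or (isinstance(level, float) and math.isnan(level)):
                continue
            mu += float(self.beta.get(cov, {}).get(level, 0.0))
            inter = self.beta.get("interactions", {}).get((cov, level))
            if inter is not None:
                coef = coef + np.asarray(inter, dtype=float)
        return mu + B @ coef

    def to_dict(self) -> dict:
        beta = {}
        for key, val in self.beta.items():
            if key == "interactions":
                beta[key] = {
                    f"{cov}|{lev}": np.asarray(v, float).tolist()
                    for (cov, lev), v in val.items()
                }
            elif isinstance(val, dict):
                beta[key] = {
                    k: (np.asarray(v, float).tolist() if np.ndim(v) else float(v))
                    for k, v in val.items()
                }
            elif np.ndim(val):
                beta[key] = np.asarray(val, float).tolist()
            else:
                beta[key] = float(val)
        return {
            "basis": self.basis.to_dict(),
            "beta": beta,
            "G": np.asarray(self.G).tolist(),
            "level1": {"kind": self.level1.kind, "cuts": list(self.level1.cuts)},
            "level1_values": list(self.level1_values),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthParams":
        beta = {}
        for key, val in d["beta"].items():
            if key == "interactions":
                beta[key] = {
                    tuple(k.split("|", 1)): np.asarray(v, float)
                    for k, v in val.items()
                }
            else:
                beta[key] = val
        return cls(
            basis=BasisSpec.from_dict(d["basis"]),
            beta=beta,
            G=np.asarray(d["G"], dtype=float),
            level1=Level1VarianceSpec(
                kind=d["level1"]["kind"], cuts=tuple(d["level1"]["cuts"])
            ),
            level1_values=tuple(d["level1_values"]),
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def read(cls, path) -> "TruthParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _psd_sqrt(G: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(G)
    return V * np.sqrt(np.clip(w, 0.0, None))


def generate_cohort(
    profile: CohortProfile, truth: TruthParams, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort.

    Returns ``(measurements, children)``: a long table of (child_id,
    cohort, age_years, weight_kg) and a one-row-per-child covariate
    table.  Weights are fixed part + child random effects + level-1
    noise; visits follow the jittered schedule truncated by dropout and
    (optionally) late entry.
    """
    rng = np.random.default_rng(seed)
    n = profile.n_children
    label = profile.cohort_label
    ids = [f"{label}-{i:06d}" for i in range(n)]

    sex = np.where(rng.random(n) < profile.sex_ratio, "male", "female")
    if profile.single_sex:
        sex[:] = "male" if profile.sex_ratio >= 0.5 else "female"

    def draw_cat(dist: dict) -> np.ndarray:
        levels = list(dist)
        return rng.choice(levels, size=n, p=[dist[l] for l in levels])

    ethnicity = draw_cat(profile.ethnicity_distribution)
    education = draw_cat(profile.education_distribution)
    occupation = draw_cat(profile.occupation_distribution)

    children = pd.DataFrame(
        {
            "child_id": ids,
            "cohort": label,
            "sex": sex,
            "ethnicity": ethnicity,
            "maternal_education": education,
            "paternal_occupation": occupation,
        }
    )
    for cov in profile.systematically_missing:
        if cov not in children.columns:
            raise ValueError(f"unknown covariate {cov!r} in systematically_missing")
        children[cov] = np.nan

    sched = np.asarray(profile.visit_schedule, dtype=float)
    lo, hi = profile.age_window
    A = _psd_sqrt(truth.G)
    q = truth.G.shape[0]

    if profile.entry_age_choices:
        entry_ages = rng.choice(
            [a for a, _ in profile.entry_age_choices],
            size=n,
            p=[p for _, p in profile.entry_age_choices],
        )
    else:
        entry_ages = np.full(n, -np.inf)

    rows_id, rows_age, rows_wt = [], [], []
    h = profile.dropout_hazard_per_visit
    for i in range(n):
        ages = sched + rng.normal(0.0, profile.schedule_jitter_sd, sched.size)
        ages = np.sort(np.clip(ages, lo, hi))
        ages = ages[ages >= entry_ages[i]]
        if ages.size == 0:
            ages = np.array([max(entry_ages[i], lo)])
        if h > 0 and ages.size > 1:
            fails = rng.random(ages.size - 1) < h
            first_fail = np.argmax(fails) if fails.any() else fails.size
            ages = ages[: first_fail + 1]
        covs = {
            "sex": sex[i],
            "ethnicity": None if "ethnicity" in profile.systematically_missing else ethnicity[i],
            "maternal_education": None
            if "maternal_education" in profile.systematically_missing
            else education[i],
            "paternal_occupation": None
            if "paternal_occupation" in profile.systematically_missing
            else occupation[i],
        }
        mu = truth.mean_weight(ages, label, covs)
        b = A @ rng.standard_normal(q)
        Z = np.column_stack([np.ones(ages.size), basis_matrix(ages, truth.basis)])
        noise_var = truth.level1.variance(ages, truth.level1_values)
        y = mu + Z @ b + rng.standard_normal(ages.size) * np.sqrt(noise_var)
        rows_id.extend([ids[i]] * ages.size)
        rows_age.append(ages)
        rows_wt.append(y)

    measurements = pd.DataFrame(
        {
            "child_id": rows_id,
            "cohort": label,
            "age_years": np.concatenate(rows_age),
            "weight_kg": np.concatenate(rows_wt),
        }
    )
    return measurements, children


def generate_multi_cohort(
    profiles, truth: TruthParams, seed: int
) -> PooledDataset:
    """Simulate several cohorts and pool them.

    Per-cohort seeds are derived deterministically from ``seed``; child
    ids are globally unique (cohort-prefixed).
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least 2 cohort profiles")
    labels = [p.cohort_label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate cohort labels")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(profiles)) % (2**31)
    meas_parts, child_parts = [], []
    for profile, s in zip(profiles, child_seeds):
        m, c = generate_cohort(profile, truth, int(s))
        meas_parts.append(m)
        child_parts.append(c)
    return PooledDataset(
        measurements=pd.concat(meas_parts, ignore_index=True),
        children=pd.concat(child_parts, ignore_index=True),
    )


@dataclass(frozen=True)
class MissingnessSpec:
    """Sporadic MAR missingness mechanism for child-level covariates.

    For each named covariate, the probability that a child's value is
    set to missing is ``logistic(intercept + slope * z)`` where ``z`` is
    the standardized trajectory proxy (e.g. the child's mean observed
    weight), plus an optional per-cohort offset.  A positive slope makes
    heavier-trajectory children more likely to be missing — missingness
    that depends on the *observed outcomes*, the setting multiple
    imputation is designed for.
    """

    rates: dict[str, tuple[float, float]]
    cohort_offsets: dict[tuple[str, str], float] = field(default_factory=dict)


def apply_covariate_missingness(
    children: pd.DataFrame,
    mechanism: MissingnessSpec,
    trajectory_proxy: pd.Series,
    seed: int,
) -> pd.DataFrame:
    """Punch sporadic MAR holes into the child covariate table.

    ``trajectory_proxy`` must be indexed by child_id.  Covariates that
    are already systematically missing are untouched.  Deterministic
    given ``seed``.
    """
    out = children.copy()
    for cov in mechanism.rates:
        if cov not in out.columns:
            raise ValueError(f"unknown covariate {cov!r}")
    proxy = trajectory_proxy.reindex(out["child_id"]).to_numpy(dtype=float)
    if np.any(~np.isfinite(proxy)):
        raise ValueError("trajectory_proxy missing for some children")
    sd = proxy.std()
    z = (proxy - proxy.mean()) / sd if sd > 0 else np.zeros_like(proxy)
    rng = np.random.default_rng(seed)
    for cov, (intercept, slope) in mechanism.rates.items():
        eta = intercept + slope * z
        for (c, cohort), off in mechanism.cohort_offsets.items():
            if c == cov:
                eta = eta + off * (out["cohort"] == cohort).to_numpy()
        p = 1.0 / (1.0 + np.exp(-eta))
        hit = rng.random(len(out)) < p
        out.loc[hit, cov] = np.nan
    return out


def table1_profiles(scale: float = 1.0) -> list[CohortProfile]:
    """Five cohort profiles emulating the real studies' structure.

    Age windows 0-20, 0-5, 0-6, 9-18 and 0-16 years; per-child
    measurement medians from ~5 to ~57; one single-sex cohort; maternal
    education systematically missing in the two oldest cohorts; a
    South-Asian majority only in the inner-city cohort.  ``scale``
    multiplies the per-cohort sample sizes (1.0 = the real cohort n's).
    """

    def n(real: int) -> int:
        return max(2, round(real * scale))

    return [
        CohortProfile(
            cohort_label="ALSPAC",
            age_window=(0.0, 20.0),
            visit_schedule=(0.0, 0.115, 0.83, 1.75, 4.0, 7.0, 8.0, 9.0, 10.0,
                            11.0, 12.0, 13.0, 15.0, 17.0),
            n_children=n(14216),
            schedule_jitter_sd=0.1,
            dropout_hazard_per_visit=0.045,
            ethnicity_distribution={"White European": 0.95, "other": 0.05},
        ),
        CohortProfile(
            cohort_label="BCG",
            age_window=(0.0, 5.0),
            visit_schedule=(0.0, 0.027, 0.115, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0,
                            2.5, 3.0, 3.5, 4.0, 4.5, 5.0),
            n_children=n(951),
            schedule_jitter_sd=0.03,
            dropout_hazard_per_visit=0.008,
            systematically_missing=frozenset({"maternal_education"}),
        ),
        CohortProfile(
            cohort_label="BiB",
            age_window=(0.0, 6.0),
            visit_schedule=(0.0, 0.04, 0.115, 0.67, 4.0, 6.0),
            n_children=n(13445),
            schedule_jitter_sd=0.08,
            dropout_hazard_per_visit=0.06,
            ethnicity_distribution={
                "White European": 0.40,
                "South Asian": 0.52,
                "other": 0.08,
            },
        ),
        CohortProfile(
            cohort_label="CHS",
            age_window=(9.0, 18.0),
            visit_schedule=tuple(np.round(np.arange(9.0, 18.0, 1.0 / 9.0), 4)),
            n_children=n(1547),
            schedule_jitter_sd=0.02,
            dropout_hazard_per_visit=0.002,
            sex_ratio=1.0,
            single_sex=True,
            entry_age_choices=((9.5, 0.47), (11.5, 0.52), (13.2, 0.01)),
            systematically_missing=frozenset({"maternal_education"}),
        ),
        CohortProfile(
            cohort_label="PROBIT",
            age_window=(0.0, 16.0),
            visit_schedule=(0.0, 0.083, 0.167, 0.25, 0.5, 0.75, 1.0, 2.0, 4.0,
                            6.5, 9.0, 11.5, 16.0),
            n_children=n(17046),
            schedule_jitter_sd=0.06,
            dropout_hazard_per_visit=0.01,
        ),
    ]


def curve_matched_beta(basis: BasisSpec) -> tuple[float, np.ndarray]:
    """Intercept + basis coefficients matching the reference curve.

    Least-squares projection of the reference weight-for-age curve onto
    ``[1, basis]``, so any candidate basis generates a realistic mean
    trajectory.
    """
    ages = TARGET_CURVE_AGES
    X = np.column_stack([np.ones(ages.size), basis_matrix(ages, basis)])
    coef, *_ = np.linalg.lstsq(X, TARGET_CURVE_KG, rcond=None)
    return float(coef[0]), coef[1:]


def default_truth(
    basis: BasisSpec | None = None,
    *,
    g_scale: float = 1.0,
    cohort_offsets: dict[str, float] | None = None,
    covariate_effects: dict | None = None,
    interactions: dict | None = None,
    level1: Level1VarianceSpec | None = None,
    level1_values: tuple[float, ...] | None = None,
) -> TruthParams:
    """Default generating truth: a realistic weight-for-age process.

    The default trajectory family is a 5-knot restricted cubic spline
    over 0-20 years; the fixed effects reproduce the reference growth
    curve.  Child-level heterogeneity defaults to an intercept SD of
    1 kg plus trajectory-coefficient SDs calibrated so each trajectory
    term contributes ~0.6 kg RMS deviation over the age range (children
    spread by a few kg in total); level-1 noise defaults to segmented
    variances (0.09 kg^2 below age 2, 2.25 kg^2 above), reflecting the
    far larger measurement scatter in adolescence than infancy.
    """
    if basis is None:
        basis = BasisSpec(family="RCS", knots=(0.5, 2.0, 7.0, 12.0, 17.0))
    intercept, coef = curve_matched_beta(basis)
    q = 1 + basis.n_columns
    # Scale each column's random-effect SD by its RMS magnitude over
    # the reference ages, so heterogeneity is expressed in kg, not in
    # (basis-dependent) coefficient units.
    B = basis_matrix(TARGET_CURVE_AGES, basis)
    rms = np.sqrt(np.mean(B**2, axis=0))
    sds = np.concatenate([[1.0], 0.6 / np.maximum(rms, 1e-6)])
    G = np.diag((sds * math.sqrt(g_scale)) ** 2)
    beta: dict = {"intercept": intercept, "basis": coef}
    if cohort_offsets:
        beta["cohort"] = dict(cohort_offsets)
    if covariate_effects:
        beta.update(covariate_effects)
    if interactions:
        beta["interactions"] = dict(interactions)
    return TruthParams(
        basis=basis,
        beta=beta,
        G=G,
        level1=level1 or Level1VarianceSpec(kind="segmented", cuts=(2.0,)),
        level1_values=level1_values or (0.09, 2.25),
    )
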