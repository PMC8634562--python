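"""Harmonization and pooling of heterogeneous cohort data.

Different cohorts record the "same" variable differently (local
ethnicity codes, country- and era-specific school qualifications,
occupational classifications).  This module maps raw cohort-specific
categories onto a shared harmonized vocabulary via user-supplied mapping
tables, converts measurement units, derives the composite parental
education x occupation variable, pools the cohorts into one long table,
and produces the audit counts (pooled totals and the complete-covariate
discard report) that quantify what a complete-covariate analysis would
throw away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SEX_LEVELS",
    "ETHNICITY_LEVELS",
    "MATERNAL_EDUCATION_LEVELS",
    "PATERNAL_OCCUPATION_LEVELS",
    "HARMONIZED_VOCABULARY",
    "MISSING",
    "MappingTable",
    "PooledDataset",
    "PoolingAudit",
    "DiscardReport",
    "harmonize_variable",
    "convert_units",
    "derive_parental_composite",
    "pool_cohorts",
    "complete_covariate_filter",
]

#: Sentinel for a missing harmonized category (NaN in DataFrames,
#: empty string on disk).
MISSING = None

SEX_LEVELS = ("male", "female")
ETHNICITY_LEVELS = ("White European", "South Asian", "other")
MATERNAL_EDUCATION_LEVELS = (
    "left school 15-16",
    "left school 17-18",
    "degree or higher",
)
PATERNAL_OCCUPATION_LEVELS = (
    "professional/managerial",
    "intermediate",
    "routine/unskilled",
)

HARMONIZED_VOCABULARY: dict[str, tuple[str, ...]] = {
    "sex": SEX_LEVELS,
    "ethnicity": ETHNICITY_LEVELS,
    "maternal_education": MATERNAL_EDUCATION_LEVELS,
    "paternal_occupation": PATERNAL_OCCUPATION_LEVELS,
}

CHILD_COVARIATES = ("sex", "ethnicity", "maternal_education", "paternal_occupation")

_WEIGHT_FACTORS = {"g": 1e-3, "kg": 1.0, "lb": 0.45359237}
_AGE_FACTORS = {
    "days": 1.0 / 365.25,
    "weeks": 7.0 / 365.25,
    "months": 1.0 / 12.0,
    "years": 1.0,
}


@dataclass(frozen=True)
class MappingTable:
    """Raw-to-harmonized category mapping for one cohort x variable.

    ``entries`` maps raw categories to harmonized categories.  Raw
    values absent from ``entries`` fall back to ``default`` (a
    harmonized category, or ``None`` for missing).  ``constant_fill``
    overrides everything: every child receives that harmonized value
    regardless of the raw input — used e.g. for cohorts that never
    recorded ethnicity but were recruited from a single-ethnicity
    population.
    """

    cohort: str
    variable: str
    entries: dict[str, str] = field(default_factory=dict)
    default: str | None = None
    constant_fill: str | None = None

    def __post_init__(self) -> None:
        vocab = HARMONIZED_VOCABULARY.get(self.variable)
        if vocab is None:
            raise ValueError(f"unknown harmonized variable {self.variable!r}")
        targets = set(self.entries.values())
        if self.default is not None:
            targets.add(self.default)
        if self.constant_fill is not None:
            targets.add(self.constant_fill)
        bad = targets - set(vocab)
        if bad:
            raise ValueError(
                f"mapping targets {sorted(bad)} outside the harmonized "
                f"vocabulary for {self.variable!r}"
            )


def harmonize_variable(raw_values, table: MappingTable) -> pd.Series:
    """Map raw categories to the harmonized vocabulary.

    Returns a Series of harmonized categories (NaN = missing).  A
    warning is emitted when more than 10% of non-null raw values fall
    through to the default.
    """
    raw = pd.Series(raw_values, dtype="object")
    if table.constant_fill is not None:
        return pd.Series([table.constant_fill] * len(raw), index=raw.index)
    out = raw.map(table.entries)
    unmapped = out.isna() & raw.notna()
    if table.default is not None:
        out[unmapped] = table.default
    n_raw = int(raw.notna().sum())
    if n_raw and int(unmapped.sum()) > 0.10 * n_raw:
        warnings.warn(
            f"{table.cohort}/{table.variable}: "
            f"{int(unmapped.sum())}/{n_raw} raw values hit the default mapping",
            stacklevel=2,
        )
    return out


def convert_units(value, from_unit: str):
    """Convert weight to kilograms or age to years.

    Grams, kilograms and pounds convert to kg; days, weeks, months and
    years convert to years (1 year = 365.25 days).
    """
    v = np.asarray(value, dtype=float)
    if np.any(~np.isfinite(v)) or np.any(v < 0):
        raise ValueError("values must be finite and non-negative")
    if from_unit in _WEIGHT_FACTORS:
        out = v * _WEIGHT_FACTORS[from_unit]
    elif from_unit in _AGE_FACTORS:
        out = v * _AGE_FACTORS[from_unit]
    else:
        raise ValueError(f"unknown unit {from_unit!r}")
    return float(out) if np.isscalar(value) else out


def derive_parental_composite(maternal_education, paternal_occupation) -> pd.Series:
    """Cross-classify maternal education with paternal occupation.

    Returns the 9-level composite ``"<education> x <occupation>"``;
    missing whenever either component is missing.
    """
    me = pd.Series(maternal_education, dtype="object")
    po = pd.Series(paternal_occupation, dtype="object").reindex(me.index)
    bad_me = me.dropna()[~me.dropna().isin(MATERNAL_EDUCATION_LEVELS)]
    bad_po = po.dropna()[~po.dropna().isin(PATERNAL_OCCUPATION_LEVELS)]
    if len(bad_me) or len(bad_po):
        raise ValueError(
            "unharmonized categories: "
            f"{sorted(set(bad_me)) + sorted(set(bad_po))}"
        )
    out = me.str.cat(po, sep=" x ")
    out[me.isna() | po.isna()] = np.nan
    return out


@dataclass
class PoolingAudit:
    """Per-cohort and total counts after pooling."""

    children_per_cohort: dict[str, int]
    measurements_per_cohort: dict[str, int]

    @property
    def total_children(self) -> int:
        return sum(self.children_per_cohort.values())

    @property
    def total_measurements(self) -> int:
        return sum(self.measurements_per_cohort.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cohort": c,
                "children": self.children_per_cohort[c],
                "measurements": self.measurements_per_cohort.get(c, 0),
            }
            for c in self.children_per_cohort
        ]
        rows.append(
            {
                "cohort": "TOTAL",
                "children": self.total_children,
                "measurements": self.total_measurements,
            }
        )
        return pd.DataFrame(rows)


@dataclass
class PooledDataset:
    """Pooled long measurement table + one-row-per-child covariate table.

    ``measurements`` columns: child_id, cohort, age_years, weight_kg.
    ``children`` columns: child_id, cohort, sex, ethnicity,
    maternal_education, paternal_occupation (NaN = missing).
    """

    measurements: pd.DataFrame
    children: pd.DataFrame

    def write(self, measurements_path, children_path) -> None:
        self.measurements.to_csv(measurements_path, index=False, na_rep="")
        self.children.to_csv(children_path, index=False, na_rep="")

    @classmethod
    def read(cls, measurements_path, children_path) -> "PooledDataset":
        meas = pd.read_csv(measurements_path, keep_default_na=False, na_values=[""])
        kids = pd.read_csv(children_path, keep_default_na=False, na_values=[""])
        meas["age_years"] = meas["age_years"].astype(float)
        meas["weight_kg"] = meas["weight_kg"].astype(float)
        return cls(measurements=meas, children=kids)


def pool_cohorts(per_cohort_tables) -> tuple[PooledDataset, PoolingAudit]:
    """Concatenate harmonized per-cohort tables into one dataset.

    ``per_cohort_tables`` is a list of ``(measurements, children)``
    DataFrame pairs, one per cohort.  Child ids are qualified with the
    cohort label so they are globally unique.
    """
    labels = []
    meas_parts, child_parts = [], []
    kids_count: dict[str, int] = {}
    meas_count: dict[str, int] = {}
    for meas, kids in per_cohort_tables:
        cohorts = set(kids["cohort"].unique()) | set(meas["cohort"].unique())
        if len(cohorts) != 1:
            raise ValueError("each input table pair must hold exactly one cohort")
        label = cohorts.pop()
        if label in kids_count:
            raise ValueError(f"duplicate cohort label {label!r}")
        if kids["child_id"].duplicated().any():
            raise ValueError(f"duplicate child ids within cohort {label!r}")
        labels.append(label)
        kids_count[label] = len(kids)
        meas_count[label] = len(meas)
        meas = meas.copy()
        kids = kids.copy()
        meas["child_id"] = label + ":" + meas["child_id"].astype(str)
        kids["child_id"] = label + ":" + kids["child_id"].astype(str)
        meas_parts.append(meas)
        child_parts.append(kids)
    pooled = PooledDataset(
        measurements=pd.concat(meas_parts, ignore_index=True),
        children=pd.concat(child_parts, ignore_index=True),
    )
    return pooled, PoolingAudit(kids_count, meas_count)


def audit_pooled(pooled: PooledDataset) -> PoolingAudit:
    """Audit counts for an already-pooled dataset."""
    return PoolingAudit(
        children_per_cohort=pooled.children.groupby("cohort").size().to_dict(),
        measurements_per_cohort=pooled.measurements.groupby("cohort")
        .size()
        .to_dict(),
    )


@dataclass
class DiscardReport:
    """What a complete-covariate analysis would discard."""

    covariates: tuple[str, ...]
    discarded_per_cohort: dict[str, int]
    children_per_cohort: dict[str, int]
    systematically_missing_cohorts: dict[str, tuple[str, ...]]

    @property
    def total_discarded(self) -> int:
        return sum(self.discarded_per_cohort.values())

    @property
    def systematically_discarded(self) -> int:
        """Children in cohorts where some covariate is 100% missing."""
        return sum(
            self.children_per_cohort[c] for c in self.systematically_missing_cohorts
        )

    @property
    def total_children(self) -> int:
        return sum(self.children_per_cohort.values())

    @property
    def discarded_fraction_pct(self) -> float:
        """Discarded share of pooled children, percent, 1 decimal."""
        return round(100.0 * self.total_discarded / self.total_children, 1)


def complete_covariate_filter(
    pooled: PooledDataset, covariates
) -> tuple[PooledDataset, DiscardReport]:
    """Restrict to children with every listed covariate observed.

    Returns the restricted dataset and a report of the per-cohort and
    total discard counts, flagging cohorts where a covariate was
    systematically (100%) missing.
    """
    covariates = tuple(covariates)
    kids = pooled.children
    for c in covariates:
        if c not in kids.columns:
            raise ValueError(f"covariate {c!r} not in the child table")
    complete = kids[list(covariates)].notna().all(axis=1)
    discarded = (
        kids.loc[~complete].groupby("cohort").size().to_dict()
        if (~complete).any()
        else {}
    )
    per_cohort = kids.groupby("cohort").size().to_dict()
    sys_missing: dict[str, tuple[str, ...]] = {}
    for cohort, grp in kids.groupby("cohort"):
        fully = tuple(c for c in covariates if grp[c].isna().all())
        if fully:
            sys_missing[cohort] = fully
    keep_ids = set(kids.loc[complete, "child_id"])
    subset = PooledDataset(
        measurements=pooled.measurements[
            pooled.measurements["child_id"].isin(keep_ids)
        ].reset_index(drop=True),
        children=kids.loc[complete].reset_index(drop=True),
    )
    report = DiscardReport(
        covariates=covariates,
        discarded_per_cohort={c: int(discarded.get(c, 0)) for c in per_cohort},
        children_per_cohort={c: int(n) for c, n in per_cohort.items()},
        systematically_missing_cohorts=sys_missing,
    )
    return subset, report
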