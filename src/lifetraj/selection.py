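"""Two-stage trajectory model selection on pooled cohort data.

Fitting every candidate to the full pooled data is impractical, and
selecting within single cohorts is biased toward simple shapes, so
selection runs on a cohort-stratified random subsample of children:

* **Stage 1** chooses the trajectory form among 35 fractional
  polynomials (degrees 1-2 over 7 powers) and restricted cubic splines
  with 3-7 knots, all fitted by ML with individual random effects for
  the intercept and every trajectory term and two independent
  measurement-level variances (ages <=2 and >2 years).  The top
  candidates per family (by AIC/BIC) are then adjudicated by mean
  squared prediction error on the held-out validation children, under
  the one-standard-error rule so statistically indistinguishable
  predictors resolve to the most parsimonious.
* **Stage 2** keeps the winning trajectory and chooses the
  measurement-level covariance structure by REML.

The summed-likelihood alternative (fit the same model separately per
cohort, add the likelihoods) is provided for comparison; it fails by
construction for splines whose knots fall outside a cohort's age range,
which is why the random-sample route is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bases import BasisSpec, enumerate_fp_candidates, rcs_knots
from .harmonize import PooledDataset
from .lmm import (
    Covariate,
    FitResult,
    ModelSpec,
    fit,
    information_criteria,
    mspe,
    prediction_squared_errors,
)
from .variance import Level1VarianceSpec

__all__ = [
    "SelectionConfig",
    "SelectionReport",
    "split_sample",
    "stage1_select",
    "stage2_select",
    "two_stage_select",
    "summed_likelihood",
    "prune_unsupported_interactions",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Settings for the data-splitting selection procedure.

    ``n_select`` children enter the selection sample (default 15,000),
    drawn so each cohort's share matches its share of the pooled data
    (largest-remainder rounding).  ``criterion`` ranks candidates
    within family; the shortlist (``top_k_per_family`` each) is then
    compared on validation MSPE.
    """

    n_select: int = 15000
    stratify_by_cohort: bool = True
    criterion: str = "BIC"
    top_k_per_family: int = 2
    seed: int = 0
    rcs_knot_counts: tuple[int, ...] = (3, 4, 5, 6, 7)
    cohort_effects: str = "main"
    stage1_level1: Level1VarianceSpec = field(
        default_factory=lambda: Level1VarianceSpec(kind="segmented", cuts=(2.0,))
    )
    fit_max_iter: int = 150
    fit_em_iter: int = 20

    def __post_init__(self) -> None:
        if self.criterion not in ("AIC", "BIC"):
            raise ValueError("criterion must be AIC or BIC")
        if self.top_k_per_family < 1:
            raise ValueError("top_k_per_family must be >= 1")


@dataclass
class SelectionReport:
    """Everything the two-stage procedure decided and why."""

    candidates: pd.DataFrame
    shortlist: list[str]
    validation_mspe: pd.DataFrame
    winner: BasisSpec
    winner_label: str
    stage2_table: pd.DataFrame | None = None
    final_spec: ModelSpec | None = None


def split_sample(
    data: PooledDataset, config: SelectionConfig
) -> tuple[PooledDataset, PooledDataset]:
    """Child-level selection/validation split, stratified by cohort.

    All of a child's measurements travel together.  Per-cohort counts
    follow largest-remainder rounding of proportional quotas, so they
    match cohort shares to within one child.
    """
    kids = data.children
    total = len(kids)
    if config.n_select >= total:
        raise ValueError("n_select must be smaller than the pooled child count")
    rng = np.random.default_rng(config.seed)
    cohorts = sorted(kids["cohort"].unique())
    if config.stratify_by_cohort:
        sizes = {c: int((kids["cohort"] == c).sum()) for c in cohorts}
        quotas = {c: config.n_select * sizes[c] / total for c in cohorts}
        base = {c: int(np.floor(quotas[c])) for c in cohorts}
        short = config.n_select - sum(base.values())
        remainders = sorted(
            cohorts, key=lambda c: (-(quotas[c] - base[c]), -sizes[c], c)
        )
        for c in remainders[:short]:
            base[c] += 1
        chosen = []
        for c in cohorts:
            if base[c] == 0:
                warnings.warn(f"cohort {c!r} allocated 0 selection children")
            ids = np.sort(kids.loc[kids["cohort"] == c, "child_id"].to_numpy())
            chosen.append(rng.choice(ids, size=base[c], replace=False))
        sel_ids = set(np.concatenate(chosen))
    else:
        ids = np.sort(kids["child_id"].to_numpy())
        sel_ids = set(rng.choice(ids, size=config.n_select, replace=False))

    in_sel = kids["child_id"].isin(sel_ids)
    meas_sel = data.measurements["child_id"].isin(sel_ids)

    def _subset(kmask, mmask):
        return PooledDataset(
            measurements=data.measurements[mmask].reset_index(drop=True),
            children=kids[kmask].reset_index(drop=True),
        )

    return _subset(in_sel, meas_sel), _subset(~in_sel, ~meas_sel)


def _candidate_bases(
    selection: PooledDataset, config: SelectionConfig
) -> list[BasisSpec]:
    cands = enumerate_fp_candidates()
    ages = selection.measurements["age_years"].to_numpy()
    for k in config.rcs_knot_counts:
        try:
            cands.append(BasisSpec(family="RCS", knots=rcs_knots(ages, k)))
        except ValueError as err:
            warnings.warn(f"RCS with {k} knots skipped: {err}")
    return cands


def stage1_select(
    data: PooledDataset, config: SelectionConfig
) -> tuple[SelectionReport, PooledDataset, PooledDataset]:
    """Stage 1: choose the trajectory form.

    Fits every FP and RCS candidate by ML on the selection sample
    (random effects: intercept + trajectory terms; level 1: the stage-1
    two-segment structure), shortlists the best ``top_k_per_family``
    per family by the configured criterion (re-polishing near-top
    non-converged fits first), and adjudicates the shortlist on
    validation MSPE under the one-standard-error rule: the most
    parsimonious candidate within one paired SE of the minimum wins
    (then fewer parameters, then candidate order).  Returns the
    partial report plus the two data splits for reuse in stage 2.
    """
    selection, validation = split_sample(data, config)
    rows = []
    fits: dict[str, tuple[BasisSpec, FitResult]] = {}
    for cand in _candidate_bases(selection, config):
        spec = ModelSpec(
            trajectory=cand,
            cohort_effects=config.cohort_effects,
            level1=config.stage1_level1,
        )
        label = cand.label()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fr = fit(
                    spec,
                    selection,
                    method="ML",
                    tol=1e-8,
                    max_iter=config.fit_max_iter,
                    em_iter=config.fit_em_iter,
                )
        except (ValueError, np.linalg.LinAlgError) as err:
            warnings.warn(f"candidate {label} failed to fit: {err}")
            continue
        aic, bic = information_criteria(fr)
        rows.append(
            {
                "candidate": label,
                "family": cand.family,
                "loglik": fr.loglik,
                "AIC": aic,
                "BIC": bic,
                "n_params": fr.n_params,
                "converged": fr.converged,
            }
        )
        fits[label] = (cand, fr)
    table = pd.DataFrame(rows).set_index("candidate", drop=False)
    if not fits:
        raise RuntimeError("no stage-1 candidate could be fitted")
    # Polish pass: candidates near the top of their family's criterion
    # ranking that have not converged under the (possibly capped)
    # stage-1 budget are refitted from their own warm start with a full
    # budget, so the shortlist compares settled optima.
    for family in ("FP", "RCS"):
        fam = table[table["family"] == family].sort_values(
            [config.criterion, "n_params"]
        )
        for label in fam["candidate"].head(config.top_k_per_family + 1):
            cand, fr = fits[label]
            if fr.converged:
                continue
            spec = ModelSpec(
                trajectory=cand,
                cohort_effects=config.cohort_effects,
                level1=config.stage1_level1,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fr = fit(
                    spec, selection, method="ML", tol=1e-9,
                    init=fr.theta, max_iter=300, em_iter=0,
                )
            fits[label] = (cand, fr)
            aic, bic = information_criteria(fr)
            table.loc[label, ["loglik", "AIC", "BIC", "converged"]] = (
                fr.loglik, aic, bic, fr.converged
            )
    # Shortlist: top-k per family by criterion among converged fits;
    # non-converged fill in only when a family lacks converged ones.
    shortlist: list[str] = []
    for family in ("FP", "RCS"):
        fam = table[table["family"] == family].sort_values(
            [config.criterion, "n_params"]
        )
        chosen = list(fam.loc[fam["converged"], "candidate"].head(
            config.top_k_per_family
        ))
        if len(chosen) < config.top_k_per_family:
            warnings.warn(
                f"stage-1 shortlist for {family} includes fits that did "
                "not reach the convergence criterion"
            )
            extra = [c for c in fam["candidate"] if c not in chosen]
            chosen += extra[: config.top_k_per_family - len(chosen)]
        shortlist.extend(chosen)
    # Validation adjudication with the one-standard-error rule: among
    # shortlisted candidates whose MSPE is within one (paired) SE of
    # the minimum, the most parsimonious wins.  Flexible splines and a
    # well-chosen fractional polynomial often predict near-identically;
    # a raw argmin would pick between them by noise.
    errors = {
        label: prediction_squared_errors(fits[label][1], validation)
        for label in shortlist
    }
    means = {label: float(np.mean(e)) for label, e in errors.items()}
    best_label = min(means, key=means.get)
    mspe_rows = []
    for label in shortlist:
        diff = errors[label] - errors[best_label]
        se = float(diff.std(ddof=1) / np.sqrt(diff.size)) if label != best_label else 0.0
        mspe_rows.append(
            {
                "candidate": label,
                "mspe": means[label],
                "se_vs_best": se,
                "within_1se": means[label] - means[best_label] <= se,
                "n_params": fits[label][1].n_params,
            }
        )
    mspe_table = pd.DataFrame(mspe_rows).sort_values(
        ["mspe", "n_params"]
    ).reset_index(drop=True)
    qualifiers = mspe_table[mspe_table["within_1se"]]
    winner_label = qualifiers.sort_values("n_params").iloc[0]["candidate"]
    report = SelectionReport(
        candidates=table.reset_index(drop=True),
        shortlist=shortlist,
        validation_mspe=mspe_table,
        winner=fits[winner_label][0],
        winner_label=winner_label,
    )
    return report, selection, validation


def stage2_select(
    winner_trajectory: BasisSpec,
    data: PooledDataset,
    candidates: list[Level1VarianceSpec] | None = None,
    config: SelectionConfig | None = None,
) -> tuple[Level1VarianceSpec, pd.DataFrame]:
    """Stage 2: choose the level-1 covariance structure by REML.

    Candidates differ only in their covariance structure (fixed effects
    are identical), so REML-based criteria are valid.  Ties break to
    fewer parameters, then candidate order.
    """
    config = config or SelectionConfig()
    if candidates is None:
        candidates = [
            Level1VarianceSpec(kind="segmented", cuts=(2.0,)),
            Level1VarianceSpec(kind="age_linear"),
        ]
    rows = []
    best = None
    best_any = None
    for i, lv in enumerate(candidates):
        spec = ModelSpec(
            trajectory=winner_trajectory,
            cohort_effects=config.cohort_effects,
            level1=lv,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fr = fit(
                spec,
                data,
                method="REML",
                tol=1e-8,
                # only a couple of candidates here, so stage 2 gets a
                # full iteration budget even when stage 1 was capped
                max_iter=max(150, config.fit_max_iter),
                em_iter=max(15, config.fit_em_iter),
            )
        aic, bic = information_criteria(fr)
        crit = aic if config.criterion == "AIC" else bic
        rows.append(
            {
                "level1": f"{lv.kind}{list(lv.cuts) if lv.kind == 'segmented' else ''}",
                "loglik": fr.loglik,
                "AIC": aic,
                "BIC": bic,
                "n_params": fr.n_params,
                "converged": fr.converged,
            }
        )
        key = (crit, fr.n_params, i)
        if best_any is None or key < best_any[0]:
            best_any = (key, lv)
        if fr.converged and (best is None or key < best[0]):
            best = (key, lv)
    if best is None:
        warnings.warn(
            "no stage-2 candidate reached the convergence criterion; "
            "ranking the fits as returned"
        )
        best = best_any
    return best[1], pd.DataFrame(rows)


def two_stage_select(
    data: PooledDataset,
    config: SelectionConfig,
    stage2_candidates: list[Level1VarianceSpec] | None = None,
) -> SelectionReport:
    """Run both stages and assemble the final model specification."""
    report, selection, _ = stage1_select(data, config)
    level1, table = stage2_select(
        report.winner, selection, stage2_candidates, config
    )
    report.stage2_table = table
    report.final_spec = ModelSpec(
        trajectory=report.winner,
        cohort_effects=config.cohort_effects,
        level1=level1,
    )
    return report


def summed_likelihood(
    spec: ModelSpec, data: PooledDataset
) -> tuple[float, float]:
    """Fit ``spec`` separately per cohort and sum the ML likelihoods.

    The AIC penalty counts the full per-cohort parameter set once per
    cohort.  RCS specs whose knots fall outside any single cohort's age
    range cannot be fitted per cohort and raise — the structural
    limitation that motivates the random-sample approach.
    """
    cohorts = sorted(data.children["cohort"].unique())
    if spec.trajectory.family == "RCS":
        knots = spec.trajectory.knots
        for c in cohorts:
            ages = data.measurements.loc[
                data.measurements["cohort"] == c, "age_years"
            ]
            if knots[0] < ages.min() or knots[-1] > ages.max():
                raise ValueError(
                    f"not fittable per cohort: RCS knots {knots} fall outside "
                    f"cohort {c!r}'s age range [{ages.min():g}, {ages.max():g}]"
                )
    per_cohort_spec = ModelSpec(
        trajectory=spec.trajectory,
        covariates=spec.covariates,
        cohort_effects="none",
        level1=spec.level1,
        dropped_interactions=spec.dropped_interactions,
    )
    total_ll = 0.0
    total_params = 0
    for c in cohorts:
        mask_k = data.children["cohort"] == c
        mask_m = data.measurements["cohort"] == c
        sub = PooledDataset(
            measurements=data.measurements[mask_m].reset_index(drop=True),
            children=data.children[mask_k].reset_index(drop=True),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fr = fit(per_cohort_spec, sub, method="ML")
        total_ll += fr.loglik
        total_params += fr.n_params
    return total_ll, -2.0 * total_ll + 2.0 * total_params


def prune_unsupported_interactions(
    spec: ModelSpec,
    data: PooledDataset,
    min_children: int = 30,
    min_measurements: int = 100,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Drop covariate x trajectory interactions the data cannot support.

    For each covariate level and trajectory column, children and
    measurements with that level are counted inside the column's
    support region (for RCS column ``rcs_j``: ages above knot ``k_j``,
    where the column becomes active; FP columns span the whole range).
    Interactions below either threshold are dropped and logged —
    e.g. an ethnic group observed only in an early-childhood cohort
    crossed with spline terms that only act at older ages.
    """
    kids = data.children.set_index("child_id")
    meas = data.measurements
    ages = meas["age_years"].to_numpy()
    bnames = spec.trajectory.column_names()
    log_rows = []
    dropped = set(spec.dropped_interactions)
    interacted = [c for c in spec.covariates if c.interact]
    if spec.cohort_effects == "interactions":
        interacted = [Covariate("cohort"), *interacted]
    for cov in interacted:
        if cov.name == "cohort":
            values = meas["cohort"].to_numpy()
            levels = sorted(pd.unique(meas["cohort"]))
        else:
            values = kids[cov.name].reindex(meas["child_id"]).to_numpy()
            levels = [l for l in pd.unique(kids[cov.name].dropna())]
        for level in levels:
            lv_mask = values == level
            for j, nm in enumerate(bnames):
                if spec.trajectory.family == "RCS" and j >= 1:
                    support = ages > spec.trajectory.knots[j - 1]
                else:
                    support = np.ones(ages.size, dtype=bool)
                mask = lv_mask & support
                n_meas = int(mask.sum())
                n_kids = int(pd.unique(meas.loc[mask, "child_id"]).size)
                drop = n_kids < min_children or n_meas < min_measurements
                log_rows.append(
                    {
                        "covariate": cov.name,
                        "level": level,
                        "column": nm,
                        "n_children": n_kids,
                        "n_measurements": n_meas,
                        "dropped": drop,
                    }
                )
                if drop:
                    dropped.add((cov.name, level, nm))
    new_spec = ModelSpec(
        trajectory=spec.trajectory,
        covariates=spec.covariates,
        cohort_effects=spec.cohort_effects,
        level1=spec.level1,
        dropped_interactions=frozenset(dropped),
    )
    return new_spec, pd.DataFrame(log_rows)
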