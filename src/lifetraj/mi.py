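"""Iterative multiple imputation of child-level categorical covariates.

Covariates such as maternal education can be missing sporadically
(individual non-response) or systematically (a cohort never measured
them).  Standard single-level MI is uncongenial with a multilevel
analysis model whose residual variance changes with age, so imputation
here works from child-specific **trajectory summaries**: the
empirical-Bayes random-effect predictions of the analysis model itself.
Because the same model generates the summaries, the imputation model
automatically respects the analysis model's interactions.

One imputation runs an iterative loop: fit the analysis model to the
current completed data; compute each child's EB summaries; regress each
incomplete covariate on the other covariates, identifiable cohort
indicators and the summaries (multinomial logistic); draw coefficients
from their asymptotic normal distribution and then draw the missing
categories.  ``M`` independent imputations are pooled by Rubin's rules.

Cohorts where a covariate is systematically missing contribute no
information about that covariate's relationship to the predictors, so
their cohort indicators are dropped from that covariate's imputation
model and the covariate-summary relationship is borrowed from the
observed cohorts — the only identifiable MAR-consistent choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .harmonize import PooledDataset
from .lmm import FitResult, ModelSpec, eb_random_effects, fit

__all__ = [
    "MIConfig",
    "PooledEstimate",
    "impute_once",
    "multiple_impute",
    "pool_rubin",
    "mi_analysis",
]


@dataclass(frozen=True)
class MIConfig:
    """Multiple-imputation settings.

    ``m`` imputed datasets (default 25); ``n_cycles`` iterations of the
    fit -> summarize -> impute loop per imputation (default 10);
    covariates are imputed in ``imputation_order``.
    """

    m: int = 25
    n_cycles: int = 10
    imputation_order: tuple[str, ...] = (
        "ethnicity",
        "maternal_education",
        "paternal_occupation",
    )
    seed: int = 0
    fit_method: str = "REML"
    ridge: float = 1e-5
    fit_max_iter: int = 200
    fit_em_iter: int = 15

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2 (Rubin's rules need between-variance)")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


# ---------------------------------------------------------------------------
# Multinomial logistic imputation model


def _mnlogit_nll_grad(theta, X, Y, ridge):
    """Negative log-likelihood and gradient; reference category 0."""
    n, p = X.shape
    k1 = Y.shape[1]  # non-reference categories
    B = theta.reshape(k1, p)
    eta = X @ B.T                              # (n, k1)
    mx = np.maximum(eta.max(axis=1), 0.0)
    lse = mx + np.log(np.exp(-mx) + np.exp(eta - mx[:, None]).sum(axis=1))
    nll = lse.sum() - (eta * Y).sum() + 0.5 * ridge * (theta @ theta)
    P = np.exp(eta - lse[:, None])             # (n, k1)
    grad = ((P - Y).T @ X).ravel() + ridge * theta
    return nll, grad


def _mnlogit_hessian(theta, X, ridge):
    n, p = X.shape
    k1 = theta.size // p
    B = theta.reshape(k1, p)
    eta = X @ B.T
    mx = np.maximum(eta.max(axis=1), 0.0)
    lse = mx + np.log(np.exp(-mx) + np.exp(eta - mx[:, None]).sum(axis=1))
    P = np.exp(eta - lse[:, None])
    H = np.zeros((k1 * p, k1 * p))
    for a in range(k1):
        for b in range(a, k1):
            w = P[:, a] * ((a == b) - P[:, b])
            blk = (X * w[:, None]).T @ X
            H[a * p:(a + 1) * p, b * p:(b + 1) * p] = blk
            if a != b:
                H[b * p:(b + 1) * p, a * p:(a + 1) * p] = blk
    H[np.diag_indices_from(H)] += ridge
    return H


def _fit_mnlogit(X, y_codes, n_cat, ridge=1e-5, max_iter=200):
    """Multinomial logistic fit returning (coef, coef_covariance).

    ``coef`` has shape (n_cat - 1, p), reference category 0.  A ridge
    penalty stabilizes separation; when the optimizer fails or the
    Hessian is near-singular the fit is retried with a stronger ridge.
    """
    n, p = X.shape
    Y = np.zeros((n, n_cat - 1))
    for k in range(1, n_cat):
        Y[:, k - 1] = y_codes == k
    for lam in (ridge, 1e-2, 1.0):
        theta0 = np.zeros((n_cat - 1) * p)
        res = optimize.minimize(
            _mnlogit_nll_grad,
            theta0,
            args=(X, Y, lam),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter},
        )
        H = _mnlogit_hessian(res.x, X, lam)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = None
        separated = np.abs(res.x).max() > 30.0 or (
            cov is not None and np.diag(cov).max() > 1e4
        )
        if res.success and cov is not None and np.all(np.isfinite(cov)) and not separated:
            if lam > ridge:
                warnings.warn(
                    f"imputation model ridge-stabilized (lambda={lam:g})"
                )
            return res.x.reshape(n_cat - 1, p), cov
    raise RuntimeError("multinomial imputation model failed to fit")


def _mnlogit_probs(coef, X):
    eta = np.column_stack([np.zeros(X.shape[0]), X @ coef.T])
    eta -= eta.max(axis=1, keepdims=True)
    P = np.exp(eta)
    return P / P.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Iterative imputation


def _dummies(values: pd.Series, levels: list) -> np.ndarray:
    return np.column_stack([(values == l).to_numpy(float) for l in levels[1:]]) \
        if len(levels) > 1 else np.empty((len(values), 0))


def _imputation_design(
    children: pd.DataFrame,
    target: str,
    others: list[str],
    summaries: pd.DataFrame,
    identifiable_cohorts: list[str],
):
    """Predictor matrix for one covariate's imputation model, plus the
    predictor names (for congeniality inspection)."""
    n = len(children)
    cols = [np.ones(n)]
    names = ["const"]
    for cov in others:
        levels = sorted(children[cov].dropna().unique())
        d = _dummies(children[cov], levels)
        cols.append(d)
        names.extend(f"{cov}[{l}]" for l in levels[1:])
    for c in identifiable_cohorts[1:]:
        cols.append(((children["cohort"] == c).to_numpy(float))[:, None])
        names.append(f"cohort[{c}]")
    summ = summaries.set_index("child_id").reindex(children["child_id"])
    scols = [c for c in summ.columns]
    s = summ.to_numpy(float)
    mu, sd = s.mean(axis=0), s.std(axis=0)
    sd[sd == 0] = 1.0
    cols.append((s - mu) / sd)
    names.extend(f"z_{c}" for c in scols)
    X = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])
    return X, names


def impute_once(
    data: PooledDataset,
    analysis_spec: ModelSpec,
    config: MIConfig,
    seed: int,
    return_details: bool = False,
):
    """One completed dataset from the iterative trajectory-summary
    procedure (deterministic given ``seed``).

    Missing values are initialized from observed within-cohort category
    frequencies (pooled frequencies where a cohort observed none); each
    cycle refits the analysis model, recomputes EB summaries, refits
    each covariate's multinomial imputation model among children with
    that covariate observed, draws coefficients from their asymptotic
    normal distribution, and redraws the missing categories.
    """
    rng = np.random.default_rng(seed)
    children = data.children.copy()
    analysis_covs = [c.name for c in analysis_spec.covariates]
    targets = [
        c for c in config.imputation_order
        if c in children.columns and children[c].isna().any()
    ]
    miss_mask = {c: children[c].isna().to_numpy() for c in targets}
    if not targets:
        return (data, {"targets": []}) if return_details else data

    # (0) frequency-based initialization
    for cov in targets:
        obs = children[cov].dropna()
        pooled_levels = sorted(obs.unique())
        pooled_freq = obs.value_counts(normalize=True)
        for cohort, grp in children.groupby("cohort"):
            idx = grp.index[grp[cov].isna()]
            if len(idx) == 0:
                continue
            local = grp[cov].dropna()
            freq = local.value_counts(normalize=True) if len(local) else pooled_freq
            levels = list(freq.index)
            children.loc[idx, cov] = rng.choice(
                levels, size=len(idx), p=freq.to_numpy()
            )

    theta = None
    details: dict = {"targets": targets, "predictors": {}, "coef_trace": []}
    completed = PooledDataset(measurements=data.measurements, children=children)
    for cycle in range(config.n_cycles):
        # (1) fit the full analysis model to the current completed data
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fr = fit(
                analysis_spec,
                completed,
                method=config.fit_method,
                init=theta,
                max_iter=config.fit_max_iter,
                em_iter=config.fit_em_iter if theta is None else 0,
            )
        if not fr.converged and theta is not None:
            # retry once from scratch before giving up on this imputation
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fr = fit(
                    analysis_spec,
                    completed,
                    method=config.fit_method,
                    max_iter=config.fit_max_iter,
                    em_iter=config.fit_em_iter,
                )
        if not fr.converged:
            raise RuntimeError(
                f"analysis model failed to converge in imputation cycle {cycle}"
            )
        theta = fr.theta
        # (3) refit and redraw each incomplete covariate
        for cov in targets:
            # (2) child-specific trajectory summaries: EB predictions
            # with this covariate's own fixed effect folded back into
            # the residual, so the summary is the child's outcome
            # location unexplained by everything *except* this
            # covariate — the statistic that predicts it.
            summaries = eb_random_effects(
                fr, completed, exclude_effects=(f"{cov}[",)
            )
            others = [c for c in ["sex", *analysis_covs] if c != cov]
            others = list(dict.fromkeys(others))
            others = [o for o in others if o in children.columns]
            observed_cohorts = sorted(
                children.loc[~miss_mask[cov], "cohort"].unique()
            )
            X, names = _imputation_design(
                children, cov, others, summaries, observed_cohorts
            )
            levels = sorted(children.loc[~miss_mask[cov], cov].dropna().unique())
            if len(levels) < 2:
                continue
            code = {l: k for k, l in enumerate(levels)}
            obs_rows = ~miss_mask[cov]
            y = children.loc[obs_rows, cov].map(code).to_numpy(int)
            coef, cov_mat = _fit_mnlogit(
                X[obs_rows], y, len(levels), ridge=config.ridge
            )
            # (3b) parameter draw from the asymptotic normal
            flat = coef.ravel()
            Lc = np.linalg.cholesky(
                cov_mat + 1e-10 * np.eye(cov_mat.shape[0])
            )
            draw = (flat + Lc @ rng.standard_normal(flat.size)).reshape(coef.shape)
            P = _mnlogit_probs(draw, X[miss_mask[cov]])
            u = rng.random(P.shape[0])
            picks = (u[:, None] > np.cumsum(P, axis=1)).sum(axis=1)
            children.loc[miss_mask[cov], cov] = [levels[k] for k in picks]
            details["predictors"][cov] = names
            details["coef_trace"].append(
                {"cycle": cycle, "covariate": cov, "coef": coef.copy()}
            )
        completed = PooledDataset(measurements=data.measurements, children=children)
    out = PooledDataset(measurements=data.measurements, children=children)
    return (out, details) if return_details else out


def multiple_impute(
    data: PooledDataset, analysis_spec: ModelSpec, config: MIConfig
) -> list[PooledDataset]:
    """``config.m`` independent completed datasets (seeds derived from
    ``config.seed``).  Any failed imputation aborts the whole run."""
    seeds = np.random.SeedSequence(config.seed).generate_state(config.m) % (2**31)
    out = []
    failed = []
    for s in seeds:
        try:
            out.append(impute_once(data, analysis_spec, config, int(s)))
        except RuntimeError as err:
            failed.append((int(s), str(err)))
    if failed:
        raise RuntimeError(f"imputations failed for seeds {failed}")
    return out


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of M per-imputation fits.

    ``W`` is the mean within-imputation covariance, ``B`` the
    between-imputation covariance of the estimates, and the total
    variance is ``T = W + (1 + 1/M) B``.
    """

    q_bar: pd.Series
    W: np.ndarray
    B: np.ndarray
    M: int

    @property
    def T(self) -> np.ndarray:
        return self.W + (1.0 + 1.0 / self.M) * self.B

    @property
    def df(self) -> pd.Series:
        Wd = np.diag(self.W)
        Bd = np.diag(self.B)
        with np.errstate(divide="ignore"):
            df = (self.M - 1) * (1.0 + Wd / ((1.0 + 1.0 / self.M) * Bd)) ** 2
        return pd.Series(np.where(Bd > 0, df, np.inf), index=self.q_bar.index)

    def ci95(self) -> pd.DataFrame:
        se = np.sqrt(np.clip(np.diag(self.T), 0, None))
        tq = np.where(
            np.isfinite(self.df), stats.t.ppf(0.975, np.clip(self.df, 1e-6, None)), 1.959963984540054
        )
        return pd.DataFrame(
            {
                "estimate": self.q_bar,
                "se": se,
                "ci_lo": self.q_bar - tq * se,
                "ci_hi": self.q_bar + tq * se,
                "df": self.df,
            }
        )

    def as_fit(self, template: FitResult) -> FitResult:
        """A FitResult carrying the pooled beta and total covariance, so
        prediction and contrast operations apply unchanged."""
        return replace(
            template, beta=self.q_bar.copy(), beta_vcov=np.asarray(self.T)
        )


def pool_rubin(estimates, vcovs, M: int | None = None) -> PooledEstimate:
    """Combine M per-imputation estimates by Rubin's rules."""
    est = [pd.Series(e) for e in estimates]
    if M is None:
        M = len(est)
    if M < 2 or len(est) != M or len(vcovs) != M:
        raise ValueError("need M >= 2 estimates and matching covariances")
    index = est[0].index
    Q = np.vstack([e.to_numpy(float) for e in est])
    W = np.mean([np.asarray(v, float) for v in vcovs], axis=0)
    dev = Q - Q.mean(axis=0)
    B = dev.T @ dev / (M - 1)
    return PooledEstimate(
        q_bar=pd.Series(Q.mean(axis=0), index=index), W=W, B=B, M=M
    )


def mi_analysis(
    data: PooledDataset, analysis_spec: ModelSpec, config: MIConfig
) -> tuple[PooledEstimate, list[FitResult]]:
    """Multiply impute, fit the analysis model on each completed
    dataset, and pool the fixed effects by Rubin's rules."""
    completed = multiple_impute(data, analysis_spec, config)
    fits = []
    theta = None
    for ds in completed:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fr = fit(
                analysis_spec,
                ds,
                method=config.fit_method,
                init=theta,
                max_iter=config.fit_max_iter,
                em_iter=config.fit_em_iter if theta is None else 0,
            )
        theta = fr.theta
        fits.append(fr)
    pooled = pool_rubin(
        [f.beta for f in fits], [f.beta_vcov for f in fits], config.m
    )
    return pooled, fits
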