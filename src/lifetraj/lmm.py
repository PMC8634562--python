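"""Two-level linear mixed model with complex level-1 variation.

The analysis model for pooled growth data: weight measurements (level
1) nested in children (level 2), with

* fixed effects: a nonlinear age trajectory (FP or RCS basis), cohort
  indicators with optional cohort x trajectory interactions, and
  child-level covariates with optional covariate x trajectory
  interactions;
* child-level random effects for the intercept and every trajectory
  term, with an unstructured covariance matrix ``G``;
* measurement-level residual variance that changes with age
  (:class:`~lifetraj.variance.Level1VarianceSpec`), all pairwise
  covariances fixed at zero.

Estimation maximizes the exact marginal likelihood (children are
independent, so the marginal covariance is block diagonal) by ML or
REML.  The fixed effects are profiled out by GLS; the variance
parameters are optimized by quasi-Newton on an unconstrained scale
(log-Cholesky factor of ``G``, log level-1 variances) with analytic
gradients.  Per-child linear algebra uses the Woodbury identity, so the
cost is linear in measurements and cubic only in the (small) number of
random effects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .bases import BasisSpec, basis_matrix
from .harmonize import HARMONIZED_VOCABULARY, PooledDataset
from .variance import Level1VarianceSpec

__all__ = [
    "Covariate",
    "ModelSpec",
    "FitResult",
    "marginal_covariance",
    "log_likelihood",
    "fit",
    "predict_mean",
    "contrast",
    "eb_random_effects",
    "information_criteria",
    "mspe",
    "prediction_squared_errors",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class Covariate:
    """A child-level fixed covariate; ``interact`` adds products with
    every trajectory column."""

    name: str
    interact: bool = True


@dataclass(frozen=True)
class ModelSpec:
    """Full description of one candidate analysis model.

    ``cohort_effects`` is ``"none"``, ``"main"`` (cohort intercept
    dummies) or ``"interactions"`` (dummies plus cohort x trajectory
    products).  ``dropped_interactions`` lists
    ``(covariate, level, trajectory_column)`` triples excluded from the
    design — interactions unsupported by the data (e.g. a minority
    ethnic group observed only at young ages crossed with a spline term
    active only at older ages).
    """

    trajectory: BasisSpec
    covariates: tuple[Covariate, ...] = ()
    cohort_effects: str = "interactions"
    level1: Level1VarianceSpec = field(default_factory=Level1VarianceSpec)
    dropped_interactions: frozenset = frozenset()
    random_effects: str = "full"  # "full": intercept + all trajectory terms

    def __post_init__(self) -> None:
        if self.cohort_effects not in ("none", "main", "interactions"):
            raise ValueError("cohort_effects must be none|main|interactions")
        if self.random_effects not in ("full", "intercept"):
            raise ValueError("random_effects must be 'full' or 'intercept'")
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(
            self, "dropped_interactions", frozenset(self.dropped_interactions)
        )

    @property
    def n_random_effects(self) -> int:
        if self.random_effects == "intercept":
            return 1
        return 1 + self.trajectory.n_columns

    def with_level1(self, level1: Level1VarianceSpec) -> "ModelSpec":
        return replace(self, level1=level1)


# ---------------------------------------------------------------------------
# Design construction


def _covariate_levels(children: pd.DataFrame, name: str) -> tuple[str, ...]:
    """Canonical level order: harmonized vocabulary where defined, else
    sorted observed levels.  Only levels present in the data are kept so
    the design stays full rank."""
    observed = set(children[name].dropna().unique())
    vocab = HARMONIZED_VOCABULARY.get(name)
    if vocab is not None:
        levels = tuple(l for l in vocab if l in observed)
        extra = observed - set(vocab)
        if extra:
            raise ValueError(f"{name}: unharmonized levels {sorted(extra)}")
        return levels
    return tuple(sorted(observed))


def _fixed_matrix(
    spec: ModelSpec,
    ages: np.ndarray,
    B: np.ndarray,
    cohort: np.ndarray,
    cov_values: dict[str, np.ndarray],
    levels: dict[str, tuple[str, ...]],
) -> tuple[np.ndarray, list[str]]:
    """Assemble the fixed-effect design matrix (shared by fitting and
    prediction so the column layout is identical)."""
    n = ages.size
    bnames = spec.trajectory.column_names()
    cols = [np.ones(n)]
    names = ["const"]
    for j, nm in enumerate(bnames):
        cols.append(B[:, j])
        names.append(nm)
    if spec.cohort_effects != "none":
        for lab in levels["cohort"][1:]:
            d = (cohort == lab).astype(float)
            cols.append(d)
            names.append(f"cohort[{lab}]")
            if spec.cohort_effects == "interactions":
                for j, nm in enumerate(bnames):
                    if ("cohort", lab, nm) in spec.dropped_interactions:
                        continue
                    cols.append(d * B[:, j])
                    names.append(f"cohort[{lab}]:{nm}")
    for cov in spec.covariates:
        vals = cov_values[cov.name]
        for lab in levels[cov.name][1:]:
            d = (vals == lab).astype(float)
            cols.append(d)
            names.append(f"{cov.name}[{lab}]")
            if cov.interact:
                for j, nm in enumerate(bnames):
                    if (cov.name, lab, nm) in spec.dropped_interactions:
                        continue
                    cols.append(d * B[:, j])
                    names.append(f"{cov.name}[{lab}]:{nm}")
    return np.column_stack(cols), names


def _drop_aliased(
    X: np.ndarray, names: list[str], tol: float = 1e-9
) -> tuple[np.ndarray, list[str], tuple[str, ...]]:
    """Remove identically-zero and linearly dependent design columns
    (pivoted QR on the scaled Gram matrix), keeping the earliest
    columns so main effects win over interactions."""
    from scipy.linalg import qr as _qr

    scale = np.sqrt((X**2).mean(axis=0))
    zero = scale == 0
    keep_idx = np.where(~zero)[0]
    Xs = X[:, keep_idx] / scale[keep_idx]
    Gram = Xs.T @ Xs
    _, R, piv = _qr(Gram, pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > tol * diag[0]).sum()) if diag.size else 0
    kept = np.sort(keep_idx[piv[:rank]])
    dropped = tuple(names[i] for i in range(len(names)) if i not in set(kept))
    if not dropped:
        return X, names, ()
    return X[:, kept], [names[i] for i in kept], dropped


@dataclass
class _Design:
    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    ages: np.ndarray
    seg: np.ndarray | None          # segment index per row (segmented kind)
    child_sizes: np.ndarray         # visits per child, in child order
    child_ids: list
    x_names: list[str]
    z_names: list[str]
    levels: dict
    cohort_age_ranges: dict
    groups: list[tuple[np.ndarray, int]]  # (row-index matrix (m, n), n)
    dropped_columns: tuple[str, ...] = ()


def _build_design(data: PooledDataset, spec: ModelSpec) -> _Design:
    meas = data.measurements.sort_values(["child_id", "age_years"], kind="mergesort")
    kids = data.children.set_index("child_id")
    needed = [c.name for c in spec.covariates]
    missing_rows = kids[needed].isna().any(axis=1) if needed else None
    if needed and missing_rows.any():
        raise ValueError(
            f"{int(missing_rows.sum())} children have missing values in "
            f"{needed}; filter to complete covariates or impute first"
        )
    child_of_row = meas["child_id"].to_numpy()
    ages = meas["age_years"].to_numpy(dtype=float)
    y = meas["weight_kg"].to_numpy(dtype=float)
    cohort_rows = meas["cohort"].to_numpy()

    levels: dict = {"cohort": tuple(sorted(data.children["cohort"].unique()))}
    for cov in spec.covariates:
        levels[cov.name] = _covariate_levels(data.children, cov.name)

    cov_values = {
        c.name: kids[c.name].reindex(child_of_row).to_numpy()
        for c in spec.covariates
    }
    B = basis_matrix(ages, spec.trajectory)
    X, x_names = _fixed_matrix(spec, ages, B, cohort_rows, cov_values, levels)
    # Cohort/covariate interaction columns can be aliased: identically
    # zero when a level never occurs inside a basis column's active
    # region, or linearly dependent when a cohort's age window lies
    # beyond several knots (truncated cubics collapse to plain cubics
    # there).  Aliased columns are dropped, mirroring the exclusion of
    # interactions unsupported by the data.
    X, x_names, dropped_columns = _drop_aliased(X, x_names)
    if spec.random_effects == "intercept":
        Z = np.ones((ages.size, 1))
        z_names = ["const"]
    else:
        Z = np.column_stack([np.ones(ages.size), B])
        z_names = ["const"] + spec.trajectory.column_names()

    seg = (
        spec.level1.segment_index(ages)
        if spec.level1.kind == "segmented"
        else None
    )

    ids, starts = np.unique(child_of_row, return_index=True)
    order = np.argsort(starts)
    ids = ids[order]
    starts = np.sort(starts)
    sizes = np.diff(np.append(starts, ages.size))

    groups: list[tuple[np.ndarray, int]] = []
    for n_i in np.unique(sizes):
        which = np.where(sizes == n_i)[0]
        idx = starts[which][:, None] + np.arange(n_i)[None, :]
        groups.append((idx, int(n_i)))

    ranges = {
        lab: (float(g.min()), float(g.max()))
        for lab, g in meas.groupby("cohort")["age_years"]
    }
    return _Design(
        y=y, X=X, Z=Z, ages=ages, seg=seg,
        child_sizes=sizes, child_ids=list(ids),
        x_names=x_names, z_names=z_names, levels=levels,
        cohort_age_ranges=ranges, groups=groups,
        dropped_columns=dropped_columns,
    )


# ---------------------------------------------------------------------------
# Likelihood machinery


def _theta_split(theta: np.ndarray, q: int) -> tuple[np.ndarray, np.ndarray]:
    """Unpack working parameters into the Cholesky factor L of G and the
    level-1 variance vector."""
    nL = q * (q + 1) // 2
    L = np.zeros((q, q))
    il = np.tril_indices(q)
    L[il] = theta[:nL]
    L[np.diag_indices(q)] = np.exp(np.diag(L))
    sig = np.exp(theta[nL:])
    return L, sig


def _theta_pack(G: np.ndarray, sig: np.ndarray) -> np.ndarray:
    q = G.shape[0]
    L = np.linalg.cholesky(G + 1e-10 * np.eye(q))
    W = L.copy()
    W[np.diag_indices(q)] = np.log(np.diag(L))
    return np.concatenate([W[np.tril_indices(q)], np.log(np.asarray(sig, float))])


def _level1_values(theta: np.ndarray, q: int) -> np.ndarray:
    return np.exp(theta[q * (q + 1) // 2:])


class _Objective:
    """Profiled ML/REML log-likelihood and gradient over grouped child
    blocks.  ``L`` may be any q x q (or q x k) factor with G = L L'."""

    def __init__(self, design: _Design, spec: ModelSpec, method: str):
        if method not in ("ML", "REML"):
            raise ValueError("method must be 'ML' or 'REML'")
        self.d = design
        self.spec = spec
        self.method = method
        self.q = design.Z.shape[1]
        self.p = design.X.shape[1]
        self.N = design.y.size
        # Pre-gathered per-group tensors.
        self._cache = []
        for idx, n_i in design.groups:
            self._cache.append(
                dict(
                    X=design.X[idx],            # (m, n, p)
                    Z=design.Z[idx],            # (m, n, q)
                    y=design.y[idx],            # (m, n)
                    age=design.ages[idx],
                    seg=None if design.seg is None else design.seg[idx],
                )
            )

    def _rvar(self, grp, sig) -> np.ndarray:
        if self.spec.level1.kind == "segmented":
            return sig[grp["seg"]]
        return sig[0] + sig[1] * grp["age"] ** 2

    def loglik(self, L: np.ndarray, sig: np.ndarray, beta=None):
        """Profiled log-likelihood; returns (ll, beta_hat, XtVX, extras)."""
        p = self.p
        S = np.zeros((p + 1, p + 1))
        logdetV = 0.0
        pieces = []
        for grp in self._cache:
            d = self._rvar(grp, sig)
            if np.any(d <= 0):
                raise FloatingPointError("non-positive level-1 variance")
            Rinv = 1.0 / d
            ZL = grp["Z"] @ L
            W = Rinv[..., None] * ZL
            K = np.einsum("mnq,mnr->mqr", ZL, W)
            K[:, np.arange(K.shape[1]), np.arange(K.shape[1])] += 1.0
            cholK = np.linalg.cholesky(K)
            logdetV += 2.0 * np.log(
                np.einsum("mqq->mq", cholK)
            ).sum() + np.log(d).sum()
            A = np.concatenate([grp["X"], grp["y"][..., None]], axis=2)
            WtA = np.einsum("mnr,mna->mra", W, A)
            KiWtA = np.linalg.solve(K, WtA)
            S += np.einsum("mna,mn,mnb->ab", A, Rinv, A)
            S -= np.einsum("mqa,mqb->ab", WtA, KiWtA)
            pieces.append((d, Rinv, ZL, W, K))
        XtVX = S[:p, :p]
        XtVy = S[:p, p]
        ytVy = S[p, p]
        if beta is None:
            try:
                beta = np.linalg.solve(XtVX, XtVy)
            except np.linalg.LinAlgError:
                beta = np.linalg.lstsq(XtVX, XtVy, rcond=None)[0]
        rVr = ytVy - 2.0 * beta @ XtVy + beta @ XtVX @ beta
        ll = -0.5 * (self.N * _LOG2PI + logdetV + rVr)
        if self.method == "REML":
            sign, ld = np.linalg.slogdet(XtVX)
            if sign <= 0:
                raise FloatingPointError("X'V^-1X not positive definite")
            ll += -0.5 * ld + 0.5 * p * _LOG2PI
        return ll, beta, XtVX, pieces

    def loglik_grad(self, theta: np.ndarray):
        """Negative profiled log-likelihood and its gradient in theta."""
        L, sig = _theta_split(theta, self.q)
        try:
            ll, beta, XtVX, pieces = self.loglik(L, sig)
        except (FloatingPointError, np.linalg.LinAlgError):
            return 1e12, np.zeros_like(theta)
        reml = self.method == "REML"
        M = None
        if reml:
            M = np.linalg.pinv(XtVX)
        A_G = np.zeros((self.q, self.q))
        n_sig = sig.size
        g_sig = np.zeros(n_sig)
        for grp, (d, Rinv, ZL, W, K) in zip(self._cache, pieces):
            r = grp["y"] - np.einsum("mnp,p->mn", grp["X"], beta)
            Wtr = np.einsum("mnq,mn->mq", W, r)
            Vinvr = Rinv * r - np.einsum(
                "mnq,mq->mn", W, np.linalg.solve(K, Wtr[..., None])[..., 0]
            )
            Z = grp["Z"]
            WtZ = np.einsum("mnq,mnr->mqr", W, Z)
            VinvZ = Rinv[..., None] * Z - np.einsum(
                "mnq,mqr->mnr", W, np.linalg.solve(K, WtZ)
            )
            u = np.einsum("mnq,mn->mq", Z, Vinvr)
            Q = np.einsum("mnq,mnr->qr", Z, VinvZ)
            A_G += -0.5 * Q + 0.5 * np.einsum("mq,mr->qr", u, u)
            KiWt = np.linalg.solve(K, np.swapaxes(W, 1, 2))
            diagVinv = Rinv - np.einsum("mnq,mqn->mn", W, KiWt)
            c = -0.5 * diagVinv + 0.5 * Vinvr**2
            if reml:
                X3 = grp["X"]
                WtX = np.einsum("mnq,mnp->mqp", W, X3)
                VinvX = Rinv[..., None] * X3 - np.einsum(
                    "mnq,mqp->mnp", W, np.linalg.solve(K, WtX)
                )
                C = np.einsum("mnq,mnp->mqp", Z, VinvX)
                CM = np.einsum("mqp,pr->mqr", C, M)
                A_G += 0.5 * np.einsum("mqr,msr->qs", CM, C)
                c = c + 0.5 * np.einsum("mnp,pr,mnr->mn", VinvX, M, VinvX)
            if self.spec.level1.kind == "segmented":
                seg = grp["seg"]
                for s in range(n_sig):
                    g_sig[s] += c[seg == s].sum()
            else:
                g_sig[0] += c.sum()
                g_sig[1] += (c * grp["age"] ** 2).sum()
        g_sig *= sig  # chain rule for the log scale
        dL = 2.0 * A_G @ L
        dL *= np.tri(self.q)
        dL[np.diag_indices(self.q)] *= np.diag(L)
        grad = np.concatenate([dL[np.tril_indices(self.q)], g_sig])
        return -ll, -grad

    def em_step(self, G: np.ndarray, sig: np.ndarray):
        """One EM update of (G, sig) treating the random effects as
        missing data (REML variant uses the projected inverse P in the
        E-step).  Returns (G_new, sig_new, loglik_at_input)."""
        w, V = np.linalg.eigh(G)
        L = V * np.sqrt(np.clip(w, 0.0, None))
        ll, beta, XtVX, pieces = self.loglik(L, sig)
        reml = self.method == "REML"
        M = np.linalg.pinv(XtVX) if reml else None
        q = self.q
        EbbT = np.zeros((q, q))
        m_total = 0
        n_sig = sig.size
        sig_num = np.zeros(n_sig)
        sig_den = np.zeros(n_sig)
        for grp, (d, Rinv, ZL, W, K) in zip(self._cache, pieces):
            m = grp["y"].shape[0]
            m_total += m
            r = grp["y"] - np.einsum("mnp,p->mn", grp["X"], beta)
            Wtr = np.einsum("mnq,mn->mq", W, r)
            Vinvr = Rinv * r - np.einsum(
                "mnq,mq->mn", W, np.linalg.solve(K, Wtr[..., None])[..., 0]
            )
            Z = grp["Z"]
            WtZ = np.einsum("mnq,mnr->mqr", W, Z)
            VinvZ = Rinv[..., None] * Z - np.einsum(
                "mnq,mqr->mnr", W, np.linalg.solve(K, WtZ)
            )
            u = np.einsum("mnq,mn->mq", Z, Vinvr)
            Q = np.einsum("mnq,mnr->mqr", Z, VinvZ)
            KiWt = np.linalg.solve(K, np.swapaxes(W, 1, 2))
            diagVinv = Rinv - np.einsum("mnq,mqn->mn", W, KiWt)
            if reml:
                X3 = grp["X"]
                WtX = np.einsum("mnq,mnp->mqp", W, X3)
                VinvX = Rinv[..., None] * X3 - np.einsum(
                    "mnq,mqp->mnp", W, np.linalg.solve(K, WtX)
                )
                C = np.einsum("mnq,mnp->mqp", Z, VinvX)
                Q = Q - np.einsum("mqp,pr,msr->mqs", C, M, C)
                diagVinv = diagVinv - np.einsum(
                    "mnp,pr,mnr->mn", VinvX, M, VinvX
                )
            Gu = u @ G.T
            EbbT += m * G - G @ Q.sum(axis=0) @ G + np.einsum("mq,mr->qr", Gu, Gu)
            # E[e_j^2 | y] per measurement-level random effect
            if self.spec.level1.kind == "segmented":
                seg = grp["seg"]
                for s in range(n_sig):
                    mask = seg == s
                    v = sig[s]
                    contrib = v - v**2 * diagVinv[mask] + v**2 * Vinvr[mask] ** 2
                    sig_num[s] += contrib.sum()
                    sig_den[s] += mask.sum()
            else:
                age = grp["age"]
                s0, s1 = sig
                c0 = s0 - s0**2 * diagVinv + s0**2 * Vinvr**2
                c1 = s1 - s1**2 * age**2 * diagVinv + s1**2 * age**2 * Vinvr**2
                sig_num[0] += c0.sum()
                sig_num[1] += c1.sum()
                sig_den[0] += c0.size
                sig_den[1] += c1.size
        G_new = EbbT / m_total
        G_new = 0.5 * (G_new + G_new.T)
        sig_new = np.clip(sig_num / np.maximum(sig_den, 1), 1e-8, None)
        return G_new, sig_new, float(ll)


# ---------------------------------------------------------------------------
# Public operations


def marginal_covariance(
    Z_i: np.ndarray,
    ages_i,
    G: np.ndarray,
    level1: Level1VarianceSpec,
    level1_values,
) -> np.ndarray:
    """Marginal covariance of one child's measurements:
    ``V_i = Z_i G Z_i' + R_i`` with diagonal age-dependent ``R_i``."""
    Z_i = np.atleast_2d(np.asarray(Z_i, dtype=float))
    G = np.asarray(G, dtype=float)
    if Z_i.shape[1] != G.shape[0]:
        raise ValueError("Z_i and G dimensions do not conform")
    R = np.diag(level1.variance(ages_i, level1_values))
    return Z_i @ G @ Z_i.T + R


def log_likelihood(
    data: PooledDataset,
    spec: ModelSpec,
    G: np.ndarray,
    level1_values,
    method: str = "ML",
    beta=None,
) -> float:
    """Profiled marginal log-likelihood at given variance parameters.

    ``beta`` defaults to the GLS solution (the profiled likelihood); ML
    is the sum of per-child multivariate-normal log densities, REML adds
    the fixed-effect correction ``-0.5 ln|X'V^-1 X| + (p/2) ln 2pi``.
    A fixed ``beta`` may be passed as a Series named by design column.
    """
    design = _build_design(data, spec)
    if beta is not None and isinstance(beta, pd.Series):
        beta = beta.reindex(design.x_names)
        if beta.isna().any():
            raise ValueError("beta missing entries for some design columns")
        beta = beta.to_numpy(dtype=float)
    obj = _Objective(design, spec, method)
    G = np.asarray(G, dtype=float)
    w, V = np.linalg.eigh(G)
    if w.min() < -1e-10:
        raise ValueError("G must be positive semi-definite")
    L = V * np.sqrt(np.clip(w, 0.0, None))
    ll, _, _, _ = obj.loglik(L, np.asarray(level1_values, dtype=float), beta=beta)
    return float(ll)


def _moment_init(design: _Design, spec: ModelSpec) -> np.ndarray:
    """Method-of-moments warm start: the covariance of per-child
    ridge-OLS growth coefficients seeds G (it overestimates G by the
    OLS sampling noise, which is harmless for a starting value), and
    pooled per-child residual variances seed the level-1 parameters."""
    bhat, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
    marg_resid = design.y - design.X @ bhat
    v = max(float(marg_resid.var()), 1e-6)
    q = design.Z.shape[1]
    starts = np.cumsum(np.append(0, design.child_sizes))
    coefs = []
    res_sq, res_age, res_seg = [], [], []
    ridge = 1e-4 * np.eye(q)
    for i, n_i in enumerate(design.child_sizes):
        if n_i < q + 1:
            continue
        sl = slice(starts[i], starts[i + 1])
        Zi = design.Z[sl]
        ri = marg_resid[sl]
        ci = np.linalg.solve(Zi.T @ Zi + ridge, Zi.T @ ri)
        coefs.append(ci)
        ei = ri - Zi @ ci
        res_sq.append(ei**2)
        res_age.append(design.ages[sl])
        if design.seg is not None:
            res_seg.append(design.seg[sl])
    if len(coefs) >= max(30, 3 * q):
        G0 = np.cov(np.array(coefs).T)
        G0 = np.atleast_2d(G0) + 1e-3 * np.eye(q) * max(np.trace(np.atleast_2d(G0)) / q, 1e-3)
        e2 = np.concatenate(res_sq)
        if spec.level1.kind == "segmented":
            seg = np.concatenate(res_seg)
            sig0 = np.array(
                [
                    max(float(e2[seg == s].mean()), 1e-4) if np.any(seg == s) else v / 2
                    for s in range(spec.level1.n_params)
                ]
            )
        else:
            a2 = np.concatenate(res_age) ** 2
            A = np.column_stack([np.ones(a2.size), a2])
            s, *_ = np.linalg.lstsq(A, e2, rcond=None)
            sig0 = np.clip(s, 1e-4, None)
    else:
        zsd = np.maximum(design.Z.std(axis=0), 1e-2)
        zsd[0] = 1.0
        G0 = np.diag(v / 2.0 / zsd**2)
        sig0 = np.full(spec.level1.n_params, v / 2.0)
        if spec.level1.kind == "age_linear":
            sig0 = np.array([v / 2.0, v / (2.0 * max(design.ages.max(), 1.0) ** 2)])
    return _theta_pack(G0, sig0)


@dataclass
class FitResult:
    """Converged (or diagnosed) mixed-model fit."""

    spec: ModelSpec
    method: str
    beta: pd.Series
    beta_vcov: np.ndarray
    G_hat: np.ndarray
    level1_hat: np.ndarray
    loglik: float
    n_obs: int
    n_children: int
    n_params: int
    converged: bool
    gradient_norm: float
    n_iter: int
    theta: np.ndarray
    x_names: list[str]
    z_names: list[str]
    levels: dict
    cohort_age_ranges: dict
    child_ids: frozenset
    dropped_columns: tuple = ()

    @property
    def n_fixed(self) -> int:
        return len(self.beta)

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.clip(np.diag(self.beta_vcov), 0, None))
        return pd.DataFrame(
            {
                "estimate": self.beta,
                "se": se,
                "ci_lo": self.beta - 1.96 * se,
                "ci_hi": self.beta + 1.96 * se,
            }
        )


def fit(
    spec: ModelSpec,
    data: PooledDataset,
    method: str = "REML",
    init: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 500,
    em_iter: int = 30,
) -> FitResult:
    """Fit the model by profiled quasi-Newton ML/REML.

    ``init`` is a working-scale parameter vector (e.g. ``theta`` of a
    previous fit with the same structure) for warm starts.  The
    ``converged`` flag requires a small relative gradient on the working
    scale; non-convergence returns a result with diagnostics rather than
    raising.
    """
    design = _build_design(data, spec)
    q = design.Z.shape[1]
    p = design.X.shape[1]
    n_children = len(design.child_ids)
    if n_children <= q:
        raise ValueError(
            f"need more children ({n_children}) than random effects ({q})"
        )
    # Standardize random-effect columns for optimization conditioning:
    # Z -> Z diag(1/s) re-expresses G as diag(s) G diag(s), which keeps
    # the log-Cholesky parameters on comparable scales.  The model is
    # unchanged; G_hat is mapped back before reporting.
    zscale = np.maximum(design.Z.std(axis=0), 1e-8)
    zscale[0] = 1.0
    design.Z = design.Z / zscale
    obj = _Objective(design, spec, method)

    if init is None:
        init = _moment_init(design, spec)
        # EM warm start: each step costs about one gradient evaluation
        # but moves variance parameters in large, stable jumps; the
        # quasi-Newton polish then only has to finish the job.
        G_cur, sig_cur = _theta_split(init, q)
        G_cur = G_cur @ G_cur.T
        ll_prev = -np.inf
        for _ in range(em_iter):
            try:
                G_cur, sig_cur, ll_cur = obj.em_step(G_cur, sig_cur)
            except (FloatingPointError, np.linalg.LinAlgError):
                break
            if abs(ll_cur - ll_prev) < 1e-6 * max(1.0, abs(ll_cur)):
                break
            ll_prev = ll_cur
        init = _theta_pack(G_cur, sig_cur)

    nL = q * (q + 1) // 2
    lb = np.full(init.size, -50.0)
    ub = np.full(init.size, 50.0)
    diag_pos = np.cumsum(np.arange(1, q + 1)) - 1  # diagonal slots in tril order
    lb[diag_pos] = -7.0
    ub[diag_pos] = 8.0
    lb[nL:] = -7.0
    ub[nL:] = 12.0
    init = np.clip(init, lb, ub)

    res = optimize.minimize(
        obj.loglik_grad,
        init,
        jac=True,
        method="L-BFGS-B",
        bounds=list(zip(lb, ub)),
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-6},
    )
    theta = res.x
    L, sig = _theta_split(theta, q)
    ll, beta, XtVX, _ = obj.loglik(L, sig)
    _, grad = obj.loglik_grad(theta)
    gnorm = float(np.max(np.abs(grad)) / max(1.0, abs(ll)))
    converged = bool(res.success) or gnorm < 1e-4
    if not converged:
        warnings.warn(
            f"mixed-model fit did not converge (relative gradient {gnorm:.2e}; "
            f"{res.message})",
            stacklevel=2,
        )
    beta_vcov = np.linalg.pinv(XtVX)
    return FitResult(
        spec=spec,
        method=method,
        beta=pd.Series(beta, index=design.x_names),
        beta_vcov=beta_vcov,
        G_hat=(L @ L.T) / np.outer(zscale, zscale),
        level1_hat=sig,
        loglik=float(ll),
        n_obs=obj.N,
        n_children=n_children,
        n_params=p + theta.size,
        converged=converged,
        gradient_norm=gnorm,
        n_iter=int(res.nit),
        theta=theta,
        x_names=design.x_names,
        z_names=design.z_names,
        levels=design.levels,
        cohort_age_ranges=design.cohort_age_ranges,
        child_ids=frozenset(design.child_ids),
        dropped_columns=design.dropped_columns,
    )


def _pattern_matrix(fit_like, pattern: dict, ages) -> np.ndarray:
    """Fixed-design rows for a covariate pattern on an age grid, laid
    out identically to the fitted design."""
    spec: ModelSpec = fit_like.spec
    levels: dict = fit_like.levels
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    for key, val in pattern.items():
        if key == "cohort":
            if val not in levels["cohort"]:
                raise ValueError(f"unknown cohort {val!r}")
        elif key in levels:
            if val not in levels[key]:
                raise ValueError(f"unknown level {val!r} for {key!r}")
        else:
            raise ValueError(f"{key!r} is not a covariate of this fit")
    B = basis_matrix(ages, spec.trajectory)
    cohort = np.full(ages.size, pattern.get("cohort", levels["cohort"][0]))
    cov_values = {
        c.name: np.full(ages.size, pattern.get(c.name, levels[c.name][0]))
        for c in spec.covariates
    }
    X, names = _fixed_matrix(spec, ages, B, cohort, cov_values, levels)
    dropped = set(fit_like.dropped_columns)
    if dropped:
        keep = [i for i, nm in enumerate(names) if nm not in dropped]
        X = X[:, keep]
        names = [names[i] for i in keep]
    if names != fit_like.x_names:
        raise ValueError("pattern design incompatible with the fitted design")
    return X


def _check_support(fit_result: FitResult, pattern: dict, ages) -> None:
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    cohort = pattern.get("cohort")
    if cohort is not None and cohort in fit_result.cohort_age_ranges:
        lo, hi = fit_result.cohort_age_ranges[cohort]
    else:
        rng = fit_result.cohort_age_ranges.values()
        lo = min(r[0] for r in rng)
        hi = max(r[1] for r in rng)
    if ages.min() < lo - 1e-9 or ages.max() > hi + 1e-9:
        raise ValueError(
            f"ages outside the observed support [{lo:g}, {hi:g}] for this "
            "pattern; predictions beyond the data are blocked unless "
            "allow_extrapolation=True"
        )


def predict_mean(
    fit_result: FitResult,
    pattern: dict,
    ages,
    allow_extrapolation: bool = False,
) -> pd.DataFrame:
    """Population-mean weight trajectory for a covariate pattern.

    Returns a DataFrame (age, mean, ci_lo, ci_hi) with pointwise
    delta-method 95% intervals.  Ages outside the age range the
    pattern's cohort actually covers raise unless
    ``allow_extrapolation`` is set.
    """
    if not allow_extrapolation:
        _check_support(fit_result, pattern, ages)
    X = _pattern_matrix(fit_result, pattern, ages)
    mean = X @ fit_result.beta.to_numpy()
    var = np.einsum("np,pq,nq->n", X, fit_result.beta_vcov, X)
    half = 1.96 * np.sqrt(np.clip(var, 0, None))
    return pd.DataFrame(
        {
            "age": np.atleast_1d(np.asarray(ages, dtype=float)),
            "mean": mean,
            "ci_lo": mean - half,
            "ci_hi": mean + half,
        }
    )


def contrast(
    fit_result: FitResult,
    pattern_a: dict,
    pattern_b: dict,
    age,
    allow_extrapolation: bool = False,
) -> tuple[float, tuple[float, float]]:
    """Difference in mean weight (a minus b) at one age, with 95% CI."""
    if not allow_extrapolation:
        _check_support(fit_result, pattern_a, age)
        _check_support(fit_result, pattern_b, age)
    xa = _pattern_matrix(fit_result, pattern_a, [age])[0]
    xb = _pattern_matrix(fit_result, pattern_b, [age])[0]
    c = xa - xb
    diff = float(c @ fit_result.beta.to_numpy())
    se = float(np.sqrt(max(c @ fit_result.beta_vcov @ c, 0.0)))
    return diff, (diff - 1.96 * se, diff + 1.96 * se)


def eb_random_effects(
    fit_result: FitResult,
    data: PooledDataset,
    exclude_effects: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Empirical-Bayes (BLUP) random-effect predictions per child:
    ``b_i = G Z_i' V_i^{-1} (y_i - X_i beta)``.

    These are the child-specific trajectory summaries that feed the
    covariate imputation models.  ``exclude_effects`` names fixed-effect
    column prefixes whose contribution is *not* removed from the
    residual (their coefficients are zeroed): when imputing a covariate,
    its own effect must stay inside the summary, otherwise the summary
    carries no information about that covariate among the children who
    have it observed."""
    design = _build_design(data, fit_result.spec)
    if design.x_names != fit_result.x_names:
        raise ValueError("data incompatible with the fitted design")
    G = fit_result.G_hat
    w, V = np.linalg.eigh(G)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    sig = fit_result.level1_hat
    spec = fit_result.spec
    beta = fit_result.beta.to_numpy().copy()
    if exclude_effects:
        for j, nm in enumerate(fit_result.x_names):
            if any(nm.startswith(pref) for pref in exclude_effects):
                beta[j] = 0.0
    out = np.zeros((len(design.child_ids), G.shape[0]))
    # groups hold row-index matrices; map each block back to its child
    # via the block's first row offset.
    starts = np.cumsum(np.append(0, design.child_sizes))[:-1]
    for idx, n_i in design.groups:
        rows = idx
        ages = design.ages[rows]
        if spec.level1.kind == "segmented":
            d = sig[design.seg[rows]]
        else:
            d = sig[0] + sig[1] * ages**2
        Rinv = 1.0 / d
        Z = design.Z[rows]
        ZL = Z @ L
        W = Rinv[..., None] * ZL
        K = np.einsum("mnq,mnr->mqr", ZL, W)
        K[:, np.arange(K.shape[1]), np.arange(K.shape[1])] += 1.0
        r = design.y[rows] - np.einsum("mnp,p->mn", design.X[rows], beta)
        Wtr = np.einsum("mnq,mn->mq", W, r)
        Vinvr = Rinv * r - np.einsum(
            "mnq,mq->mn", W, np.linalg.solve(K, Wtr[..., None])[..., 0]
        )
        u = np.einsum("mnq,mn->mq", Z, Vinvr)
        b = u @ G.T
        child_pos = np.searchsorted(starts, rows[:, 0])
        out[child_pos] = b
    cols = [f"re_{nm}" for nm in design.z_names]
    df = pd.DataFrame(out, columns=cols)
    df.insert(0, "child_id", design.child_ids)
    return df


def information_criteria(fit_result: FitResult) -> tuple[float, float]:
    """AIC and BIC; the parameter count includes fixed effects and free
    variance parameters."""
    k = fit_result.n_params
    aic = -2.0 * fit_result.loglik + 2.0 * k
    bic = -2.0 * fit_result.loglik + k * math.log(fit_result.n_obs)
    return aic, bic


def prediction_squared_errors(
    fit_result: FitResult, validation: PooledDataset
) -> np.ndarray:
    """Per-measurement squared prediction errors on held-out children
    (fixed-effects-only predictions — validation children are new, so
    their random effects are unknown)."""
    val_ids = set(validation.children["child_id"])
    overlap = val_ids & set(fit_result.child_ids)
    if overlap:
        raise ValueError(
            f"{len(overlap)} validation children overlap the training set"
        )
    meas = validation.measurements
    kids = validation.children.set_index("child_id")
    ages = meas["age_years"].to_numpy(dtype=float)
    B = basis_matrix(ages, fit_result.spec.trajectory)
    cohort = meas["cohort"].to_numpy()
    cov_values = {
        c.name: kids[c.name].reindex(meas["child_id"]).to_numpy()
        for c in fit_result.spec.covariates
    }
    X, names = _fixed_matrix(
        fit_result.spec, ages, B, cohort, cov_values, fit_result.levels
    )
    dropped = set(fit_result.dropped_columns)
    if dropped:
        keep = [i for i, nm in enumerate(names) if nm not in dropped]
        X = X[:, keep]
        names = [names[i] for i in keep]
    if names != fit_result.x_names:
        raise ValueError("validation design incompatible with the fitted design")
    resid = meas["weight_kg"].to_numpy(dtype=float) - X @ fit_result.beta.to_numpy()
    return resid**2


def mspe(fit_result: FitResult, validation: PooledDataset) -> float:
    """Mean squared prediction error on held-out children."""
    return float(np.mean(prediction_squared_errors(fit_result, validation)))
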