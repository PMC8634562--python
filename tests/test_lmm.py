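"""Mixed-model engine: likelihood correctness against dense oracles,
variance estimation, prediction/contrast algebra, empirical-Bayes
effects, information criteria and out-of-sample MSPE."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from lifetraj import (
    BasisSpec,
    CohortProfile,
    Covariate,
    Level1VarianceSpec,
    ModelSpec,
    PooledDataset,
    TruthParams,
    contrast,
    default_truth,
    eb_random_effects,
    fit,
    generate_cohort,
    generate_multi_cohort,
    information_criteria,
    log_likelihood,
    marginal_covariance,
    mspe,
    predict_mean,
)
from lifetraj.lmm import _build_design

from conftest import two_cohort_profiles

FP1 = BasisSpec(family="FP", powers=(1.0,))


def dense_loglik(data, spec, G, vals, method, beta=None):
    """Naive oracle: explicit per-child V_i, scipy MVN log-densities,
    plus the REML fixed-effect correction."""
    d = _build_design(data, spec)
    starts = np.cumsum(np.append(0, d.child_sizes))
    blocks = []
    for i in range(len(d.child_sizes)):
        sl = slice(starts[i], starts[i + 1])
        V = marginal_covariance(d.Z[sl], d.ages[sl], G, spec.level1, vals)
        blocks.append((d.X[sl], d.y[sl], V))
    XtVX = sum(X.T @ np.linalg.solve(V, X) for X, _, V in blocks)
    XtVy = sum(X.T @ np.linalg.solve(V, y) for X, y, V in blocks)
    if beta is None:
        beta = np.linalg.solve(XtVX, XtVy)
    ll = sum(
        multivariate_normal.logpdf(y, mean=X @ beta, cov=V) for X, y, V in blocks
    )
    if method == "REML":
        p = blocks[0][0].shape[1]
        ll += -0.5 * np.linalg.slogdet(XtVX)[1] + 0.5 * p * math.log(2 * math.pi)
    return ll


def random_small_dataset(rng):
    """<=5 children x <=6 visits, random ages/weights, one cohort."""
    n_children = rng.integers(2, 6)
    rows = []
    for i in range(n_children):
        n_visits = rng.integers(1, 7)
        ages = np.sort(rng.uniform(0, 10, n_visits))
        for a in ages:
            rows.append((f"c{i}", "A", a, rng.normal(10 + 2 * a, 3)))
    meas = pd.DataFrame(rows, columns=["child_id", "cohort", "age_years", "weight_kg"])
    kids = pd.DataFrame(
        {"child_id": [f"c{i}" for i in range(n_children)], "cohort": "A"}
    )
    return PooledDataset(measurements=meas, children=kids)


class TestMarginalCovariance:
    def test_pure_level1_is_diagonal(self):
        V = marginal_covariance(
            np.ones((2, 1)),
            [1.0, 3.0],
            np.zeros((1, 1)),
            Level1VarianceSpec(kind="segmented", cuts=(2.0,)),
            (1.0, 4.0),
        )
        np.testing.assert_array_equal(V, np.diag([1.0, 4.0]))

    def test_age_linear_entry(self):
        V = marginal_covariance(
            np.ones((1, 1)),
            [2.0],
            np.zeros((1, 1)),
            Level1VarianceSpec(kind="age_linear"),
            (1.0, 1.0),
        )
        assert V[0, 0] == pytest.approx(5.0)  # 1 + 1 * 2^2

    def test_matches_simulation_covariance(self):
        rng = np.random.default_rng(0)
        ages = np.array([0.5, 2.5, 7.0])
        Z = np.column_stack([np.ones(3), ages])
        A = rng.normal(size=(2, 2))
        G = A @ A.T
        lv = Level1VarianceSpec(kind="segmented", cuts=(2.0,))
        vals = (0.3, 1.2)
        V = marginal_covariance(Z, ages, G, lv, vals)
        assert np.allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() > 0
        n = 400_000
        b = rng.multivariate_normal(np.zeros(2), G, size=n)
        e = rng.standard_normal((n, 3)) * np.sqrt(lv.variance(ages, vals))
        sims = b @ Z.T + e
        mc_se = np.abs(V).max() * math.sqrt(2.0 / n) * 6
        np.testing.assert_allclose(np.cov(sims.T), V, atol=max(0.05, mc_se))


class TestLogLikelihood:
    def test_single_visit_standard_normal_density(self):
        meas = pd.DataFrame(
            {"child_id": ["c0"], "cohort": ["A"], "age_years": [3.0],
             "weight_kg": [7.0]}
        )
        kids = pd.DataFrame({"child_id": ["c0"], "cohort": ["A"]})
        data = PooledDataset(meas, kids)
        spec = ModelSpec(
            trajectory=FP1,
            cohort_effects="none",
            level1=Level1VarianceSpec(kind="segmented", cuts=()),
        )
        # G = 0, sigma^2 = 1, beta chosen so the residual is exactly 0
        ll = log_likelihood(
            data, spec, np.zeros((2, 2)), (1.0,), method="ML",
            beta=pd.Series({"const": 7.0, "t^1": 0.0}),
        )
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-12)

    @pytest.mark.parametrize("method", ["ML", "REML"])
    def test_matches_dense_oracle_on_random_instances(self, method):
        rng = np.random.default_rng(42)
        spec = ModelSpec(
            trajectory=FP1,
            cohort_effects="none",
            level1=Level1VarianceSpec(kind="segmented", cuts=(2.0,)),
        )
        for _ in range(25):
            data = random_small_dataset(rng)
            A = rng.normal(size=(2, 2)) * 0.7
            G = A @ A.T
            vals = tuple(rng.uniform(0.2, 3.0, 2))
            ours = log_likelihood(data, spec, G, vals, method=method)
            oracle = dense_loglik(data, spec, G, vals, method)
            assert ours == pytest.approx(oracle, abs=1e-8)

    def test_age_linear_variance_against_oracle(self):
        rng = np.random.default_rng(7)
        spec = ModelSpec(
            trajectory=FP1,
            cohort_effects="none",
            level1=Level1VarianceSpec(kind="age_linear"),
        )
        data = random_small_dataset(rng)
        G = np.diag([1.0, 0.1])
        vals = (0.5, 0.05)
        assert log_likelihood(data, spec, G, vals, method="REML") == pytest.approx(
            dense_loglik(data, spec, G, vals, "REML"), abs=1e-8
        )


class TestFit:
    def test_recovers_fixed_effects_with_no_random_effects(self):
        basis = FP1
        truth = TruthParams(
            basis=basis,
            beta={"intercept": 4.0, "basis": np.array([2.0])},
            G=np.zeros((2, 2)),
            level1=Level1VarianceSpec(kind="segmented", cuts=()),
            level1_values=(1.0,),
        )
        profile = CohortProfile(
            cohort_label="A", age_window=(0, 8),
            visit_schedule=(0.0, 2.0, 4.0, 6.0, 8.0), n_children=500,
            schedule_jitter_sd=0.05,
        )
        meas, kids = generate_cohort(profile, truth, seed=20)
        data = PooledDataset(meas, kids)
        spec = ModelSpec(
            trajectory=basis, cohort_effects="none",
            level1=Level1VarianceSpec(kind="segmented", cuts=()),
        )
        fr = fit(spec, data, method="REML")
        assert fr.converged
        se = np.sqrt(np.diag(fr.beta_vcov))
        assert abs(fr.beta["const"] - 4.0) < 3 * se[0]
        assert abs(fr.beta["t^1"] - 2.0) < 3 * se[1]

    def test_balanced_random_intercept_matches_anova(self):
        """With every visit at age 0 the model degenerates to the
        balanced one-way random-effects ANOVA, whose REML variance
        estimates have a closed form via the mean squares."""
        rng = np.random.default_rng(21)
        n, m = 120, 4
        sig_b, sig_e = 2.0, 0.5
        b = rng.normal(0, math.sqrt(sig_b), n)
        y = 10.0 + np.repeat(b, m) + rng.normal(0, math.sqrt(sig_e), n * m)
        meas = pd.DataFrame(
            {
                "child_id": np.repeat([f"c{i:03d}" for i in range(n)], m),
                "cohort": "A",
                "age_years": 0.0,
                "weight_kg": y,
            }
        )
        kids = pd.DataFrame(
            {"child_id": [f"c{i:03d}" for i in range(n)], "cohort": "A"}
        )
        data = PooledDataset(meas, kids)
        spec = ModelSpec(
            trajectory=FP1,
            cohort_effects="none",
            level1=Level1VarianceSpec(kind="segmented", cuts=()),
            random_effects="intercept",
        )
        fr = fit(spec, data, method="REML", tol=1e-12)
        Y = y.reshape(n, m)
        msw = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum() / (n * (m - 1))
        msb = m * ((Y.mean(axis=1) - Y.mean()) ** 2).sum() / (n - 1)
        assert fr.level1_hat[0] == pytest.approx(msw, rel=1e-4)
        assert fr.G_hat[0, 0] == pytest.approx((msb - msw) / m, rel=1e-4)

    def test_matches_statsmodels_random_intercept(self, toy_data):
        """Independent cross-check on the homoscedastic random-intercept
        subcase, which statsmodels MixedLM also covers."""
        sm = pytest.importorskip("statsmodels.api")
        spec = ModelSpec(
            trajectory=FP1,
            cohort_effects="main",
            level1=Level1VarianceSpec(kind="segmented", cuts=()),
            random_effects="intercept",
        )
        fr = fit(spec, toy_data, method="REML", tol=1e-12)
        d = _build_design(toy_data, spec)
        groups = np.repeat(np.arange(len(d.child_sizes)), d.child_sizes)
        md = sm.MixedLM(d.y, d.X, groups=groups).fit(reml=True)
        np.testing.assert_allclose(fr.beta.to_numpy(), md.fe_params, rtol=1e-4)
        assert fr.G_hat[0, 0] == pytest.approx(
            float(np.asarray(md.cov_re)[0, 0]), rel=1e-3
        )
        assert fr.level1_hat[0] == pytest.approx(md.scale, rel=1e-3)

    def test_multi_start_reaches_same_optimum(self, toy_data):
        spec = ModelSpec(
            trajectory=FP1, cohort_effects="main",
            level1=Level1VarianceSpec(kind="segmented", cuts=(2.0,)),
        )
        rng = np.random.default_rng(22)
        base = fit(spec, toy_data, method="ML", tol=1e-12)
        for _ in range(5):
            init = base.theta + rng.normal(0, 0.5, base.theta.size)
            other = fit(spec, toy_data, method="ML", init=init, tol=1e-12)
            assert other.loglik == pytest.approx(base.loglik, abs=1e-4 * abs(base.loglik) * 1e-1 + 1e-5 * abs(base.loglik))

    def test_reml_variances_exceed_ml_on_average(self, fp_line_truth):
        """ML variance components are biased downward; REML corrects."""
        diffs = []
        profiles = two_cohort_profiles(30, 25)
        for seed in range(8):
            data = generate_multi_cohort(profiles, fp_line_truth, seed=100 + seed)
            spec = ModelSpec(
                trajectory=FP1, cohort_effects="main",
                level1=Level1VarianceSpec(kind="segmented", cuts=(2.0,)),
            )
            ml = fit(spec, data, method="ML")
            reml = fit(spec, data, method="REML")
            diffs.append(reml.G_hat[0, 0] - ml.G_hat[0, 0])
        assert np.mean(diffs) > 0

    def test_mcar_measurement_deletion_shifts_estimates_within_noise(
        self, toy_data, toy_fit
    ):
        """Likelihood fits are valid under MAR outcomes: deleting half
        the measurements completely at random moves the fixed effects
        by less than 3 SE."""
        rng = np.random.default_rng(23)
        keep = rng.random(len(toy_data.measurements)) < 0.5
        thinned = PooledDataset(
            measurements=toy_data.measurements[keep].reset_index(drop=True),
            children=toy_data.children,
        )
        fr2 = fit(toy_fit.spec, thinned, method="REML")
        se = np.sqrt(np.diag(fr2.beta_vcov))
        shared = [n for n in toy_fit.x_names if n in fr2.x_names]
        for nm in shared:
            i = fr2.x_names.index(nm)
            assert abs(toy_fit.beta[nm] - fr2.beta[nm]) < 3 * se[i]


class TestPrediction:
    def test_intercept_at_basis_origin(self, toy_fit):
        # FP(1) basis column is zero at age 0, reference cohort
        out = predict_mean(toy_fit, {"cohort": "A"}, [0.0])
        assert out["mean"].iloc[0] == pytest.approx(toy_fit.beta["const"])

    def test_ci_width_scales_with_vcov(self, toy_fit):
        wide = replace(toy_fit, beta_vcov=4.0 * toy_fit.beta_vcov)
        a = predict_mean(toy_fit, {"cohort": "A"}, [2.0])
        b = predict_mean(wide, {"cohort": "A"}, [2.0])
        half_a = (a["ci_hi"] - a["ci_lo"]).iloc[0]
        half_b = (b["ci_hi"] - b["ci_lo"]).iloc[0]
        assert half_b == pytest.approx(2 * half_a, rel=1e-9)

    def test_tracks_generating_curve(self, toy_fit, fp_line_truth, toy_data):
        ages = np.linspace(0.5, 9.5, 10)
        out = predict_mean(toy_fit, {"cohort": "A"}, ages)
        true_curve = fp_line_truth.mean_weight(ages, "A", {})
        se = (out["ci_hi"] - out["ci_lo"]) / (2 * 1.96)
        assert (np.abs(out["mean"] - true_curve) < 3 * se + 1e-9).all()

    def test_extrapolation_guard(self, toy_fit):
        with pytest.raises(ValueError, match="support"):
            predict_mean(toy_fit, {"cohort": "B"}, [9.0])  # B stops at 6
        out = predict_mean(
            toy_fit, {"cohort": "B"}, [9.0], allow_extrapolation=True
        )
        assert np.isfinite(out["mean"]).all()

    def test_unknown_level_rejected(self, toy_fit):
        with pytest.raises(ValueError, match="unknown cohort"):
            predict_mean(toy_fit, {"cohort": "Z"}, [1.0])


class TestContrast:
    def test_null_contrast_is_exactly_zero(self, toy_fit):
        diff, (lo, hi) = contrast(toy_fit, {"cohort": "A"}, {"cohort": "A"}, 2.0)
        assert diff == 0.0 and lo == 0.0 and hi == 0.0

    def test_antisymmetry(self, toy_fit):
        d_ab, _ = contrast(toy_fit, {"cohort": "A"}, {"cohort": "B"}, 2.0)
        d_ba, _ = contrast(toy_fit, {"cohort": "B"}, {"cohort": "A"}, 2.0)
        assert d_ab == -d_ba

    def test_recovers_cohort_offset(self):
        truth = default_truth(FP1, cohort_offsets={"B": 2.0})
        data = generate_multi_cohort(two_cohort_profiles(400, 400), truth, seed=30)
        spec = ModelSpec(
            trajectory=FP1, cohort_effects="main",
            level1=Level1VarianceSpec(kind="segmented", cuts=(2.0,)),
        )
        fr = fit(spec, data, method="REML")
        diff, (lo, hi) = contrast(fr, {"cohort": "B"}, {"cohort": "A"}, 3.0)
        se = (hi - lo) / (2 * 1.96)
        assert abs(diff - 2.0) < 3 * se


class TestEmpiricalBayes:
    def test_shrinks_to_zero_as_g_vanishes(self, toy_fit, toy_data):
        tiny = replace(toy_fit, G_hat=1e-12 * np.eye(2))
        eb = eb_random_effects(tiny, toy_data)
        assert np.abs(eb.filter(like="re_").to_numpy()).max() < 1e-6

    def test_mean_near_zero(self, toy_fit, toy_data):
        eb = eb_random_effects(toy_fit, toy_data)
        vals = eb["re_const"].to_numpy()
        assert abs(vals.mean()) < 3 * vals.std() / math.sqrt(vals.size)

    def test_dense_child_approaches_ols_deviation(self):
        basis = FP1
        truth = TruthParams(
            basis=basis,
            beta={"intercept": 6.0, "basis": np.array([2.0])},
            G=np.diag([4.0, 0.25]),
            level1=Level1VarianceSpec(kind="segmented", cuts=()),
            level1_values=(0.01,),  # tiny measurement noise
        )
        profile = CohortProfile(
            cohort_label="A", age_window=(0, 10),
            visit_schedule=tuple(np.linspace(0, 10, 40)), n_children=60,
        )
        meas, kids = generate_cohort(profile, truth, seed=31)
        data = PooledDataset(meas, kids)
        spec = ModelSpec(
            trajectory=basis, cohort_effects="none",
            level1=Level1VarianceSpec(kind="segmented", cuts=()),
        )
        fr = fit(spec, data, method="REML")
        eb = eb_random_effects(fr, data).set_index("child_id")
        cid = kids["child_id"].iloc[0]
        grp = meas[meas["child_id"] == cid]
        Z = np.column_stack([np.ones(len(grp)), grp["age_years"]])
        dev = grp["weight_kg"].to_numpy() - Z @ np.array(
            [fr.beta["const"], fr.beta["t^1"]]
        )
        ols = np.linalg.lstsq(Z, dev, rcond=None)[0]
        np.testing.assert_allclose(
            eb.loc[cid, ["re_const", "re_t^1"]].to_numpy(), ols, atol=0.05
        )


class TestCriteriaAndMSPE:
    def test_information_criteria_closed_form(self, toy_fit):
        fake = replace(toy_fit, loglik=0.0, n_params=3, n_obs=int(round(math.e**2)))
        # n_obs must be e^2 for BIC = AIC; use the formulas directly
        aic = -2 * 0.0 + 2 * 3
        bic = -2 * 0.0 + 3 * math.log(fake.n_obs)
        got_aic, got_bic = information_criteria(fake)
        assert got_aic == pytest.approx(aic)
        assert got_bic == pytest.approx(bic)

    def test_nested_models_ml_loglik_ordering(self, toy_data):
        small = ModelSpec(
            trajectory=FP1, cohort_effects="none",
            level1=Level1VarianceSpec(kind="segmented", cuts=(2.0,)),
        )
        big = ModelSpec(
            trajectory=FP1, cohort_effects="main",
            level1=Level1VarianceSpec(kind="segmented", cuts=(2.0,)),
        )
        ll_small = fit(small, toy_data, method="ML").loglik
        ll_big = fit(big, toy_data, method="ML").loglik
        assert ll_big >= ll_small - 1e-4

    def test_zero_noise_gives_zero_mspe(self):
        truth = TruthParams(
            basis=FP1,
            beta={"intercept": 4.0, "basis": np.array([2.0])},
            G=np.zeros((2, 2)),
            level1=Level1VarianceSpec(kind="segmented", cuts=()),
            level1_values=(0.0,),
        )
        prof = CohortProfile(
            cohort_label="A", age_window=(0, 8),
            visit_schedule=(0.0, 2.0, 4.0, 6.0, 8.0), n_children=40,
        )
        meas, kids = generate_cohort(prof, truth, seed=32)
        train = PooledDataset(
            meas[meas["child_id"] < "A-000020"].reset_index(drop=True),
            kids[kids["child_id"] < "A-000020"].reset_index(drop=True),
        )
        val = PooledDataset(
            meas[meas["child_id"] >= "A-000020"].reset_index(drop=True),
            kids[kids["child_id"] >= "A-000020"].reset_index(drop=True),
        )
        spec = ModelSpec(
            trajectory=FP1, cohort_effects="none",
            level1=Level1VarianceSpec(kind="segmented", cuts=()),
        )
        fr = fit(spec, train, method="ML")
        assert mspe(fr, val) == pytest.approx(0.0, abs=1e-10)

    def test_mspe_approaches_total_variance(self, fp_line_truth):
        data = generate_multi_cohort(
            two_cohort_profiles(800, 700), fp_line_truth, seed=33
        )
        split = data.children["child_id"].rank(method="first") <= 750
        ids = set(data.children.loc[split, "child_id"])
        m_in = data.measurements["child_id"].isin(ids)
        train = PooledDataset(
            data.measurements[m_in].reset_index(drop=True),
            data.children[split].reset_index(drop=True),
        )
        val = PooledDataset(
            data.measurements[~m_in].reset_index(drop=True),
            data.children[~split].reset_index(drop=True),
        )
        spec = ModelSpec(
            trajectory=fp_line_truth.basis, cohort_effects="main",
            level1=Level1VarianceSpec(kind="segmented", cuts=(2.0,)),
        )
        fr = fit(spec, train, method="REML")
        got = mspe(fr, val)
        ages = val.measurements["age_years"].to_numpy()
        Z = np.column_stack([np.ones(ages.size), ages])
        expected = np.mean(
            np.einsum("nq,qr,nr->n", Z, fp_line_truth.G, Z)
            + fp_line_truth.level1.variance(ages, fp_line_truth.level1_values)
        )
        assert got == pytest.approx(expected, rel=0.08)

    def test_misspecified_mean_inflates_mspe(self):
        truth = default_truth()  # curved 5-knot spline truth
        profs = [
            CohortProfile(
                cohort_label="A", age_window=(0, 18),
                visit_schedule=(0.0, 0.5, 1.5, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0),
                n_children=500, schedule_jitter_sd=0.1,
            ),
            CohortProfile(
                cohort_label="B", age_window=(0, 18),
                visit_schedule=(0.25, 1.0, 2.0, 4.0, 8.0, 12.0, 16.0),
                n_children=300, schedule_jitter_sd=0.1,
            ),
        ]
        data = generate_multi_cohort(profs, truth, seed=34)
        split = data.children["child_id"].rank(method="first") <= 600
        ids = set(data.children.loc[split, "child_id"])
        m_in = data.measurements["child_id"].isin(ids)
        train = PooledDataset(
            data.measurements[m_in].reset_index(drop=True),
            data.children[split].reset_index(drop=True),
        )
        val = PooledDataset(
            data.measurements[~m_in].reset_index(drop=True),
            data.children[~split].reset_index(drop=True),
        )
        lv = Level1VarianceSpec(kind="segmented", cuts=(2.0,))
        linear = fit(
            ModelSpec(trajectory=FP1, cohort_effects="main", level1=lv),
            train, method="ML",
        )
        correct = fit(
            ModelSpec(trajectory=truth.basis, cohort_effects="main", level1=lv),
            train, method="ML",
        )
        assert mspe(linear, val) > mspe(correct, val)

    def test_overlapping_validation_children_rejected(self, toy_fit, toy_data):
        with pytest.raises(ValueError, match="overlap"):
            mspe(toy_fit, toy_data)
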