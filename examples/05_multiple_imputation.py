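"""Impute a covariate whose missingness depends on the outcome.

Maternal education shifts the child's weight level by 0/1/2 kg in the
generating truth, and the chance it is recorded falls as the child's
age-adjusted weight rises — exactly the setting where restricting to
complete covariates is biased.  The iterative trajectory-summary MI
procedure imputes the missing categories (M = 5 imputations, 3 cycles)
and Rubin's rules pool the per-imputation fits; the example compares
both estimators of the degree-or-higher effect with the truth.
"""

from lifetraj import (
    MissingnessSpec,
    PooledDataset,
    apply_covariate_missingness,
    complete_covariate_filter,
    fit,
    generate_multi_cohort,
    mi_analysis,
)
from lifetraj.studies import (
    MI_ANALYSIS_SPEC,
    MI_TARGET,
    MI_TARGET_TRUTH,
    _fast_mi_config,
    age_adjusted_proxy,
    mi_profiles,
    mi_truth,
)

full = generate_multi_cohort(mi_profiles(800), mi_truth(), seed=5)
proxy = age_adjusted_proxy(full)
holey = apply_covariate_missingness(
    full.children,
    MissingnessSpec(rates={"maternal_education": (-1.2, 1.8)}),
    proxy,
    seed=6,
)
data = PooledDataset(full.measurements, holey)
n_missing = int(holey["maternal_education"].isna().sum())
print(f"{n_missing}/{len(holey)} children missing maternal education")

cc_data, report = complete_covariate_filter(data, ["maternal_education"])
cc = fit(MI_ANALYSIS_SPEC, cc_data, method="REML")
pooled, fits = mi_analysis(data, MI_ANALYSIS_SPEC, _fast_mi_config(seed=7))

print(f"\ntrue '{MI_TARGET}' effect: {MI_TARGET_TRUTH:.2f} kg")
print(f"complete-covariate estimate: {cc.beta[MI_TARGET]:.3f}")
print(f"MI pooled estimate:          {pooled.q_bar[MI_TARGET]:.3f}")
row = pooled.ci95().loc[MI_TARGET]
print(f"MI 95% CI: ({row.ci_lo:.3f}, {row.ci_hi:.3f}), "
      f"Rubin df {row.df:.0f}")
# Complete-covariate analysis under-states the effect because it
# preferentially drops the heaviest children of the best-educated
# mothers; MI recovers the generating value within sampling noise.
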