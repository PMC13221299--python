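"""Between-cluster comparison machinery.

One-way ANOVA and chi-square tests across the five body-composition
clusters, Pearson correlations, and adjusted regressions of each health
indicator on cluster membership (indicator-coded against cluster 1),
measurement year (categorical), sex (boys 0 / girls 1) and age, with a
Gaussian random intercept per child fitted by REML when repeated measures
are present. Regression coefficients and their Wald 95% confidence limits
are also reported exponentiated, matching the forest-plot convention used
for these outcomes. For multiply imputed data the regression is refit per
completed dataset (ordinary least squares — the random intercept is dropped
on this path) and pooled by Rubin's rules before exponentiation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .impute import ImputationSet, pool_rubin

__all__ = [
    "ComparisonResult",
    "RegressionSpec",
    "oneway_anova",
    "chi_square",
    "pearson",
    "fit_regression",
    "run_comparison_suite",
    "add_lipid_ratios",
]

DEFAULT_OUTCOMES = (
    "bfp",
    "ac",
    "tc_hdlc",
    "tg_hdlc",
    "steps_per_day",
    "activity_min",
    "sleep_min",
)


@dataclass
class ComparisonResult:
    """A single test or model: statistic, df, p, and (for regressions) terms."""

    outcome: str
    test: str  # anova_F | chi2 | pearson_r | regression
    statistic: float | None
    df: tuple | float | None
    p_value: float | None
    coefficients: pd.DataFrame | None = None  # term, estimate, exp, CI, p
    pooled: bool = False


@dataclass
class RegressionSpec:
    """Fixed/random structure of the adjusted outcome regressions."""

    response: str
    cluster_col: str = "cluster"
    year_col: str = "wave"
    sex_col: str = "sex"
    age_col: str = "age"
    group_col: str | None = "subject_id"  # random-intercept grouping
    reference_cluster: int = 1


def oneway_anova(groups) -> ComparisonResult:
    """Classical one-way fixed-effects ANOVA across k groups.

    F = MSB/MSW on (k-1, N-k) degrees of freedom. Requires at least two
    groups of at least two observations each and non-degenerate
    within-group variance.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0:
        raise ValueError("zero within-group variance; F undefined")
    df1, df2 = k - 1, n_total - k
    f = (ssb / df1) / (ssw / df2)
    p = float(sps.f.sf(f, df1, df2))
    return ComparisonResult(
        outcome="", test="anova_F", statistic=float(f), df=(df1, df2), p_value=p
    )


def chi_square(table) -> ComparisonResult:
    """Pearson chi-square test of independence, no continuity correction."""
    table = np.asarray(table, float)
    if (table < 0).any() or table.sum() <= 0:
        raise ValueError("counts must be non-negative with a positive total")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    res = sps.chi2_contingency(table, correction=False)
    return ComparisonResult(
        outcome="",
        test="chi2",
        statistic=float(res.statistic),
        df=float(res.dof),
        p_value=float(res.pvalue),
    )


def pearson(x, y) -> ComparisonResult:
    """Sample Pearson correlation with a t-based p-value on n-2 df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matching vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in at least one variable")
    res = sps.pearsonr(x, y)
    return ComparisonResult(
        outcome="",
        test="pearson_r",
        statistic=float(res.statistic),
        df=float(len(x) - 2),
        p_value=float(res.pvalue),
    )


def _formula(spec: RegressionSpec) -> str:
    return (
        f"{spec.response} ~ C({spec.cluster_col}, "
        f"Treatment(reference={spec.reference_cluster})) "
        f"+ C({spec.year_col}) + {spec.sex_col} + {spec.age_col}"
    )


def _coef_table(params, ses, pvals, ci) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "term": list(params.index),
            "estimate": params.to_numpy(float),
            "se": np.asarray(ses, float),
            "ci_lo": ci[0],
            "ci_hi": ci[1],
            "p_value": np.asarray(pvals, float),
        }
    )
    # raw-scale outcomes (e.g. step counts) can overflow exp; report inf
    with np.errstate(over="ignore"):
        out["exp_estimate"] = np.exp(out["estimate"])
        out["exp_ci_lo"] = np.exp(out["ci_lo"])
        out["exp_ci_hi"] = np.exp(out["ci_hi"])
    return out


def _encode_sex(data: pd.DataFrame, sex_col: str) -> pd.DataFrame:
    if data[sex_col].dtype == object:
        data = data.copy()
        data[sex_col] = data[sex_col].map({"male": 0, "female": 1})
        if data[sex_col].isna().any():
            raise ValueError("sex column must be male/female or 0/1")
    return data


def fit_regression(
    spec: RegressionSpec, data: pd.DataFrame | ImputationSet, extra: pd.DataFrame | None = None
) -> ComparisonResult:
    """Adjusted regression of one outcome on cluster, year, sex and age.

    With ``spec.group_col`` set and repeated measures present, a linear
    mixed model with a Gaussian random intercept is fitted by REML; a
    non-positive between-subject variance estimate degenerates to OLS (with
    a warning). Without grouping the model is ordinary least squares.

    When ``data`` is an :class:`ImputationSet`, per-term OLS estimates from
    each completed dataset (joined with ``extra`` for the design columns
    absent from the imputed matrix) are pooled by Rubin's rules; the random
    intercept is not used on this path.
    """
    if isinstance(data, ImputationSet):
        return _fit_pooled(spec, data, extra)
    data = _encode_sex(data.dropna(subset=[spec.response]), spec.sex_col)
    formula = _formula(spec)
    use_mixed = (
        spec.group_col is not None
        and data[spec.group_col].duplicated().any()
    )
    if use_mixed:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data, groups=data[spec.group_col])
            fit = model.fit(reml=True)
        var_re = float(fit.cov_re.iloc[0, 0])
        if not np.isfinite(var_re) or var_re <= 0:
            warnings.warn(
                "between-subject variance estimated at the zero boundary; "
                "falling back to OLS",
                stacklevel=2,
            )
            use_mixed = False
        else:
            fe = fit.fe_params
            ci = fit.conf_int().loc[fe.index]
            table = _coef_table(
                fe,
                fit.bse.loc[fe.index],
                fit.pvalues.loc[fe.index],
                (ci[0].to_numpy(float), ci[1].to_numpy(float)),
            )
            table.attrs["var_random_intercept"] = var_re
            table.attrs["var_residual"] = float(fit.scale)
            cluster_terms = table["term"].str.startswith(f"C({spec.cluster_col}")
            p_min = float(table.loc[cluster_terms, "p_value"].min())
            return ComparisonResult(
                outcome=spec.response,
                test="regression",
                statistic=None,
                df=float(fit.df_resid),
                p_value=p_min,
                coefficients=table,
            )
    fit = smf.ols(formula, data).fit()
    ci = fit.conf_int()
    table = _coef_table(
        fit.params, fit.bse, fit.pvalues, (ci[0].to_numpy(float), ci[1].to_numpy(float))
    )
    table.attrs["var_random_intercept"] = 0.0
    table.attrs["var_residual"] = float(fit.mse_resid)
    cluster_terms = table["term"].str.startswith(f"C({spec.cluster_col}")
    p_min = (
        float(table.loc[cluster_terms, "p_value"].min()) if cluster_terms.any() else None
    )
    return ComparisonResult(
        outcome=spec.response,
        test="regression",
        statistic=None,
        df=float(fit.df_resid),
        p_value=p_min,
        coefficients=table,
    )


def _fit_pooled(
    spec: RegressionSpec, imputations: ImputationSet, extra: pd.DataFrame | None
) -> ComparisonResult:
    per_term_est: dict[str, list[float]] = {}
    per_term_var: dict[str, list[float]] = {}
    df_complete = None
    for completed in imputations.completed:
        frame = completed if extra is None else pd.concat(
            [extra.reset_index(drop=True), completed.reset_index(drop=True)], axis=1
        )
        frame = _encode_sex(frame, spec.sex_col)
        fit = smf.ols(_formula(spec), frame).fit()
        df_complete = float(fit.df_resid)
        for term, est, se in zip(fit.params.index, fit.params, fit.bse):
            per_term_est.setdefault(term, []).append(float(est))
            per_term_var.setdefault(term, []).append(float(se) ** 2)
    rows = []
    for term in per_term_est:
        pooled, t_var, (lo, hi) = pool_rubin(
            per_term_est[term], per_term_var[term], df_complete=df_complete
        )
        se = np.sqrt(t_var)
        z = pooled / se if se > 0 else np.inf
        with np.errstate(over="ignore"):
            exp_est, exp_lo, exp_hi = np.exp([pooled, lo, hi])
        rows.append(
            {
                "term": term,
                "estimate": pooled,
                "se": se,
                "ci_lo": lo,
                "ci_hi": hi,
                "p_value": float(2 * sps.norm.sf(abs(z))),
                "exp_estimate": float(exp_est),
                "exp_ci_lo": float(exp_lo),
                "exp_ci_hi": float(exp_hi),
            }
        )
    table = pd.DataFrame(rows)
    cluster_terms = table["term"].str.startswith(f"C({spec.cluster_col}")
    p_min = float(table.loc[cluster_terms, "p_value"].min()) if cluster_terms.any() else None
    return ComparisonResult(
        outcome=spec.response,
        test="regression",
        statistic=None,
        df=df_complete,
        p_value=p_min,
        coefficients=table,
        pooled=True,
    )


def add_lipid_ratios(data: pd.DataFrame) -> pd.DataFrame:
    """Add TC/HDLC and TG/HDLC ratio columns from the lipid panel."""
    out = data.copy()
    out["tc_hdlc"] = out["tc"] / out["hdlc"]
    out["tg_hdlc"] = out["tg"] / out["hdlc"]
    return out


def run_comparison_suite(
    data: pd.DataFrame,
    outcomes=DEFAULT_OUTCOMES,
    cluster_col: str = "cluster",
    group_col: str | None = "subject_id",
) -> list[ComparisonResult]:
    """ANOVA + adjusted regression per numeric outcome; chi-square for
    sex, measurement year and integer age across clusters.

    ``data`` must be a clustered, imputed (complete) cohort table. Lipid
    ratio columns are derived from tc/tg/hdlc when absent.
    """
    data = data.copy()
    if ("tc_hdlc" in outcomes or "tg_hdlc" in outcomes) and "tc_hdlc" not in data.columns:
        data = add_lipid_ratios(data)
    missing = [o for o in outcomes if o not in data.columns]
    if missing:
        raise KeyError(f"outcome column(s) not found: {missing}")
    results: list[ComparisonResult] = []
    clusters = sorted(data[cluster_col].unique())
    for outcome in outcomes:
        groups = [
            data.loc[data[cluster_col] == c, outcome].dropna().to_numpy(float)
            for c in clusters
        ]
        res = oneway_anova(groups)
        res.outcome = outcome
        results.append(res)
        reg = fit_regression(
            RegressionSpec(response=outcome, cluster_col=cluster_col, group_col=group_col),
            data,
        )
        results.append(reg)
    for factor in ("sex", "wave"):
        if factor in data.columns:
            table = pd.crosstab(data[factor], data[cluster_col]).to_numpy()
            res = chi_square(table)
            res.outcome = factor
            results.append(res)
    if "age" in data.columns:
        table = pd.crosstab(np.floor(data["age"]).astype(int), data[cluster_col])
        res = chi_square(table.to_numpy())
        res.outcome = "age"
        results.append(res)
    return results


def results_table(results: list[ComparisonResult]) -> pd.DataFrame:
    """Tidy one-row-per-outcome(-term) summary of a comparison suite."""
    rows = []
    for r in results:
        if r.test == "regression" and r.coefficients is not None:
            for _, c in r.coefficients.iterrows():
                rows.append(
                    {
                        "outcome": r.outcome,
                        "test": r.test,
                        "term": c["term"],
                        "estimate": c["estimate"],
                        "exp_estimate": c["exp_estimate"],
                        "ci_lo": c["ci_lo"],
                        "ci_hi": c["ci_hi"],
                        "p_value": c["p_value"],
                    }
                )
        else:
            rows.append(
                {
                    "outcome": r.outcome,
                    "test": r.test,
                    "term": "",
                    "estimate": r.statistic,
                    "exp_estimate": np.nan,
                    "ci_lo": np.nan,
                    "ci_hi": np.nan,
                    "p_value": r.p_value,
                }
            )
    return pd.DataFrame(rows)
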