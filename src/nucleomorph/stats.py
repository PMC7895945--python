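"""Longitudinal mixed-effects statistics.

Random-intercept linear mixed models (REML) for the volume-change
correlations, fixed-effects ("marginal") R², variance inflation factors,
pairwise timepoint contrasts with multiplicity correction, one-sample
change-versus-baseline tests, and a repeated-measures ANOVA with Tukey
post-hoc for descriptive timecourses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MixedModelResult",
    "fit_random_intercept_model",
    "marginal_r2",
    "vif",
    "holm_adjust",
    "pairwise_timepoint_contrasts",
    "ChangeTestResult",
    "one_sample_change_test",
    "repeated_measures_anova",
]


@dataclass
class MixedModelResult:
    """Fixed-effect estimates and variance components of a random-intercept fit."""

    params: pd.Series
    se: pd.Series
    pvalues: pd.Series
    df_resid: float
    cov_params: pd.DataFrame
    random_intercept_var: float
    residual_var: float
    fixed_effects_var: float  # variance of the fixed-effect linear predictor
    vif: pd.Series | None
    n_obs: int
    n_groups: int
    method: str  # "reml-mixed" | "ml-mixed" | "ols-fallback"

    @property
    def marginal_r2(self) -> float:
        denom = self.fixed_effects_var + self.random_intercept_var + self.residual_var
        return self.fixed_effects_var / denom if denom > 0 else 0.0

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        crit = sps.t.ppf(1 - alpha / 2, self.df_resid)
        return pd.DataFrame(
            {"lower": self.params - crit * self.se, "upper": self.params + crit * self.se}
        )


def _find_collinear(X: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
        denom = np.var(X[:, j])
        if denom == 0 or np.var(resid) / denom < 1e-10:
            bad.append(names[j])
    return bad


def fit_random_intercept_model(
    table: pd.DataFrame,
    response: str,
    fixed_terms: list[str],
    group: str = "animal_id",
    reml: bool = True,
) -> MixedModelResult:
    """REML fit of ``response ~ fixed_terms`` with one random intercept per group.

    Fixed-effect p-values are Wald t-tests with ``n_obs − k`` residual degrees
    of freedom.  With a single group the model degenerates and an ordinary
    least-squares fit is returned with a warning.
    """
    fixed_terms = list(fixed_terms)
    for col in [response, group, *fixed_terms]:
        if col not in table.columns:
            raise ValueError(f"column {col!r} missing from the table")
    y = table[response].to_numpy(dtype=float)
    X = table[fixed_terms].to_numpy(dtype=float)
    names = ["Intercept", *fixed_terms]
    exog = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        bad = _find_collinear(X, fixed_terms) or fixed_terms
        raise ValueError(f"singular fixed-effect design; collinear terms: {bad}")
    groups = table[group].to_numpy()
    n_groups = len(pd.unique(groups))
    k = exog.shape[1]
    df_resid = len(y) - k

    if n_groups < 2:
        warnings.warn("single group: falling back to ordinary least squares")
        ols = sm.OLS(y, exog).fit()
        params = pd.Series(ols.params, index=names)
        se = pd.Series(ols.bse, index=names)
        tvals = params / se
        pvals = pd.Series(2 * sps.t.sf(np.abs(tvals), df_resid), index=names)
        fitted = exog @ ols.params
        return MixedModelResult(
            params, se, pvals, df_resid,
            pd.DataFrame(ols.cov_params(), index=names, columns=names),
            0.0, float(ols.mse_resid), float(np.var(fitted)),
            _vif_from_design(X, fixed_terms), len(y), n_groups, "ols-fallback",
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, exog, groups=groups)
        try:
            fit = model.fit(reml=reml)
        except np.linalg.LinAlgError:
            fit = model.fit(reml=reml, method="lbfgs")
    params = pd.Series(fit.fe_params, index=names)
    se = pd.Series(fit.bse_fe.to_numpy() if hasattr(fit.bse_fe, "to_numpy") else fit.bse_fe,
                   index=names)
    tvals = params / se
    pvals = pd.Series(2 * sps.t.sf(np.abs(tvals), df_resid), index=names)
    cov_fe = pd.DataFrame(
        np.asarray(fit.cov_params())[:k, :k], index=names, columns=names
    )
    fitted = exog @ params.to_numpy()
    re_var = float(np.asarray(fit.cov_re)[0, 0])
    return MixedModelResult(
        params, se, pvals, df_resid, cov_fe,
        re_var, float(fit.scale), float(np.var(fitted)),
        _vif_from_design(X, fixed_terms), len(y), n_groups,
        "reml-mixed" if reml else "ml-mixed",
    )


def marginal_r2(result: MixedModelResult) -> float:
    """Fixed-effects variance over total variance (fixed + intercept + residual)."""
    return result.marginal_r2


def _vif_from_design(X: np.ndarray, names: list[str]) -> pd.Series | None:
    if X.shape[1] < 2:
        return None
    values = []
    for j in range(X.shape[1]):
        others = np.column_stack([np.ones(X.shape[0]), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ beta
        total = np.var(X[:, j])
        if total == 0:
            raise ValueError(f"constant predictor {names[j]!r}")
        r2 = 1.0 - np.var(resid) / total
        if r2 > 1 - 1e-12:
            raise ValueError(f"exact collinearity involving {names[j]!r}")
        values.append(1.0 / (1.0 - r2))
    return pd.Series(values, index=names)


def vif(table: pd.DataFrame, fixed_terms: list[str]) -> pd.Series:
    """Variance inflation factor per term: 1/(1 − R²) regressing it on the rest."""
    fixed_terms = list(fixed_terms)
    if len(fixed_terms) < 2:
        raise ValueError("VIF requires at least 2 terms")
    X = table[fixed_terms].to_numpy(dtype=float)
    out = _vif_from_design(X, fixed_terms)
    assert out is not None
    return out


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="holm")[1]


def pairwise_timepoint_contrasts(
    table: pd.DataFrame,
    response: str,
    timepoint: str = "timepoint",
    group: str = "animal_id",
    correction: str = "holm",
) -> pd.DataFrame:
    """All pairwise timepoint differences from a random-intercept model.

    The model uses treatment coding of the timepoint factor; contrasts are
    Wald t-tests on coefficient differences with multiplicity-adjusted
    p-values (Holm by default).
    """
    levels = list(pd.unique(table[timepoint]))
    if len(levels) < 2:
        raise ValueError("timepoint factor must have at least 2 levels")
    dummies = pd.get_dummies(
        pd.Categorical(table[timepoint], categories=levels), drop_first=True, dtype=float
    )
    dummies.columns = [f"tp_{lvl}" for lvl in levels[1:]]
    work = pd.concat(
        [table[[response, group]].reset_index(drop=True), dummies.reset_index(drop=True)],
        axis=1,
    )
    result = fit_random_intercept_model(work, response, list(dummies.columns), group=group)
    # level means relative to the reference level
    coef = {levels[0]: 0.0}
    coef.update({lvl: result.params[f"tp_{lvl}"] for lvl in levels[1:]})
    names = list(result.params.index)
    cov = result.cov_params.to_numpy()

    def _cvec(lvl):
        c = np.zeros(len(names))
        if lvl != levels[0]:
            c[names.index(f"tp_{lvl}")] = 1.0
        return c

    rows = []
    for a, b in combinations(levels, 2):
        c = _cvec(b) - _cvec(a)
        est = float(c @ result.params.to_numpy())
        var = float(c @ cov @ c)
        se = np.sqrt(var)
        t = est / se
        p = 2 * sps.t.sf(abs(t), result.df_resid)
        rows.append({"level_a": a, "level_b": b, "estimate": est, "se": se, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"].to_numpy(), method=correction)[1]
    return out


@dataclass(frozen=True)
class ChangeTestResult:
    statistic: float
    pvalue: float
    method: str
    n: int


def one_sample_change_test(
    values, mu: float = 100.0, method: str = "auto", exact_below_n: int = 25
) -> ChangeTestResult:
    """Two-sided one-sample test of percent-of-baseline values against ``mu``.

    ``method`` is ``"t"``, ``"wilcoxon"`` or ``"auto"`` (Wilcoxon when a
    Shapiro normality pre-check fails at α = 0.05).  Wilcoxon p-values are
    exact below ``exact_below_n`` observations and use the normal
    approximation with continuity correction otherwise.
    """
    v = np.asarray(values, dtype=float)
    if method == "auto":
        if len(v) >= 3 and np.ptp(v) > 0:
            method = "wilcoxon" if sps.shapiro(v).pvalue < 0.05 else "t"
        else:
            method = "t"
    if method == "t":
        if len(v) < 2:
            raise ValueError("t-test requires at least 2 values")
        if np.ptp(v) == 0:
            raise ValueError("zero variance: t-test undefined")
        res = sps.ttest_1samp(v, mu)
        return ChangeTestResult(float(res.statistic), float(res.pvalue), "t", len(v))
    if method == "wilcoxon":
        d = v - mu
        d = d[d != 0]
        if len(d) == 0:
            raise ValueError("all values tie with mu: Wilcoxon undefined")
        use_exact = len(d) < exact_below_n and len(np.unique(np.abs(d))) == len(d)
        res = sps.wilcoxon(
            d, method="exact" if use_exact else "approx", correction=not use_exact
        )
        return ChangeTestResult(
            float(res.statistic), float(res.pvalue), "wilcoxon", len(d)
        )
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class RmAnovaResult:
    f_value: float
    df_num: float
    df_den: float
    pvalue: float
    tukey: pd.DataFrame


def repeated_measures_anova(
    table: pd.DataFrame,
    value: str,
    subject: str = "animal_id",
    within: str = "timepoint",
) -> RmAnovaResult:
    """Repeated-measures one-way ANOVA with a Tukey HSD post-hoc.

    Requires complete data (every subject observed at every level).
    """
    res = AnovaRM(table, depvar=value, subject=subject, within=[within]).fit()
    row = res.anova_table.iloc[0]
    levels = list(pd.unique(table[within]))
    samples = [table.loc[table[within] == lvl, value].to_numpy(dtype=float) for lvl in levels]
    tk = sps.tukey_hsd(*samples)
    rows = []
    for i, j in combinations(range(len(levels)), 2):
        rows.append(
            {
                "level_a": levels[i],
                "level_b": levels[j],
                "estimate": float(samples[j].mean() - samples[i].mean()),
                "p_adj": float(tk.pvalue[i, j]),
            }
        )
    return RmAnovaResult(
        float(row["F Value"]),
        float(row["Num DF"]),
        float(row["Den DF"]),
        float(row["Pr > F"]),
        pd.DataFrame(rows),
    )
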