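"""Shared linear-mixed-model machinery (random-intercept models).

Estimation is by maximum likelihood (not REML) so nested-model comparisons
remain valid; confidence intervals are Wald intervals on t quantiles with a
residual degrees-of-freedom approximation (n_obs - n_fixed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning


@dataclass
class ModelResult:
    """Coefficient table plus variance components and fit diagnostics."""

    coefficients: pd.DataFrame = field(repr=False)  # term, estimate, se, t, ci_low, ci_high
    var_subject: float
    var_residual: float
    icc1: float
    pseudo_r2_marginal: float
    n_obs: int
    n_subjects: int
    loglike: float
    flags: list[str] = field(default_factory=list)

    def coef(self, term: str) -> pd.Series:
        hit = self.coefficients[self.coefficients["term"] == term]
        if hit.empty:
            raise KeyError(f"no term {term!r}; have {list(self.coefficients['term'])}")
        return hit.iloc[0]


def compare_random_structures(
    endog: np.ndarray,
    exog: np.ndarray,
    names: list[str],
    groups: np.ndarray,
    slope_term: str,
) -> dict:
    """BIC comparison: random intercept vs random intercept + slope.

    The slope varies over the within-subject column ``slope_term``; both
    models are fitted by ML so the comparison is valid.  Returns BICs and
    the preferred structure (lower BIC).
    """
    endog = np.asarray(endog, float)
    exog = np.asarray(exog, float)
    j = names.index(slope_term)
    exog_re = np.column_stack([np.ones(len(endog)), exog[:, j]])
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for label, re_design in (("intercept", None), ("intercept_slope", exog_re)):
            try:
                res = sm.MixedLM(endog, exog, groups=groups, exog_re=re_design).fit(
                    reml=False
                )
                k = len(res.params)
                out[label] = float(-2 * res.llf + k * np.log(len(endog)))
            except (np.linalg.LinAlgError, ValueError):
                out[label] = np.inf
    out["preferred"] = min(("intercept", "intercept_slope"), key=out.__getitem__)
    return out


def fit_random_intercept(
    endog: np.ndarray,
    exog: np.ndarray,
    names: list[str],
    groups: np.ndarray,
    conf_level: float = 0.95,
) -> ModelResult:
    """Random-intercept LMM (ML); falls back to OLS for a single group."""
    endog = np.asarray(endog, float)
    exog = np.asarray(exog, float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    flags: list[str] = []
    n, p = exog.shape
    df_resid = max(n - p, 1)
    tq = stats.t.ppf(0.5 + conf_level / 2.0, df_resid)

    if uniq.size < 2:
        # variance component unidentifiable: reduces to OLS on the rows
        flags.append("single_group_ols")
        res = sm.OLS(endog, exog).fit()
        params, bse = res.params, res.bse
        var_sub, var_res, ll = 0.0, float(res.scale), float(res.llf)
    else:
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            model = sm.MixedLM(endog, exog, groups=groups)
            try:
                res = model.fit(reml=False)
            except (np.linalg.LinAlgError, ValueError):
                res = None
        if res is None:
            # boundary fit (subject variance ~ 0): report the OLS limit
            flags.append("singular_random_effect")
            ols = sm.OLS(endog, exog).fit()
            params, bse = ols.params, ols.bse
            var_sub, var_res, ll = 0.0, float(ols.scale), float(ols.llf)
        else:
            if not res.converged:
                flags.append("not_converged")
            params = np.asarray(res.fe_params)
            bse = np.asarray(res.bse_fe)
            var_sub = float(np.squeeze(res.cov_re))
            var_res = float(res.scale)
            ll = float(res.llf)
            if var_sub <= 1e-10 * max(var_res, 1e-12):
                flags.append("singular_random_effect")

    tvals = np.divide(params, bse, out=np.full_like(params, np.nan), where=bse > 0)
    coeffs = pd.DataFrame(
        {
            "term": names,
            "estimate": params,
            "se": bse,
            "t": tvals,
            "ci_low": params - tq * bse,
            "ci_high": params + tq * bse,
        }
    )
    fixed_pred = exog @ params
    var_fixed = float(np.var(fixed_pred))
    denom = var_fixed + var_sub + var_res
    pseudo_r2 = var_fixed / denom if denom > 0 else np.nan
    icc = var_sub / (var_sub + var_res) if (var_sub + var_res) > 0 else np.nan
    return ModelResult(
        coefficients=coeffs,
        var_subject=var_sub,
        var_residual=var_res,
        icc1=icc,
        pseudo_r2_marginal=pseudo_r2,
        n_obs=n,
        n_subjects=int(uniq.size),
        loglike=ll,
        flags=flags,
    )
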