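"""Experiment-1 inference: does resting-state band power predict L2 gain?

The analysis ladder mirrors small-sample brain-behaviour practice:

* per electrode-pool x band Spearman correlations of T1 log power with the
  corrected learning gain, Benjamini-Hochberg adjusted across all cells;
* a one-way ICC(1) on the power values to justify mixed modelling (power
  observations are nested in subjects);
* a random-intercept mixed model ``log10 power ~ CorP_z x Band`` with
  alpha as the reference band, ML estimation, Wald CIs and a marginal
  pseudo-R²; the band-specific interaction terms carry the substantive
  question (is the CorP-power link specific to beta1?);
* paired Wilcoxon signed-rank comparisons (T1 vs T2) with a
  Hodges-Lehmann CI, and an OLS regression of the beta1 power *change* on
  the learning gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from ._lmm import ModelResult, fit_random_intercept
from .spectral import BAND_ORDER

__all__ = [
    "ModelResult",
    "spearman_fdr",
    "icc1",
    "Icc1Result",
    "fit_power_model",
    "wilcoxon_paired",
    "WilcoxonResult",
    "change_outcome_regression",
    "RegressionResult",
    "signed_rank_pmf",
]


# ---------------------------------------------------------------------------
# correlations with FDR

def spearman_fdr(
    power_table: pd.DataFrame, outcomes: pd.Series, conf_level: float = 0.95
) -> pd.DataFrame:
    """Spearman rho per pool x band vs the per-subject outcome, BH-adjusted.

    Ties get average ranks; the CI is the Fisher-z interval.  Cells with a
    constant power column have undefined rho, are recorded with NaN and are
    excluded from the BH family.
    """
    if outcomes.index.nunique() < 4:
        raise ValueError("need at least 4 subjects")
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    rows = []
    for (pool, band), grp in power_table.groupby(["pool", "band"], sort=True):
        sub = grp.set_index("subject")["log10_power"].reindex(outcomes.index)
        ok = sub.notna() & outcomes.notna()
        x, y = sub[ok].to_numpy(), outcomes[ok].to_numpy()
        n = x.size
        if n < 4 or np.all(x == x[0]) or np.all(y == y[0]):
            rho, p = np.nan, np.nan
        else:
            rho, p = stats.spearmanr(x, y)
        if np.isfinite(rho) and abs(rho) < 1 and n > 3:
            fz = np.arctanh(rho)
            ci = np.tanh([fz - z / np.sqrt(n - 3), fz + z / np.sqrt(n - 3)])
        else:
            ci = (np.nan, np.nan)
        rows.append(
            {"pool": pool, "band": band, "n": n, "rho": rho,
             "ci_low": ci[0], "ci_high": ci[1], "p": p}
        )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    valid = out["p"].notna()
    if valid.any():
        out.loc[valid, "q"] = multipletests(out.loc[valid, "p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# ICC(1)

@dataclass
class Icc1Result:
    icc: float
    f_stat: float
    df_between: int
    df_within: int
    k_bar: float


def icc1(values: np.ndarray, groups: np.ndarray) -> Icc1Result:
    """One-way ANOVA intraclass correlation ICC(1).

    ``(MSB - MSW) / (MSB + (k̄ - 1) MSW)`` with the harmonic-mean-adjusted
    group size ``k̄ = (N - Σnᵢ²/N) / (a - 1)`` for unequal groups; may be
    negative when subjects differ less than chance.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    uniq, inv = np.unique(groups, return_inverse=True)
    a = uniq.size
    if a < 2:
        raise ValueError("ICC(1) needs at least 2 groups")
    n_i = np.bincount(inv)
    n_tot = values.size
    grand = values.mean()
    means = np.bincount(inv, weights=values) / n_i
    ssb = float(np.sum(n_i * (means - grand) ** 2))
    ssw = float(np.sum((values - means[inv]) ** 2))
    df_b, df_w = a - 1, n_tot - a
    if df_w < 1:
        raise ValueError("no within-group degrees of freedom")
    msb, msw = ssb / df_b, ssw / df_w
    k_bar = (n_tot - np.sum(n_i**2) / n_tot) / df_b
    if msw == 0:
        icc = 1.0
        f = np.inf
    else:
        icc = (msb - msw) / (msb + (k_bar - 1) * msw)
        f = msb / msw
    return Icc1Result(float(icc), float(f), df_b, df_w, float(k_bar))


# ---------------------------------------------------------------------------
# mixed model

def fit_power_model(
    power_table: pd.DataFrame,
    outcomes: pd.Series,
    reference_band: str = "alpha",
) -> ModelResult:
    """Random-intercept LMM: ``log10 power ~ CorP_z * Band``.

    Treatment coding with ``reference_band`` as the reference level; the
    outcome is z-scored over the analysed subjects.  Interaction terms are
    named ``corp_z:band[<name>]``.  A zero-variance outcome falls back to a
    Band-only fit, flagged ``degenerate_predictor``.
    """
    df = power_table.copy()
    df["corp"] = df["subject"].map(outcomes)
    if df["corp"].isna().any():
        missing = sorted(df.loc[df["corp"].isna(), "subject"].unique())
        raise ValueError(f"no outcome for subjects {missing}")
    sd = outcomes.std(ddof=1)
    degenerate = not np.isfinite(sd) or sd == 0
    df["corp_z"] = 0.0 if degenerate else (df["corp"] - outcomes.mean()) / sd

    bands = [b for b in BAND_ORDER if b in set(df["band"])]
    extra = sorted(set(df["band"]) - set(bands))
    bands += extra
    if reference_band not in bands:
        raise ValueError(f"reference band {reference_band!r} not in table")
    others = [b for b in bands if b != reference_band]

    n = len(df)
    cols = [np.ones(n)]
    names = ["Intercept"]
    if not degenerate:
        cols.append(df["corp_z"].to_numpy())
        names.append("corp_z")
    for b in others:
        cols.append((df["band"] == b).to_numpy(float))
        names.append(f"band[{b}]")
    if not degenerate:
        for b in others:
            cols.append(df["corp_z"].to_numpy() * (df["band"] == b).to_numpy(float))
            names.append(f"corp_z:band[{b}]")
    exog = np.column_stack(cols)
    result = fit_random_intercept(
        df["log10_power"].to_numpy(float), exog, names, df["subject"].to_numpy()
    )
    if degenerate:
        result.flags.append("degenerate_predictor")
    return result


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank

def signed_rank_pmf(n: int) -> np.ndarray:
    """Exact null PMF of the signed-rank statistic W+ for ``n`` pairs."""
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[: m + 1 - r].copy()
    return counts / 2.0**n


@dataclass
class WilcoxonResult:
    w_plus: float
    p_value: float
    n: int
    effect_size: float
    effect_convention: str
    hodges_lehmann: float
    ci_low: float
    ci_high: float
    alternative: str


def wilcoxon_paired(
    x_t1: np.ndarray,
    x_t2: np.ndarray,
    alternative: str = "two-sided",
    effect: str = "r",
    conf_level: float = 0.95,
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on ``d = x_t2 - x_t1``.

    Zero differences are dropped; the statistic is W+ (sum of positive
    ranks), the p-value exact when scipy's exact path applies.  Effect size
    is matched-rank ``r = |Z| / sqrt(n)`` by default, or the rank-biserial
    correlation with ``effect="rank_biserial"``.  The CI is the
    Hodges-Lehmann interval from Walsh averages with exact signed-rank
    critical values (normal approximation beyond n = 60).
    """
    d = np.asarray(x_t2, float) - np.asarray(x_t1, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    if n < 5:
        raise ValueError("need at least 5 non-zero paired differences")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")

    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    p = float(stats.wilcoxon(d, alternative=alternative).pvalue)

    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_counts**3 - tie_counts
    ) / 48.0
    zval = (w_plus - mu) / np.sqrt(sigma2) if sigma2 > 0 else np.inf
    if effect == "r":
        es = abs(zval) / np.sqrt(n)
    elif effect == "rank_biserial":
        es = (w_plus - w_minus) / (w_plus + w_minus)
    else:
        raise ValueError(f"unknown effect-size convention {effect!r}")

    walsh = np.sort((d[:, None] + d[None, :])[np.triu_indices(n)] / 2.0)
    hl = float(np.median(walsh))
    alpha = 1 - conf_level
    side = alpha / 2 if alternative == "two-sided" else alpha
    if n <= 60:
        cdf = np.cumsum(signed_rank_pmf(n))
        k = int(np.searchsorted(cdf, side, side="right") - 1)  # P(W <= k) <= side
    else:
        k = int(np.floor(mu - stats.norm.ppf(1 - side) * np.sqrt(sigma2)))
    k = max(k, -1)
    m = walsh.size
    lo = float(walsh[k + 1]) if k + 1 < m else float(walsh[0])
    hi = float(walsh[m - k - 2]) if m - k - 2 >= 0 else float(walsh[-1])
    if alternative == "greater":
        hi = np.inf
    elif alternative == "less":
        lo = -np.inf
    return WilcoxonResult(w_plus, p, n, float(es), effect, hl, lo, hi, alternative)


# ---------------------------------------------------------------------------
# standardized OLS

@dataclass
class RegressionResult:
    slope: float
    se: float
    t: float
    ci_low: float
    ci_high: float
    n: int
    flags: list[str]


def change_outcome_regression(
    x: np.ndarray, y: np.ndarray, conf_level: float = 0.95
) -> RegressionResult:
    """OLS slope of ``y`` on ``x`` after z-scoring both (Wald CI).

    Used for the beta1-change vs learning-gain association and, in the ERP
    experiment, for the N400-effect vs proficiency regression.  ``n = 2``
    is flagged degenerate (perfect fit, no CI).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need paired samples of length >= 2")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("zero-variance variable: slope undefined")
    xz = (x - x.mean()) / x.std(ddof=1)
    yz = (y - y.mean()) / y.std(ddof=1)
    flags: list[str] = []
    if x.size == 2:
        return RegressionResult(
            float(xz @ yz / (xz @ xz)), np.nan, np.nan, np.nan, np.nan, 2, ["degenerate"]
        )
    res = sm.OLS(yz, sm.add_constant(xz)).fit()
    ci = res.conf_int(1 - conf_level)
    return RegressionResult(
        slope=float(res.params[1]),
        se=float(res.bse[1]),
        t=float(res.tvalues[1]),
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        n=int(x.size),
        flags=flags,
    )
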