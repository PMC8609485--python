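"""Experiment-2 analysis: N400 and LPC in a language-switching paradigm.

Sentence-final words appear in a 2 (switch vs. no-switch) x 2 (congruent
vs. incongruent) design.  Baseline-corrected -100..1000 ms epochs are
averaged per condition; window-mean amplitudes are extracted at 300-450 ms
over the Central pool (N400) and 600-800 ms over the Parietal pool (LPC).
A random-intercept mixed model ``amplitude_z ~ Switch * Congruency + age_z``
is fitted per component; the per-subject N400 effect (no-switch minus
switch, positive for the canonical switch negativity) is regressed on L2
proficiency at T2 — the substantive prediction is a *negative* slope:
beginners with lower proficiency show larger switch effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._lmm import ModelResult, fit_random_intercept
from .preprocessing import EpochSet
from .stats_rest import RegressionResult, change_outcome_regression

SWITCH_LEVELS = ("no-switch", "switch")
CONGRUENCY_LEVELS = ("congruent", "incongruent")
CONDITIONS = tuple(f"{s}/{c}" for s in SWITCH_LEVELS for c in CONGRUENCY_LEVELS)

#: component -> (window ms, pool name) defaults
COMPONENT_WINDOWS = {"N400": ((300.0, 450.0), "central"), "LPC": ((600.0, 800.0), "parietal")}


def parse_condition(tag: str) -> tuple[str, str]:
    parts = tag.split("/")
    if len(parts) != 2 or parts[0] not in SWITCH_LEVELS or parts[1] not in CONGRUENCY_LEVELS:
        raise ValueError(f"unknown condition label {tag!r}")
    return parts[0], parts[1]


@dataclass
class ERPSet:
    """Per-condition average waveforms (channels x samples, µV)."""

    averages: dict[str, np.ndarray] = field(repr=False)
    trial_counts: dict[str, int]
    fs: float
    window_ms: tuple[float, float]
    labels: tuple[str, ...]

    @property
    def times_ms(self) -> np.ndarray:
        n = next(iter(self.averages.values())).shape[1]
        return self.window_ms[0] + np.arange(n) / self.fs * 1000.0


def condition_average(epochs: EpochSet) -> ERPSet:
    """Pointwise mean per condition; every condition needs >= 1 trial."""
    if not epochs.tags:
        raise ValueError("epochs carry no condition tags")
    tags = np.array(epochs.tags)
    averages, counts = {}, {}
    for cond in CONDITIONS:
        sel = tags == cond
        if not sel.any():
            raise ValueError(f"condition {cond!r} has zero trials")
        averages[cond] = epochs.data[sel].mean(axis=0)
        counts[cond] = int(sel.sum())
    unknown = set(tags) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown condition labels {sorted(unknown)}")
    return ERPSet(averages, counts, epochs.fs, epochs.window_ms, epochs.labels)


def window_mean(
    erps: ERPSet,
    component: str,
    pool: tuple[str, ...],
    window_ms: tuple[float, float] | None = None,
    subject=None,
) -> pd.DataFrame:
    """Mean amplitude over pool channels and a time window, per condition."""
    if window_ms is None:
        window_ms = COMPONENT_WINDOWS[component][0]
    if not pool:
        raise ValueError("empty electrode pool")
    missing = [p for p in pool if p not in erps.labels]
    if missing:
        raise KeyError(f"pool channels {missing} not in montage")
    t = erps.times_ms
    lo, hi = window_ms
    if lo < t[0] - 1e-9 or hi > t[-1] + 1.0 / erps.fs * 1000 + 1e-9:
        raise ValueError(f"window {window_ms} outside epoch span ({t[0]}, {t[-1]}) ms")
    sel = (t >= lo) & (t < hi)
    ch = [erps.labels.index(p) for p in pool]
    rows = []
    for cond, avg in erps.averages.items():
        rows.append(
            {
                "subject": subject,
                "condition": cond,
                "component": component,
                "window_ms": window_ms,
                "amplitude_uv": float(avg[np.ix_(ch, np.flatnonzero(sel))].mean()),
            }
        )
    return pd.DataFrame(rows)


def fit_erp_model(amplitudes: pd.DataFrame, ages: pd.Series) -> dict[str, ModelResult]:
    """Switch x Congruency mixed model with age control, per component.

    Amplitudes are z-scored within component, age over subjects; treatment
    coding (reference no-switch / congruent), random intercept per subject.
    Term names: ``switch``, ``incongruent``, ``switch:incongruent``,
    ``age_z``.
    """
    out = {}
    for component, df in amplitudes.groupby("component"):
        df = df.copy()
        sw = df["condition"].map(lambda c: float(parse_condition(c)[0] == "switch"))
        ic = df["condition"].map(lambda c: float(parse_condition(c)[1] == "incongruent"))
        age = df["subject"].map(ages)
        if age.isna().any():
            raise ValueError("missing age for some subjects")
        amp = df["amplitude_uv"].to_numpy(float)
        amp_sd = amp.std(ddof=1)
        amp_z = (amp - amp.mean()) / amp_sd if amp_sd > 0 else amp * 0.0
        age_v = age.to_numpy(float)
        age_sd = age_v.std(ddof=1)
        age_z = (age_v - age_v.mean()) / age_sd if age_sd > 0 else age_v * 0.0
        exog = np.column_stack(
            [np.ones(len(df)), sw, ic, sw.to_numpy() * ic.to_numpy(), age_z]
        )
        names = ["Intercept", "switch", "incongruent", "switch:incongruent", "age_z"]
        out[component] = fit_random_intercept(
            amp_z, exog, names, df["subject"].to_numpy()
        )
    return out


def n400_effect(amplitudes: pd.DataFrame) -> pd.Series:
    """Per-subject N400 effect: no-switch minus switch window mean.

    Averaged over congruency levels; positive values mean the switch
    condition was more negative (the canonical direction).
    """
    df = amplitudes[amplitudes["component"] == "N400"]
    out = {}
    for subject, grp in df.groupby("subject"):
        g = grp.set_index("condition")["amplitude_uv"]
        missing = [c for c in CONDITIONS if c not in g.index]
        if missing:
            raise ValueError(f"subject {subject!r} missing conditions {missing}")
        no_sw = (g["no-switch/congruent"] + g["no-switch/incongruent"]) / 2.0
        sw = (g["switch/congruent"] + g["switch/incongruent"]) / 2.0
        out[subject] = float(no_sw - sw)
    return pd.Series(out, name="n400_effect")


def lpc_effect(amplitudes: pd.DataFrame) -> pd.Series:
    """Per-subject LPC effect: incongruent minus congruent window mean."""
    df = amplitudes[amplitudes["component"] == "LPC"]
    out = {}
    for subject, grp in df.groupby("subject"):
        g = grp.set_index("condition")["amplitude_uv"]
        ic = (g["no-switch/incongruent"] + g["switch/incongruent"]) / 2.0
        cg = (g["no-switch/congruent"] + g["switch/congruent"]) / 2.0
        out[subject] = float(ic - cg)
    return pd.Series(out, name="lpc_effect")


def effect_proficiency_regression(
    effects: pd.Series, proficiency_t2: pd.Series
) -> RegressionResult:
    """Standardized OLS of a per-subject ERP effect on T2 proficiency."""
    joined = pd.concat([effects, proficiency_t2], axis=1, join="inner").dropna()
    if len(joined) < 2:
        raise ValueError("need at least 2 subjects with effect and proficiency")
    return change_outcome_regression(
        joined.iloc[:, 1].to_numpy(), joined.iloc[:, 0].to_numpy()
    )


def _design(df: pd.DataFrame, ages: pd.Series):
    sw = df["condition"].map(lambda c: float(parse_condition(c)[0] == "switch"))
    ic = df["condition"].map(lambda c: float(parse_condition(c)[1] == "incongruent"))
    age = df["subject"].map(ages).to_numpy(float)
    age_sd = age.std(ddof=1)
    age_z = (age - age.mean()) / age_sd if age_sd > 0 else age * 0.0
    exog = np.column_stack([np.ones(len(df)), sw, ic, sw.to_numpy() * ic.to_numpy(), age_z])
    return exog, ["Intercept", "switch", "incongruent", "switch:incongruent", "age_z"]


def compare_random_structures(
    amplitudes: pd.DataFrame, ages: pd.Series, component: str = "N400"
) -> dict:
    """Random intercept vs intercept+slope (over Switch), by BIC (ML fits)."""
    from ._lmm import compare_random_structures as _compare

    df = amplitudes[amplitudes["component"] == component]
    exog, names = _design(df, ages)
    amp = df["amplitude_uv"].to_numpy(float)
    amp_z = (amp - amp.mean()) / amp.std(ddof=1)
    return _compare(amp_z, exog, names, df["subject"].to_numpy(), "switch")


def compare_predictors_bic(
    effects: pd.Series, predictors: dict[str, pd.Series]
) -> pd.Series:
    """BIC of OLS fits of an ERP effect on alternative predictors.

    Used to ask whether attained proficiency or task accuracy better
    explains the component effect; lower BIC wins.  Purely descriptive.
    """
    import statsmodels.api as sm_api

    out = {}
    for name, pred in predictors.items():
        joined = pd.concat([effects, pred], axis=1, join="inner").dropna()
        y = joined.iloc[:, 0].to_numpy(float)
        x = joined.iloc[:, 1].to_numpy(float)
        res = sm_api.OLS(
            (y - y.mean()) / y.std(ddof=1),
            sm_api.add_constant((x - x.mean()) / x.std(ddof=1)),
        ).fit()
        out[name] = float(res.bic)
    return pd.Series(out, name="bic")


def peak_latency(
    erps: ERPSet,
    component: str,
    pool: tuple[str, ...],
    window_ms: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Descriptive peak latency within the component window per condition.

    Local minimum for the N400, local maximum for the LPC, on the
    pool-mean waveform.
    """
    if window_ms is None:
        window_ms = COMPONENT_WINDOWS[component][0]
    t = erps.times_ms
    sel = (t >= window_ms[0]) & (t < window_ms[1])
    ch = [erps.labels.index(p) for p in pool]
    sign = -1.0 if component == "N400" else 1.0
    rows = []
    for cond, avg in erps.averages.items():
        wave = sign * avg[ch].mean(axis=0)[sel]
        rows.append(
            {
                "condition": cond,
                "component": component,
                "latency_ms": float(t[sel][int(np.argmax(wave))]),
                "peak_uv": float(sign * wave.max()),
            }
        )
    return pd.DataFrame(rows)


def comprehension_accuracy(responses: pd.DataFrame) -> tuple[pd.Series, float]:
    """Percent-correct per subject and the group mean.

    ``responses`` has one row per answered question with ``subject`` and a
    boolean ``correct`` column.
    """
    if responses.empty:
        raise ValueError("no responses")
    per = responses.groupby("subject")["correct"].agg(["sum", "count"])
    if (per["count"] == 0).any():
        raise ValueError("subject with zero answered questions")
    acc = (100.0 * per["sum"] / per["count"]).rename("accuracy_pct")
    return acc, float(acc.mean())
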