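"""End-to-end experiment runs: synth -> preprocessing -> spectral/behaviour
-> statistics (Experiment 1) and synth -> ERP analysis (Experiment 2).

Every run is a pure function of (config, seed): reports carry a config
hash, outputs are plain TSV/JSON, and regenerating a run from its logged
config reproduces it byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import erp as erp_mod
from . import io as io_mod
from . import spectral, stats_rest, synth
from ._lmm import ModelResult
from .montage import erp_pools, resting_pools
from .preprocessing import (
    EpochSet,
    bandpass_filter,
    baseline_correct,
    correct_ocular,
    detect_artifacts,
    epoch_fixed_overlap,
    extract_ec_segments,
    rereference_average,
    replace_channels,
)


@dataclass
class PrepParams:
    """Preprocessing thresholds; defaults mirror the recording protocol."""

    filter_low_hz: float = 0.1
    filter_high_hz: float = 30.0
    filter_low_rolloff_db_oct: float = 12.0
    filter_high_rolloff_db_oct: float = 48.0
    gradient_uv: float = 50.0
    maxdiff_uv: float = 200.0
    maxdiff_window_ms: float = 200.0
    lowact_uv: float = 0.5
    lowact_window_ms: float = 100.0
    pad_ms: float = 200.0
    windows: str = "sliding"
    reject_fraction: float = 0.10
    max_interp: int = 5
    k_neighbors: int = 4
    trim_s: float = 5.0
    epoch_s: float = 2.0
    overlap: float = 0.5
    taper: str = "hann"
    ocular_method: str = "regression"


@dataclass
class RunConfig:
    sim: synth.SimulationConfig = field(default_factory=synth.SimulationConfig)
    prep: PrepParams = field(default_factory=PrepParams)
    include_gamma: bool = False
    reuse_cached: bool = False

    def to_dict(self) -> dict:
        d = {"sim": synth.config_to_dict(self.sim), "prep": asdict(self.prep),
             "include_gamma": self.include_gamma, "reuse_cached": self.reuse_cached}
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Strict YAML loader: unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {"sim", "prep", "include_gamma", "reuse_cached", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    sim_kwargs = dict(raw.get("sim") or {})
    unknown = set(sim_kwargs) - set(synth.SimulationConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown sim keys {sorted(unknown)}")
    if "erp_components" in sim_kwargs:
        sim_kwargs["erp_components"] = tuple(
            synth.ErpComponent(**c) for c in sim_kwargs["erp_components"]
        )
    if "seed" in raw:
        sim_kwargs["seed"] = int(raw["seed"])
    prep_kwargs = dict(raw.get("prep") or {})
    unknown = set(prep_kwargs) - set(PrepParams.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown prep keys {sorted(unknown)}")
    return RunConfig(
        sim=synth.SimulationConfig(**sim_kwargs),
        prep=PrepParams(**prep_kwargs),
        include_gamma=bool(raw.get("include_gamma", False)),
        reuse_cached=bool(raw.get("reuse_cached", False)),
    )


# ---------------------------------------------------------------------------
# preprocessing composition

def preprocess_resting(rec, prep: PrepParams) -> tuple[EpochSet, dict]:
    """Eyes-closed preprocessing chain for one recording.

    The two EC segments are sliced first and each is filtered, ocular-
    corrected, artifact-masked, interpolated (decision pooled over both
    segments) and average-referenced; the 5-s adjustment trim is applied at
    epoching, where it also absorbs filter edge effects.
    """
    raw_segs = extract_ec_segments(rec, trim_s=0.0)
    segs = [rec.slice(s, e) for s, e in raw_segs]
    segs = [
        bandpass_filter(
            s, prep.filter_low_hz, prep.filter_high_hz,
            prep.filter_low_rolloff_db_oct, prep.filter_high_rolloff_db_oct,
        )
        for s in segs
    ]
    ocular_reports = []
    cleaned = []
    for s in segs:
        c, rep = correct_ocular(s, method=prep.ocular_method)
        cleaned.append(c)
        ocular_reports.append(rep)
    masks = [
        detect_artifacts(
            s, prep.gradient_uv, prep.maxdiff_uv, prep.maxdiff_window_ms,
            prep.lowact_uv, prep.lowact_window_ms, prep.pad_ms, prep.windows,
        )
        for s in cleaned
    ]
    flagged = sum(m.flagged_fraction() * m.n_samples for m in masks)
    total = sum(m.n_samples for m in masks)
    frac = flagged / total
    bad = np.flatnonzero(frac > prep.reject_fraction)
    if bad.size > prep.max_interp:
        raise ValueError(
            f"{bad.size} channels exceed the {prep.reject_fraction:.0%} rejection "
            f"budget (limit {prep.max_interp}): recording unusable"
        )
    if bad.size:
        cleaned = [replace_channels(s, bad, prep.k_neighbors) for s in cleaned]
        masks = [m.clear_channels(bad) for m in masks]
    cleaned = [rereference_average(s) for s in cleaned]

    trim = int(round(prep.trim_s * rec.fs))
    epoch_sets = []
    for s, m in zip(cleaned, masks):
        if s.n_samples <= 2 * trim:
            continue
        es = epoch_fixed_overlap(
            s, [(trim, s.n_samples - trim)], m, prep.epoch_s, prep.overlap
        )
        epoch_sets.append(es)
    if not epoch_sets:
        raise ValueError("no epochs survived preprocessing")
    data = np.concatenate([e.data for e in epoch_sets], axis=0)
    epochs = EpochSet(data, rec.fs, epoch_sets[0].window_ms, rec.labels)
    report = {
        "flagged_fraction": frac.tolist(),
        "replaced": [rec.labels[i] for i in bad],
        "n_epochs": epochs.n_epochs,
        "ocular": ocular_reports,
    }
    return epochs, report


def subject_band_power(
    cfg: synth.SimulationConfig,
    prep: PrepParams,
    subject: int,
    session: str = "T1",
    bands: spectral.BandScheme | None = None,
    pools: dict | None = None,
    taper: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full resting pipeline for one subject: synth EEG -> band-power rows."""
    rec, gt = synth.generate_resting_eeg(cfg, subject, session)
    if pools is None:
        pools = resting_pools(cfg.montage())
    epochs, report = preprocess_resting(rec, prep)
    spectra = spectral.epoch_psd(epochs, taper=taper or prep.taper)
    table = spectral.band_pool_means(spectra, bands or spectral.BandScheme(), pools)
    table.insert(0, "session", session)
    table.insert(0, "subject", subject)
    report["ground_truth"] = {
        "aptitude": gt.aptitude,
        "beta1_amplitude_uv": gt.beta1_amplitude_uv,
        "n_artifacts": len(gt.artifact_log),
    }
    return table, report


# ---------------------------------------------------------------------------
# Experiment 1

@dataclass
class Exp1Result:
    band_power: dict[str, pd.DataFrame]  # session -> long table
    behavior: pd.DataFrame
    correlations: pd.DataFrame
    icc: stats_rest.Icc1Result
    model: ModelResult
    wilcoxon_l2: stats_rest.WilcoxonResult | None
    wilcoxon_beta1: stats_rest.WilcoxonResult | None
    change_regression: stats_rest.RegressionResult | None
    reports: dict


def experiment1_core(
    cfg: synth.SimulationConfig,
    prep: PrepParams | None = None,
    sessions: tuple[str, ...] = ("T1", "T2"),
    include_gamma: bool = False,
) -> Exp1Result:
    """Run Experiment 1 in memory (no file output)."""
    prep = prep or PrepParams()
    bands = spectral.BandScheme.with_gamma() if include_gamma else spectral.BandScheme()
    pools = resting_pools(cfg.montage())
    tables: dict[str, list] = {s: [] for s in sessions}
    reports: dict = {s: {} for s in sessions}
    for session in sessions:
        for subject in range(cfg.n_subjects):
            tab, rep = subject_band_power(cfg, prep, subject, session, bands, pools)
            tables[session].append(tab)
            reports[session][subject] = rep
    power = {s: pd.concat(tables[s], ignore_index=True) for s in sessions}
    behav = synth.generate_behavioral_scores(cfg)
    corp = behav.set_index("subject")["corp"]

    t1 = power["T1"]
    correlations = stats_rest.spearman_fdr(t1, corp)
    icc = stats_rest.icc1(t1["log10_power"].to_numpy(), t1["subject"].to_numpy())
    model = stats_rest.fit_power_model(t1, corp)

    wil_l2 = wil_b1 = change = None
    if "T2" in power:
        wil_l2 = stats_rest.wilcoxon_paired(
            behav["composite_T1"].to_numpy(), behav["composite_T2"].to_numpy(),
            alternative="greater",
        )
        b1_t1 = (
            t1[t1["band"] == "beta1"].groupby("subject")["log10_power"].mean()
        )
        b1_t2 = (
            power["T2"][power["T2"]["band"] == "beta1"]
            .groupby("subject")["log10_power"].mean()
        )
        wil_b1 = stats_rest.wilcoxon_paired(b1_t1.to_numpy(), b1_t2.to_numpy())
        delta = spectral.band_power_change(t1, power["T2"], "beta1")
        change = stats_rest.change_outcome_regression(
            delta.reindex(corp.index).to_numpy(), corp.to_numpy()
        )
    return Exp1Result(power, behav, correlations, icc, model, wil_l2, wil_b1, change,
                      reports)


def _model_to_dict(m: ModelResult) -> dict:
    return {
        "coefficients": m.coefficients.to_dict(orient="records"),
        "var_subject": m.var_subject,
        "var_residual": m.var_residual,
        "icc1": m.icc1,
        "pseudo_r2_marginal": m.pseudo_r2_marginal,
        "n_obs": m.n_obs,
        "n_subjects": m.n_subjects,
        "loglike": m.loglike,
        "flags": m.flags,
    }


def _wilcoxon_to_dict(w: stats_rest.WilcoxonResult | None) -> dict | None:
    return None if w is None else asdict(w)


def run_experiment1(run_cfg: RunConfig, out_dir: str | Path) -> Exp1Result:
    """Experiment 1 with file outputs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cached = out / "band_power_T1.tsv"
    if run_cfg.reuse_cached and cached.exists():
        power = {
            s: pd.read_csv(out / f"band_power_{s}.tsv", sep="\t")
            for s in ("T1", "T2")
            if (out / f"band_power_{s}.tsv").exists()
        }
        behav = synth.generate_behavioral_scores(run_cfg.sim)
        corp = behav.set_index("subject")["corp"]
        t1 = power["T1"]
        result = Exp1Result(
            power, behav,
            stats_rest.spearman_fdr(t1, corp),
            stats_rest.icc1(t1["log10_power"].to_numpy(), t1["subject"].to_numpy()),
            stats_rest.fit_power_model(t1, corp),
            None, None, None, {"cached": True},
        )
    else:
        result = experiment1_core(
            run_cfg.sim, run_cfg.prep, include_gamma=run_cfg.include_gamma
        )
    for session, tab in result.band_power.items():
        io_mod.write_tsv(tab, out / f"band_power_{session}.tsv")
    io_mod.write_tsv(result.behavior, out / "behavior.tsv")
    io_mod.write_tsv(result.correlations, out / "correlations.tsv")
    io_mod.write_json(
        {
            "model": _model_to_dict(result.model),
            "icc1": asdict(result.icc),
            "wilcoxon_l2": _wilcoxon_to_dict(result.wilcoxon_l2),
            "wilcoxon_beta1": _wilcoxon_to_dict(result.wilcoxon_beta1),
            "change_regression": None
            if result.change_regression is None
            else asdict(result.change_regression),
        },
        out / "stats_exp1.json",
    )
    _write_report_exp1(result, run_cfg, out / "report_exp1.txt")
    _write_manifest(run_cfg, out, "experiment1")
    return result


def _write_report_exp1(res: Exp1Result, run_cfg: RunConfig, path: Path) -> None:
    lines = [
        "Experiment 1: resting-state band power and L2 development",
        f"config_hash: {run_cfg.config_hash()}  seed: {run_cfg.sim.seed}",
        f"subjects: {run_cfg.sim.n_subjects}  channels: {run_cfg.sim.n_channels}",
        "",
        f"ICC(1) of log power within subjects: {res.icc.icc:.3f} "
        f"(F = {res.icc.f_stat:.2f})",
        f"Mixed model marginal pseudo-R2: {res.model.pseudo_r2_marginal:.3f}",
        "",
        "Fixed effects (log10 power ~ CorP_z x Band, ref alpha):",
        res.model.coefficients.to_string(index=False, float_format="%.4f"),
        "",
        "Spearman correlations (pool x band vs CorP):",
        res.correlations.to_string(index=False, float_format="%.4f"),
    ]
    if res.wilcoxon_l2 is not None:
        lines += [
            "",
            f"Wilcoxon L2 T2>T1: W+ = {res.wilcoxon_l2.w_plus:.1f}, "
            f"p = {res.wilcoxon_l2.p_value:.4g}, r = {res.wilcoxon_l2.effect_size:.2f}",
            f"Wilcoxon beta1 T2 vs T1: W+ = {res.wilcoxon_beta1.w_plus:.1f}, "
            f"p = {res.wilcoxon_beta1.p_value:.4g}",
            f"beta1 change ~ CorP slope: {res.change_regression.slope:.3f} "
            f"[{res.change_regression.ci_low:.3f}, {res.change_regression.ci_high:.3f}]",
        ]
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Experiment 2

@dataclass
class Exp2Result:
    amplitudes: pd.DataFrame
    models: dict[str, ModelResult]
    n400_effects: pd.Series
    lpc_effects: pd.Series
    n400_regression: stats_rest.RegressionResult
    lpc_regression: stats_rest.RegressionResult
    accuracy: pd.Series
    accuracy_group: float
    latencies: pd.DataFrame
    behavior: pd.DataFrame


def experiment2_core(cfg: synth.SimulationConfig) -> Exp2Result:
    """Run Experiment 2 in memory."""
    pools = erp_pools(cfg.montage())
    behav = synth.generate_behavioral_scores(cfg)
    amp_rows, resp_rows, lat_rows = [], [], []
    for subject in range(cfg.n_subjects):
        trial_data = synth.generate_erp_dataset(cfg, subject)
        epochs = baseline_correct(trial_data.epochs, (-100.0, 0.0))
        erps = erp_mod.condition_average(epochs)
        for component, (window, pool_name) in erp_mod.COMPONENT_WINDOWS.items():
            amp_rows.append(
                erp_mod.window_mean(erps, component, pools[pool_name], window, subject)
            )
            lat = erp_mod.peak_latency(erps, component, pools[pool_name], window)
            lat.insert(0, "subject", subject)
            lat_rows.append(lat)
        resp_rows.append(trial_data.responses)
    amplitudes = pd.concat(amp_rows, ignore_index=True)
    responses = pd.concat(resp_rows, ignore_index=True)
    ages = behav.set_index("subject")["age"]
    models = erp_mod.fit_erp_model(amplitudes, ages)
    n400 = erp_mod.n400_effect(amplitudes)
    lpc = erp_mod.lpc_effect(amplitudes)
    prof = behav.set_index("subject")["composite_T2"]
    n400_reg = erp_mod.effect_proficiency_regression(n400, prof)
    lpc_reg = erp_mod.effect_proficiency_regression(lpc, prof)
    acc, acc_group = erp_mod.comprehension_accuracy(responses)
    latencies = pd.concat(lat_rows, ignore_index=True)
    return Exp2Result(
        amplitudes, models, n400, lpc, n400_reg, lpc_reg, acc, acc_group, latencies,
        behav,
    )


def run_experiment2(run_cfg: RunConfig, out_dir: str | Path) -> Exp2Result:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = experiment2_core(run_cfg.sim)
    io_mod.write_tsv(result.amplitudes, out / "window_amplitudes.tsv")
    io_mod.write_tsv(
        result.n400_effects.rename_axis("subject").reset_index(), out / "n400_effects.tsv"
    )
    io_mod.write_tsv(result.latencies, out / "latencies.tsv")
    io_mod.write_tsv(
        result.accuracy.rename_axis("subject").reset_index(), out / "accuracy.tsv"
    )
    io_mod.write_json(
        {
            "models": {k: _model_to_dict(m) for k, m in result.models.items()},
            "n400_regression": asdict(result.n400_regression),
            "lpc_regression": asdict(result.lpc_regression),
            "accuracy_group_pct": result.accuracy_group,
        },
        out / "stats_exp2.json",
    )
    lines = [
        "Experiment 2: language-switching ERPs",
        f"config_hash: {run_cfg.config_hash()}  seed: {run_cfg.sim.seed}",
        f"comprehension accuracy (group): {result.accuracy_group:.2f}%",
        "",
        "N400 model (amplitude_z ~ Switch x Congruency + age_z):",
        result.models["N400"].coefficients.to_string(index=False, float_format="%.4f"),
        "",
        "LPC model:",
        result.models["LPC"].coefficients.to_string(index=False, float_format="%.4f"),
        "",
        f"N400 effect ~ T2 proficiency: slope {result.n400_regression.slope:.3f} "
        f"[{result.n400_regression.ci_low:.3f}, {result.n400_regression.ci_high:.3f}]",
        f"LPC effect ~ T2 proficiency: slope {result.lpc_regression.slope:.3f} "
        f"[{result.lpc_regression.ci_low:.3f}, {result.lpc_regression.ci_high:.3f}]",
    ]
    (out / "report_exp2.txt").write_text("\n".join(lines) + "\n")
    _write_manifest(run_cfg, out, "experiment2")
    return result


def _write_manifest(run_cfg: RunConfig, out: Path, kind: str) -> None:
    files = sorted(
        p.name for p in out.iterdir() if p.is_file() and p.name != "MANIFEST.json"
    )
    io_mod.write_json(
        {
            "kind": kind,
            "config_hash": run_cfg.config_hash(),
            "seed": run_cfg.sim.seed,
            "config": run_cfg.to_dict(),
            "files": files,
        },
        out / "MANIFEST.json",
    )
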