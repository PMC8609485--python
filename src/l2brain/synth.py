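"""Synthetic study data: resting EEG, language-switching ERP trials,
stimulus lists and L2 test scores, with recorded ground truth.

The generator emulates the study protocol — 128-channel 512 Hz recordings,
8 min of alternating 2-min eyes-open/eyes-closed rest, a 2x2 language-
switching ERP design with 80 trials per condition, and three L2 tests at
two time points — so the whole analysis pipeline can be exercised and
validated without any recorded data.

Signal model.  Resting EEG is pink (1/f) background noise plus narrowband
oscillators, one per frequency band: a sinusoid at a random in-band carrier
frequency, random phase per channel, with slow random amplitude modulation.
A subject's latent learning aptitude (a unitless z-score) raises the beta1
(13–14.5 Hz) oscillator amplitude linearly and, through a logistic link,
the true corrected learning gain (CorP) — the brain–behaviour association
the resting analysis is meant to recover.  Ocular, voltage-step and
flatline artifacts are injected at configurable rates and every injected
event is logged.  ERP trials are pink noise plus Gaussian-windowed
components: a central negativity at 300–450 ms scaled by the condition
pattern of the switch effect and attenuated with proficiency, and a
parietal positivity at 600–800 ms for semantic incongruence.

All randomness flows from ``numpy`` generators seeded with
``(seed, stream, subject)`` so subjects are reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import behavior
from .montage import Montage, build_montage, erp_pools, frontal_channels
from .preprocessing import EpochSet, Event, Recording

# seed stream tags
_STREAM_APTITUDE = 17
_STREAM_AGE = 18
_STREAM_REST = {"T1": 1, "T2": 11}
_STREAM_ERP = 2
_STREAM_BEHAVIOR = 3


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ErpComponent:
    """A Gaussian-windowed ERP component with per-condition scaling."""

    name: str
    center_ms: float
    sd_ms: float
    peak_uv: float
    pool: str  # "central" or "parietal"
    condition_scale: dict[str, float]
    proficiency_attenuation: float = 0.0


def _default_components() -> tuple[ErpComponent, ...]:
    # Switch negativity graded by congruency (switch conditions clearly more
    # negative; mean switch-minus-no-switch scale difference is exactly 1.0
    # so the injected switch effect equals peak_uv), plus an incongruence
    # positivity.  Peaks are small, as reported for older adults.
    return (
        ErpComponent(
            name="N400",
            center_ms=375.0,
            sd_ms=40.0,
            peak_uv=-2.0,
            pool="central",
            condition_scale={
                "switch/incongruent": 1.4,
                "switch/congruent": 1.0,
                "no-switch/incongruent": 0.4,
                "no-switch/congruent": 0.0,
            },
            proficiency_attenuation=0.3,
        ),
        ErpComponent(
            name="LPC",
            center_ms=700.0,
            sd_ms=60.0,
            peak_uv=1.5,
            pool="parietal",
            condition_scale={
                "switch/incongruent": 1.0,
                "switch/congruent": 0.0,
                "no-switch/incongruent": 1.0,
                "no-switch/congruent": 0.0,
            },
            proficiency_attenuation=0.0,
        ),
    )


@dataclass
class SimulationConfig:
    """All knobs of the simulated study; defaults mirror the protocol."""

    n_subjects: int = 10
    n_channels: int = 128
    fs: float = 512.0
    ec_segment_seconds: float = 120.0
    eo_segment_seconds: float = 120.0
    n_ec_segments: int = 2
    # oscillators: band name -> mean amplitude (µV); edges from the band scheme
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: {
            "theta": 3.0, "alpha": 6.0, "beta1": 1.5, "beta2": 1.2, "beta3": 1.0
        }
    )
    oscillator_bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "theta": (4.0, 7.5), "alpha": (8.0, 12.5), "beta1": (13.0, 14.5),
            "beta2": (15.0, 17.5), "beta3": (18.0, 29.5),
        }
    )
    beta1_aptitude_slope: float = 0.5  # µV per unit latent aptitude
    beta1_t2_log10_shift: float = -0.04  # training-related beta1 power drop
    amplitude_modulation_depth: float = 0.25
    amplitude_jitter_sd: float = 0.15  # log-normal per-subject band jitter
    noise_sd: float = 10.0  # pink background, µV
    noise_jitter_sd: float = 0.10  # log-normal per-subject broadband jitter
    subject_scale_sd: float = 0.15  # log-normal whole-signal scale (conductivity)
    artifact_rates: dict[str, float] = field(
        default_factory=lambda: {"blink": 4.0, "step": 0.5, "flat": 0.2}
    )  # events per minute
    # ERP design
    erp_trials_per_condition: int = 80
    erp_window_ms: tuple[float, float] = (-100.0, 1000.0)
    erp_noise_sd: float = 6.0
    erp_components: tuple[ErpComponent, ...] = field(default_factory=_default_components)
    # behaviour
    corp_base: float = 15.0
    corp_range: float = 70.0
    corp_link_scale: float = 1.2
    corp_noise_sd: float = 5.0
    t1_mean: float = 40.0
    t1_sd: float = 18.0
    intertest_corr: float = 0.85
    t2_test_noise_sd: float = 2.5
    accuracy_base: float = 0.81
    accuracy_slope: float = 0.10
    accuracy_noise_sd: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        if self.ec_segment_seconds <= 0 or self.eo_segment_seconds <= 0:
            raise ConfigError("segment durations must be positive")
        if self.n_subjects < 1 or self.n_channels < 2 or self.n_ec_segments < 1:
            raise ConfigError("need >= 1 subject, >= 2 channels, >= 1 EC segment")
        if any(a < 0 for a in self.band_amplitudes.values()):
            raise ConfigError("band amplitudes must be >= 0")
        if set(self.band_amplitudes) - set(self.oscillator_bands):
            raise ConfigError("every amplitude needs matching oscillator band edges")
        if any(r < 0 for r in self.artifact_rates.values()):
            raise ConfigError("artifact rates must be >= 0")
        if self.erp_trials_per_condition < 1:
            raise ConfigError("need >= 1 trial per condition")
        if not 0 < self.intertest_corr <= 1:
            raise ConfigError("intertest_corr must lie in (0, 1]")

    def montage(self) -> Montage:
        return build_montage(self.n_channels)


@dataclass
class RestingGroundTruth:
    subject: int
    session: str
    aptitude: float
    beta1_amplitude_uv: float
    carrier_hz: dict[str, float]
    artifact_log: list[tuple[str, int, str]]  # (channel label, start sample, kind)


@dataclass
class ErpGroundTruth:
    subject: int
    aptitude: float
    n400_subject_scale: float
    n400_effect_uv: float  # injected switch-minus-no-switch peak, µV
    lpc_effect_uv: float
    accuracy_true: float


@dataclass
class ErpTrialData:
    epochs: EpochSet
    responses: pd.DataFrame
    ground_truth: ErpGroundTruth


def latent_aptitude(cfg: SimulationConfig, subject: int) -> float:
    """The subject's latent L2 aptitude (z-score); fixed across generators."""
    return float(
        np.random.default_rng([cfg.seed, _STREAM_APTITUDE, subject]).standard_normal()
    )


def subject_age(cfg: SimulationConfig, subject: int) -> float:
    rng = np.random.default_rng([cfg.seed, _STREAM_AGE, subject])
    return float(rng.integers(65, 75))


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float,
                f_floor: float = 0.5, chunk: int = 64) -> np.ndarray:
    """Unit-variance 1/f-power noise, synthesized in the frequency domain.

    Each half-spectrum bin is an independent complex Gaussian scaled by
    f^-1/2 (flat below ``f_floor`` to keep drift bounded); rows are
    normalized to unit variance.
    """
    from scipy import fft as sfft

    n_rows, n = shape
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    gain = (1.0 / np.sqrt(np.maximum(freqs, f_floor))).astype(np.float32)
    gain[0] = 0.0
    m = freqs.size
    # analytic unit-variance scaling (E|X_k|^2 = 2 gain_k^2; DC zero; for
    # even n the Nyquist bin is made real, contributing gain^2)
    e = 2.0 * gain.astype(np.float64) ** 2
    if n % 2 == 0:
        msq = (2.0 * e[1:-1].sum() + e[-1] / 2.0) / n**2
    else:
        msq = 2.0 * e[1:].sum() / n**2
    gain /= np.float32(np.sqrt(msq))
    out = np.empty(shape, np.float32)
    for i in range(0, n_rows, chunk):
        rows = min(chunk, n_rows - i)
        spec = rng.standard_normal((rows, m, 2), dtype=np.float32).view(np.complex64)[..., 0]
        spec *= gain
        if n % 2 == 0:
            spec[:, -1] = spec[:, -1].real
        out[i : i + rows] = sfft.irfft(spec, n=n, axis=1)
    return out


def generate_resting_eeg(
    cfg: SimulationConfig, subject: int, session: str = "T1"
) -> tuple[Recording, RestingGroundTruth]:
    """Simulate one subject's 8-min alternating EO/EC resting recording."""
    if not 0 <= subject < cfg.n_subjects:
        raise ConfigError(f"subject {subject} outside 0..{cfg.n_subjects - 1}")
    if session not in _STREAM_REST:
        raise ConfigError(f"session must be one of {sorted(_STREAM_REST)}")
    rng = np.random.default_rng([cfg.seed, _STREAM_REST[session], subject])
    apt = latent_aptitude(cfg, subject)
    montage = cfg.montage()
    n_ch = cfg.n_channels
    fs = cfg.fs

    seg_plan: list[tuple[str, int]] = []
    for _ in range(cfg.n_ec_segments):
        seg_plan.append(("eyes-open", int(round(cfg.eo_segment_seconds * fs))))
        seg_plan.append(("eyes-closed", int(round(cfg.ec_segment_seconds * fs))))
    n = sum(length for _, length in seg_plan)

    events, cursor = [], 0
    for kind, length in seg_plan:
        events.append(Event(cursor, kind))
        cursor += length

    noise_scale = cfg.noise_sd
    if cfg.noise_jitter_sd > 0:
        noise_scale *= float(np.exp(cfg.noise_jitter_sd * rng.standard_normal()))
    if noise_scale > 0:
        data = _pink_noise(rng, (n_ch, n), fs) * np.float32(noise_scale)
    else:
        data = np.zeros((n_ch, n), np.float32)

    t = (np.arange(n) / fs).astype(np.float32)
    carriers: dict[str, float] = {}
    for band in sorted(cfg.band_amplitudes):
        amp = cfg.band_amplitudes[band]
        lo, hi = cfg.oscillator_bands[band]
        f_c = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        carriers[band] = f_c
        if band == "beta1":
            amp = max(amp + cfg.beta1_aptitude_slope * apt, 0.05)
            if session == "T2":
                amp *= 10.0 ** (cfg.beta1_t2_log10_shift / 2.0)
        if cfg.amplitude_jitter_sd > 0:
            amp *= float(np.exp(cfg.amplitude_jitter_sd * rng.standard_normal()))
        if band == "beta1":
            beta1_amp = amp
        phases = rng.uniform(0, 2 * np.pi, n_ch)
        if cfg.amplitude_modulation_depth > 0:
            node_t = np.arange(0, float(t[-1]) + 2.0, 2.0)
            env_nodes = 1.0 + cfg.amplitude_modulation_depth * rng.standard_normal(node_t.size)
            env = np.interp(t, node_t, np.clip(env_nodes, 0.0, None)).astype(np.float32)
        else:
            env = np.ones(n, np.float32)
        if amp == 0:
            continue
        # sin(theta + phi_c) expanded so the n-length carrier is shared by channels
        theta = np.float32(2 * np.pi * f_c) * t
        es, ec = env * np.sin(theta), env * np.cos(theta)
        cphi = (amp * np.cos(phases)).astype(np.float32)
        sphi = (amp * np.sin(phases)).astype(np.float32)
        data += cphi[:, None] * es + sphi[:, None] * ec
    if "beta1" not in cfg.band_amplitudes:
        beta1_amp = 0.0

    # shared per-subject scale on the neural signal (not on artifacts):
    # electrode/skull geometry moves all bands together
    if cfg.subject_scale_sd > 0:
        scale = float(np.exp(cfg.subject_scale_sd * rng.standard_normal()))
        data *= np.float32(scale)
        beta1_amp *= scale

    minutes = n / fs / 60.0
    frontal = frontal_channels(montage)
    fidx = [montage.index(lab) for lab in frontal]
    log: list[tuple[str, int, str]] = []
    for kind in sorted(cfg.artifact_rates):
        rate = cfg.artifact_rates[kind]
        n_events = int(rng.poisson(rate * minutes)) if rate > 0 else 0
        for _ in range(n_events):
            if kind == "blink":
                dur = int(round(0.4 * fs))
                start = int(rng.integers(0, max(1, n - dur)))
                amp = float(rng.uniform(100.0, 200.0))
                tt = np.arange(dur) / fs
                tpl = amp * (
                    np.exp(-(((tt - 0.16) / 0.06) ** 2)) - 0.3 * np.exp(-(((tt - 0.28) / 0.09) ** 2))
                )
                data[fidx, start : start + dur] += tpl.astype(np.float32)
                for i in fidx:
                    log.append((montage.labels[i], start, "blink"))
            elif kind == "step":
                ch = int(rng.integers(0, n_ch))
                dur = int(round(float(rng.uniform(0.5, 2.0)) * fs))
                start = int(rng.integers(0, max(1, n - dur)))
                amp = float(rng.uniform(60.0, 150.0)) * (1 if rng.random() < 0.5 else -1)
                data[ch, start : start + dur] += np.float32(amp)
                log.append((montage.labels[ch], start, "step"))
            elif kind == "flat":
                ch = int(rng.integers(0, n_ch))
                dur = int(round(float(rng.uniform(0.35, 1.0)) * fs))
                start = int(rng.integers(0, max(1, n - dur)))
                data[ch, start : start + dur] = data[ch, start]
                log.append((montage.labels[ch], start, "flat"))
            else:
                raise ConfigError(f"unknown artifact kind {kind!r}")

    rec = Recording(data, fs, montage.labels, montage.positions, events)
    gt = RestingGroundTruth(subject, session, apt, float(beta1_amp), carriers, log)
    return rec, gt


def generate_erp_dataset(cfg: SimulationConfig, subject: int) -> ErpTrialData:
    """Simulate one subject's 4 x 80 language-switching ERP trials."""
    if not 0 <= subject < cfg.n_subjects:
        raise ConfigError(f"subject {subject} outside 0..{cfg.n_subjects - 1}")
    from .erp import CONDITIONS

    rng = np.random.default_rng([cfg.seed, _STREAM_ERP, subject])
    apt = latent_aptitude(cfg, subject)
    montage = cfg.montage()
    pools = erp_pools(montage)
    fs = cfg.fs
    w0, w1 = cfg.erp_window_ms
    n_t = int(np.rint((w1 - w0) / 1000.0 * fs))
    times = w0 + np.arange(n_t) / fs * 1000.0
    n_trials = 4 * cfg.erp_trials_per_condition
    tags = [c for c in CONDITIONS for _ in range(cfg.erp_trials_per_condition)]
    order = rng.permutation(n_trials)
    tags = [tags[i] for i in order]

    if cfg.erp_noise_sd > 0:
        data = _pink_noise(rng, (n_trials * cfg.n_channels, n_t), fs, f_floor=1.0)
        data = data.reshape(n_trials, cfg.n_channels, n_t) * np.float32(cfg.erp_noise_sd)
    else:
        data = np.zeros((n_trials, cfg.n_channels, n_t), np.float32)

    tag_arr = np.array(tags)
    gt_effects: dict[str, float] = {}
    n400_scale = 1.0
    for comp in cfg.erp_components:
        for unknown in set(comp.condition_scale) - set(CONDITIONS):
            raise ConfigError(f"component {comp.name}: unknown condition {unknown!r}")
        subj_scale = max(0.0, 1.0 - comp.proficiency_attenuation * apt)
        if comp.name == "N400":
            n400_scale = subj_scale
        tpl = comp.peak_uv * np.exp(-(((times - comp.center_ms) / comp.sd_ms) ** 2) / 2.0)
        ch = [montage.index(lab) for lab in pools[comp.pool]]
        sw = np.mean([comp.condition_scale.get(f"switch/{c}", 0.0) for c in ("congruent", "incongruent")])
        ns = np.mean([comp.condition_scale.get(f"no-switch/{c}", 0.0) for c in ("congruent", "incongruent")])
        ic = np.mean([comp.condition_scale.get(f"{s}/incongruent", 0.0) for s in ("switch", "no-switch")])
        cg = np.mean([comp.condition_scale.get(f"{s}/congruent", 0.0) for s in ("switch", "no-switch")])
        if comp.name == "N400":
            gt_effects["N400"] = float(comp.peak_uv * subj_scale * (sw - ns))
        if comp.name == "LPC":
            gt_effects["LPC"] = float(comp.peak_uv * subj_scale * (ic - cg))
        for cond, scale in comp.condition_scale.items():
            amp = subj_scale * scale
            if amp == 0:
                continue
            sel = np.flatnonzero(tag_arr == cond)
            data[np.ix_(sel, ch)] += np.float32(amp) * tpl.astype(np.float32)

    epochs = EpochSet(data, fs, (w0, w1), montage.labels, tags)

    n_q = max(1, int(round(n_trials / 3.0)))
    q_trials = np.sort(rng.choice(n_trials, size=n_q, replace=False))
    p_true = float(
        np.clip(
            cfg.accuracy_base + cfg.accuracy_slope * apt
            + cfg.accuracy_noise_sd * rng.standard_normal(),
            0.5, 0.98,
        )
    )
    correct = rng.random(n_q) < p_true
    responses = pd.DataFrame(
        {"subject": subject, "trial": q_trials, "correct": correct}
    )
    gt = ErpGroundTruth(
        subject=subject,
        aptitude=apt,
        n400_subject_scale=n400_scale,
        n400_effect_uv=gt_effects.get("N400", 0.0),
        lpc_effect_uv=gt_effects.get("LPC", 0.0),
        accuracy_true=p_true,
    )
    return ErpTrialData(epochs, responses, gt)


def generate_behavioral_scores(
    cfg: SimulationConfig, aptitudes: Sequence[float] | None = None
) -> pd.DataFrame:
    """Per-subject L2 test percentiles at T1/T2, composites and CorP.

    Three correlated T1 tests (shared-ability model tuned to
    ``intertest_corr``), a true CorP drawn from a logistic link on
    aptitude, and T2 scores back-computed so the realized corrected gain
    matches the true one up to test noise.
    """
    n = cfg.n_subjects
    if aptitudes is None:
        aptitudes = [latent_aptitude(cfg, s) for s in range(n)]
    aptitudes = np.asarray(list(aptitudes), float)
    if aptitudes.size != n:
        raise ConfigError("one aptitude per subject required")
    rng = np.random.default_rng([cfg.seed, _STREAM_BEHAVIOR])
    ability = np.clip(cfg.t1_mean + cfg.t1_sd * rng.standard_normal(n), 2.0, 85.0)
    r = cfg.intertest_corr
    sd_e = cfg.t1_sd * np.sqrt((1 - r) / r) if r < 1 else 0.0
    t1_tests = np.clip(
        ability[:, None] + sd_e * rng.standard_normal((n, 3)), 0.0, 100.0
    )
    true_corp = np.clip(
        cfg.corp_base
        + cfg.corp_range / (1.0 + np.exp(-cfg.corp_link_scale * aptitudes))
        + cfg.corp_noise_sd * rng.standard_normal(n),
        1.0, 99.0,
    )
    t1c = t1_tests.mean(axis=1)
    t2_target = t1c + true_corp * (100.0 - t1c) / 100.0
    t2_tests = np.clip(
        t2_target[:, None] + cfg.t2_test_noise_sd * rng.standard_normal((n, 3)),
        0.0, 100.0,
    )
    t1_df = pd.DataFrame(t1_tests, columns=list(behavior.TESTS))
    t1_df.insert(0, "subject", np.arange(n))
    t2_df = pd.DataFrame(t2_tests, columns=list(behavior.TESTS))
    t2_df.insert(0, "subject", np.arange(n))
    out = behavior.assessment_table(t1_df, t2_df)
    out["true_corp"] = true_corp
    out["aptitude"] = aptitudes
    out["age"] = [subject_age(cfg, s) for s in range(n)]
    return out


# ---------------------------------------------------------------------------
# stimulus material

@dataclass(frozen=True)
class LexEntry:
    l2: str  # English form
    l1: str  # German form

    def letter_difference(self) -> int:
        return _levenshtein(self.l2.lower(), self.l1.lower())


def _levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


DEFAULT_NOUNS = tuple(
    LexEntry(*p)
    for p in [
        ("book", "Buch"), ("potato", "Kartoffel"), ("girl", "Mädchen"),
        ("teacher", "Lehrer"), ("dog", "Hund"), ("cat", "Katze"),
        ("apple", "Apfel"), ("letter", "Brief"), ("house", "Haus"),
        ("garden", "Garten"), ("water", "Wasser"), ("bread", "Brot"),
        ("table", "Tisch"), ("chair", "Stuhl"), ("car", "Auto"),
        ("city", "Stadt"), ("child", "Kind"), ("song", "Lied"),
        ("door", "Tür"), ("window", "Fenster"),
    ]
)
DEFAULT_VERBS = tuple(
    LexEntry(*p)
    for p in [
        ("see", "sehen"), ("write", "schreiben"), ("read", "lesen"),
        ("eat", "essen"), ("drink", "trinken"), ("buy", "kaufen"),
        ("find", "finden"), ("like", "mögen"), ("want", "wollen"),
        ("open", "öffnen"), ("close", "schließen"), ("carry", "tragen"),
        ("paint", "malen"), ("wash", "waschen"), ("bring", "bringen"),
    ]
)

_TEMPLATES = (
    "The {s} that does not {v1} {v2}s a {t}",
    "The {s} that does not {v1} much {v2}s a {t}",
    "The {s} that really does not {v1} much {v2}s a {t}",
    "The {s} that really does not {v1} very much {v2}s a {t}",
)


class StimulusError(ValueError):
    pass


def generate_stimulus_list(
    n_sentences: int = 80,
    nouns: Sequence[LexEntry] = DEFAULT_NOUNS,
    verbs: Sequence[LexEntry] = DEFAULT_VERBS,
    seed: int = 0,
) -> pd.DataFrame:
    """Build the sentence set; each sentence appears in all four conditions.

    Noun and verb usage follows balanced round-robin quotas (shuffled
    starting order); sentence-final targets are restricted to nouns whose
    English and German forms differ in at least two letters, so a language
    switch is always orthographically detectable.  Returns one row per
    sentence x condition (4 * n_sentences rows).
    """
    if n_sentences < 1:
        raise StimulusError("need at least 1 sentence")
    if len(verbs) < 2:
        raise StimulusError(f"need >= 2 verbs, got {len(verbs)}")
    eligible = [e for e in nouns if e.letter_difference() >= 2]
    if len(eligible) < 2:
        raise StimulusError(
            f"need >= 2 switch-eligible target nouns (letter difference >= 2); "
            f"only {len(eligible)} of {len(nouns)} qualify"
        )
    rng = np.random.default_rng(seed)
    noun_order = list(rng.permutation(len(nouns)))
    elig_order = list(rng.permutation(len(eligible)))
    verb_order = list(rng.permutation(len(verbs)))

    rows = []
    for i in range(n_sentences):
        subj = nouns[noun_order[i % len(nouns)]]
        target = eligible[elig_order[i % len(eligible)]]
        if target.l2 == subj.l2:  # subject must differ from target
            target = eligible[elig_order[(i + 1) % len(eligible)]]
        incong = eligible[elig_order[(i + len(eligible) // 2) % len(eligible)]]
        if incong.l2 == target.l2:
            incong = eligible[elig_order[(i + 1 + len(eligible) // 2) % len(eligible)]]
        v1 = verbs[verb_order[i % len(verbs)]]
        v2 = verbs[verb_order[(i + len(verbs) // 2) % len(verbs)]]
        if v2.l2 == v1.l2:
            v2 = verbs[verb_order[(i + 1 + len(verbs) // 2) % len(verbs)]]
        template = _TEMPLATES[i % len(_TEMPLATES)]
        stem = template.format(s=subj.l2, v1=v1.l2, v2=v2.l2, t="{t}")
        for switch in ("no-switch", "switch"):
            for congruency in ("congruent", "incongruent"):
                tgt = target if congruency == "congruent" else incong
                final = tgt.l1 if switch == "switch" else tgt.l2
                text = stem.format(t=final)
                rows.append(
                    {
                        "sentence_id": i,
                        "condition": f"{switch}/{congruency}",
                        "switch": switch == "switch",
                        "congruent": congruency == "congruent",
                        "text": text,
                        "target_l2": tgt.l2,
                        "target_l1": tgt.l1,
                        "final_word": final,
                        "n_words": len(text.split()),
                    }
                )
    return pd.DataFrame(rows)


def config_to_dict(cfg: SimulationConfig) -> dict:
    """JSON-serializable dump (for manifests and config hashing)."""
    d = asdict(cfg)
    d["erp_components"] = [asdict(c) for c in cfg.erp_components]
    return d
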