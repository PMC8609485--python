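"""Synthetic-data generator: determinism, degenerate configs, ground-truth
recovery, stimulus quotas and behavioral structure."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from l2brain import synth
from l2brain.montage import frontal_channels
from l2brain.synth import ConfigError, LexEntry, SimulationConfig, StimulusError

NO_ARTIFACTS = {"blink": 0.0, "step": 0.0, "flat": 0.0}


def pure_tone_cfg(**kw):
    base = dict(
        n_subjects=2,
        n_channels=8,
        ec_segment_seconds=4.0,
        eo_segment_seconds=2.0,
        band_amplitudes={"osc": 2.0},
        oscillator_bands={"osc": (10.0, 10.0)},
        noise_sd=0.0,
        noise_jitter_sd=0.0,
        amplitude_jitter_sd=0.0,
        subject_scale_sd=0.0,
        amplitude_modulation_depth=0.0,
        artifact_rates=NO_ARTIFACTS,
        seed=3,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"fs": 0.0},
            {"ec_segment_seconds": -1.0},
            {"band_amplitudes": {"alpha": -1.0}},
            {"artifact_rates": {"blink": -2.0}},
            {"erp_trials_per_condition": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigError):
            SimulationConfig(**kw)


class TestRestingEeg:
    def test_deterministic(self, fast_cfg):
        a, ga = synth.generate_resting_eeg(fast_cfg, 1)
        b, gb = synth.generate_resting_eeg(fast_cfg, 1)
        np.testing.assert_array_equal(a.data, b.data)
        assert ga == gb

    def test_protocol_events(self, fast_cfg):
        rec, _ = synth.generate_resting_eeg(fast_cfg, 0)
        kinds = [e.kind for e in rec.events]
        assert kinds == ["eyes-open", "eyes-closed"] * 2
        assert rec.fs == 512.0

    def test_degenerate_config_pure_sinusoid(self):
        rec, _ = synth.generate_resting_eeg(pure_tone_cfg(), 0)
        for ch in range(rec.n_channels):
            x = np.asarray(rec.data[ch], np.float64)
            amp = np.sqrt(2) * x.std()
            assert amp == pytest.approx(2.0, rel=1e-3)
            # single-frequency check via the DFT peak
            spec = np.abs(np.fft.rfft(x))
            freqs = np.fft.rfftfreq(x.size, 1 / rec.fs)
            assert freqs[spec.argmax()] == pytest.approx(10.0, abs=0.1)

    def test_oscillator_peaks_in_configured_bands(self, fast_cfg):
        # brute-force periodogram peak per band, artifacts off
        cfg = replace(
            fast_cfg, artifact_rates=NO_ARTIFACTS, noise_sd=1.0,
            amplitude_modulation_depth=0.0,
        )
        rec, gt = synth.generate_resting_eeg(cfg, 2)
        x = np.asarray(rec.data[0], np.float64)
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(x.size, 1 / rec.fs)
        for band, (lo, hi) in cfg.oscillator_bands.items():
            sel = (freqs > lo - 0.5) & (freqs <= hi + 0.5)
            peak_f = freqs[sel][spec[sel].argmax()]
            assert lo - 0.5 <= peak_f <= hi + 0.5
            assert lo <= gt.carrier_hz[band] <= hi

    def test_beta1_amplitude_tracks_aptitude(self):
        cfg = SimulationConfig(
            n_subjects=12, n_channels=8, ec_segment_seconds=4.0, eo_segment_seconds=2.0,
            beta1_aptitude_slope=1.0, amplitude_jitter_sd=0.0, subject_scale_sd=0.0,
            seed=11,
        )
        apts, amps = [], []
        for s in range(cfg.n_subjects):
            _, gt = synth.generate_resting_eeg(cfg, s)
            apts.append(gt.aptitude)
            amps.append(gt.beta1_amplitude_uv)
        rho = stats.spearmanr(apts, amps).statistic
        assert rho > 0.95

    def test_artifact_log_matches_injected_events(self, fast_cfg):
        cfg = replace(fast_cfg, artifact_rates={"blink": 6.0, "step": 4.0, "flat": 3.0})
        rec, gt = synth.generate_resting_eeg(cfg, 0)
        assert gt.artifact_log, "expected artifacts at these rates"
        frontal = set(frontal_channels(cfg.montage()))
        for label, start, kind in gt.artifact_log:
            assert 0 <= start < rec.n_samples
            ch = rec.labels.index(label)
            if kind == "flat":
                seg = rec.data[ch, start : start + int(0.3 * rec.fs)]
                assert seg.max() - seg.min() < 0.5
            elif kind == "step":
                d = np.abs(np.diff(rec.data[ch, max(0, start - 2) : start + 2].astype(float)))
                assert d.max() >= 50.0
            elif kind == "blink":
                assert label in frontal

    def test_subject_out_of_range_rejected(self, fast_cfg):
        with pytest.raises(ConfigError):
            synth.generate_resting_eeg(fast_cfg, 99)


class TestErpDataset:
    def small_cfg(self, **kw):
        base = dict(n_subjects=3, n_channels=16, erp_trials_per_condition=10, seed=5)
        base.update(kw)
        return SimulationConfig(**base)

    def test_deterministic(self):
        cfg = self.small_cfg()
        a = synth.generate_erp_dataset(cfg, 0)
        b = synth.generate_erp_dataset(cfg, 0)
        np.testing.assert_array_equal(a.epochs.data, b.epochs.data)
        assert a.epochs.tags == b.epochs.tags
        assert a.responses.equals(b.responses)

    def test_design_counts_and_window(self):
        cfg = self.small_cfg()
        out = synth.generate_erp_dataset(cfg, 1)
        assert out.epochs.n_epochs == 40
        tags = np.array(out.epochs.tags)
        for cond in set(tags):
            assert (tags == cond).sum() == 10
        assert out.epochs.window_ms == (-100.0, 1000.0)
        assert out.epochs.data.shape[2] == int(np.rint(1.1 * cfg.fs))

    def test_no_components_null_averages(self):
        cfg = self.small_cfg(erp_components=(), erp_trials_per_condition=40)
        out = synth.generate_erp_dataset(cfg, 0)
        tags = np.array(out.epochs.tags)
        for cond in set(tags):
            avg = out.epochs.data[tags == cond].mean(axis=0)
            assert np.abs(avg).max() < 5 * cfg.erp_noise_sd / np.sqrt(40)

    def test_noise_free_switch_effect_matches_template_integral(self):
        comp = synth.ErpComponent(
            name="N400", center_ms=375.0, sd_ms=40.0, peak_uv=-2.0, pool="central",
            condition_scale={"switch/congruent": 1.0, "switch/incongruent": 1.0},
            proficiency_attenuation=0.0,
        )
        cfg = self.small_cfg(erp_noise_sd=0.0, erp_components=(comp,))
        out = synth.generate_erp_dataset(cfg, 0)
        from l2brain.montage import erp_pools

        pool = erp_pools(cfg.montage())["central"]
        ch = [out.epochs.labels.index(p) for p in pool]
        t = out.epochs.times_ms
        sel = (t >= 300) & (t < 450)
        tags = np.array(out.epochs.tags)
        sw = out.epochs.data[tags == "switch/congruent"][:, ch][:, :, sel].mean()
        ns = out.epochs.data[tags == "no-switch/congruent"][:, ch][:, :, sel].mean()
        # independent closed-form: window mean of the Gaussian template
        expected = -2.0 * np.mean(np.exp(-(((t[sel] - 375.0) / 40.0) ** 2) / 2))
        assert sw - ns == pytest.approx(expected, abs=1e-5)

    def test_unknown_condition_label_rejected(self):
        comp = synth.ErpComponent(
            name="N400", center_ms=375, sd_ms=40, peak_uv=-2, pool="central",
            condition_scale={"bogus": 1.0},
        )
        with pytest.raises(ConfigError):
            synth.generate_erp_dataset(self.small_cfg(erp_components=(comp,)), 0)


class TestBehavioralScores:
    def test_zero_noise_identical_aptitude_identical_corp(self):
        cfg = SimulationConfig(
            n_subjects=5, corp_noise_sd=0.0, t2_test_noise_sd=0.0, seed=1
        )
        out = synth.generate_behavioral_scores(cfg, aptitudes=[0.3] * 5)
        assert np.allclose(out["corp"], out["corp"].iloc[0], atol=1e-9)

    def test_first_pc_share_above_80(self):
        from l2brain.behavior import first_pc_variance_share

        cfg = SimulationConfig(n_subjects=200, seed=4)
        out = synth.generate_behavioral_scores(cfg)
        share = first_pc_variance_share(
            out[["c_test_T1", "course_test_T1", "listening_T1"]].to_numpy()
        )
        # generating covariance: equicorrelation 0.85 -> (1 + 2*0.85)/3 = 90%
        assert share > 80.0

    def test_monotone_link_aptitude_to_corp(self):
        cfg = SimulationConfig(
            n_subjects=50, corp_noise_sd=1.0, t2_test_noise_sd=0.5, seed=9
        )
        out = synth.generate_behavioral_scores(cfg)
        rho = stats.spearmanr(out["aptitude"], out["corp"]).statistic
        assert rho > 0.9

    def test_corp_moments_match_configuration(self):
        cfg = SimulationConfig(n_subjects=300, seed=13)
        out = synth.generate_behavioral_scores(cfg)
        # oracle: quadrature over the standard normal for the logistic link
        z = np.linspace(-8, 8, 4001)
        w = stats.norm.pdf(z)
        w /= w.sum()
        link = cfg.corp_base + cfg.corp_range / (1 + np.exp(-cfg.corp_link_scale * z))
        mean_th = float(link @ w)
        var_th = float(((link - mean_th) ** 2) @ w) + cfg.corp_noise_sd**2
        n = cfg.n_subjects
        se_mean = np.sqrt(var_th / n)
        assert abs(out["true_corp"].mean() - mean_th) < 2 * se_mean
        se_sd = np.sqrt(var_th / (2 * n))  # delta-method SE of the SD
        assert abs(out["true_corp"].std() - np.sqrt(var_th)) < 2 * se_sd

    def test_percentiles_bounded(self):
        cfg = SimulationConfig(n_subjects=100, seed=2)
        out = synth.generate_behavioral_scores(cfg)
        cols = [c for c in out.columns if c.endswith(("_T1", "_T2"))]
        vals = out[cols].to_numpy()
        assert vals.min() >= 0 and vals.max() <= 100


class TestStimulusList:
    def test_paper_design_counts(self):
        table = synth.generate_stimulus_list(80)
        assert len(table) == 320
        assert table["condition"].value_counts().eq(80).all()
        assert table["n_words"].between(9, 12).all()

    def test_single_sentence_four_conditions(self):
        table = synth.generate_stimulus_list(1)
        assert len(table) == 4
        assert table["condition"].nunique() == 4

    def test_close_orthography_excluded_from_targets(self):
        # garden/Garten differ in one letter -> never a sentence-final target
        assert LexEntry("garden", "Garten").letter_difference() == 1
        table = synth.generate_stimulus_list(80)
        assert "garden" not in set(table["target_l2"])
        # switch rows present the German form of an eligible noun
        sw = table[table["switch"]]
        assert (sw["final_word"] == sw["target_l1"]).all()

    def test_round_robin_balance(self):
        table = synth.generate_stimulus_list(80)
        per_sentence = table[~table["switch"] & table["congruent"]]
        counts = per_sentence["target_l2"].value_counts()
        # round-robin with collision shifts: near-uniform target usage
        assert counts.max() - counts.min() <= 3

    def test_lexicon_too_small_rejected(self):
        bad_nouns = [LexEntry("garden", "Garten"), LexEntry("hand", "Hand")]
        with pytest.raises(StimulusError, match="eligible"):
            synth.generate_stimulus_list(4, nouns=bad_nouns)
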