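"""Synthetic-signal generator: ground-truth recovery and determinism."""

import dataclasses

import numpy as np
import pytest

import hipfatigue as hf
from hipfatigue.features import mean_abs_signal, mean_frequency, wobble_measures
from hipfatigue.preprocess import resultant, segment
from hipfatigue.synthetic import cohort_truth, generate_accel, generate_semg


def periodogram_mnf(x, fs):
    """Independent oracle: direct periodogram mean frequency (no band limit)."""
    p = np.abs(np.fft.rfft(np.asarray(x, float))) ** 2
    f = np.fft.rfftfreq(len(x), 1 / fs)
    return float((f * p).sum() / p.sum())


class TestGenerateSemg:
    def test_sample_count_at_acquisition_rate(self):
        rec = generate_semg(hf.SemgSynthParams(seed=0))
        assert rec.samples.size == 393_300  # 90 s at 4370 Hz
        assert rec.fs == 4370.0

    def test_seed_determinism(self, small_semg_params):
        a = generate_semg(small_semg_params)
        b = generate_semg(small_semg_params)
        assert np.array_equal(a.samples, b.samples)

    def test_different_seed_differs(self, small_semg_params):
        a = generate_semg(small_semg_params)
        b = generate_semg(dataclasses.replace(small_semg_params, seed=99))
        assert not np.array_equal(a.samples, b.samples)

    def test_zero_mean(self, small_semg_params):
        rec = generate_semg(small_semg_params)
        assert abs(np.mean(rec.samples)) < 5 * np.std(rec.samples) / np.sqrt(rec.samples.size)

    def test_stationary_when_no_drift(self):
        p = hf.SemgSynthParams(
            duration_s=60.0, fs_emg=2000.0, center_freq0=120.0, rel_mnf_slope=0.0,
            bandwidth=60.0, rel_amp_slope=0.0, noise_floor=0.0, seed=3,
        )
        rec = generate_semg(p)
        half = rec.samples.size // 2
        m1 = periodogram_mnf(rec.samples[:half], rec.fs)
        m2 = periodogram_mnf(rec.samples[half:], rec.fs)
        assert abs(m1 - m2) / m1 < 0.02

    def test_block_mnf_tracks_programmed_center(self):
        """Periodogram oracle per 1/10 block stays within bandwidth/4 of the carrier."""
        p = hf.SemgSynthParams(
            duration_s=90.0, fs_emg=4370.0, center_freq0=100.0, rel_mnf_slope=-0.003,
            bandwidth=60.0, noise_floor=0.0, seed=5,
        )
        rec = generate_semg(p)
        seg = segment(rec.samples, rec.fs, 10)
        for i, block in enumerate(seg.intervals):
            t_mid = (i + 0.5) * seg.interval_duration
            programmed = p.center_freq0 * (1 + p.rel_mnf_slope * t_mid)
            assert abs(periodogram_mnf(block, rec.fs) - programmed) < p.bandwidth / 4

    def test_downstream_slope_recovery_against_oracle(self):
        """Fitted relative MNF slope recovers the programmed -0.3 %/s."""
        p = hf.SemgSynthParams(
            center_freq0=100.0, rel_mnf_slope=-0.003, noise_floor=0.0, seed=2,
        )
        rec = generate_semg(p)
        seg = segment(rec.samples, rec.fs, 10)
        mnfs = [periodogram_mnf(b, rec.fs) for b in seg.intervals]
        t = (np.arange(10) + 0.5) * seg.interval_duration
        reg = hf.interval_regression(mnfs, t)
        rel = 100 * reg.slope / reg.intercept
        assert rel == pytest.approx(-0.3, rel=0.10)

    def test_amplitude_envelope_recovered(self):
        """Block mean-abs scales linearly with the programmed envelope (R² > 0.95)."""
        p = hf.SemgSynthParams(
            duration_s=60.0, fs_emg=2000.0, center_freq0=120.0, bandwidth=60.0,
            rel_mnf_slope=0.0, rel_amp_slope=0.01, noise_floor=2e-6, seed=4,
        )
        rec = generate_semg(p)
        seg = segment(rec.samples, rec.fs, 10)
        measured = [mean_abs_signal(b) for b in seg.intervals]
        t = (np.arange(10) + 0.5) * seg.interval_duration
        envelope = p.amp0 * (1 + p.rel_amp_slope * t)
        r = np.corrcoef(measured, envelope)[0, 1]
        assert r**2 > 0.95

    @pytest.mark.parametrize(
        "bad",
        [
            dict(duration_s=-1.0),
            dict(fs_emg=250.0),           # Nyquist-unsafe for the default band
            dict(center_freq0=10.0),      # below the analysis band
            dict(center_freq0=450.0, fs_emg=2000.0),
            dict(bandwidth=0.0),
            dict(rel_amp_slope=-0.01),
        ],
    )
    def test_invalid_params_raise(self, bad):
        with pytest.raises(ValueError):
            hf.SemgSynthParams(**bad)


class TestGenerateAccel:
    def test_sample_count_at_acquisition_rate(self):
        rec = generate_accel(hf.AccelSynthParams(seed=0))
        assert rec.n_samples == 33_300  # 90 s at 370 Hz
        assert rec.fs == 370.0

    def test_seed_determinism(self, small_accel_params):
        a = generate_accel(small_accel_params)
        b = generate_accel(small_accel_params)
        assert np.array_equal(a.ax, b.ax) and np.array_equal(a.az, b.az)

    def test_gravity_offset_on_one_axis(self, small_accel_params):
        rec = generate_accel(small_accel_params)
        assert np.mean(rec.az) == pytest.approx(small_accel_params.gravity, rel=0.01)
        assert abs(np.mean(rec.ax)) < 0.1

    def test_stationary_tremor_gives_identical_interval_auc(self):
        p = hf.AccelSynthParams(
            duration_s=43.0, fs_imu=100.0, rel_tremor_slope=0.0, noise_sd=0.0, seed=1,
        )
        rec = generate_accel(p)
        seg = segment(resultant(rec), rec.fs, 10)
        aucs = [wobble_measures(b, rec.fs)[1] for b in seg.intervals]
        assert np.allclose(aucs, aucs[0], rtol=1e-9)

    def test_growing_tremor_max_nondecreasing_in_expectation(self):
        """Monte-Carlo over 20 seeds: mean interval-max sequence tracks the envelope."""
        maxima = np.zeros(10)
        for seed in range(20):
            p = hf.AccelSynthParams(
                duration_s=43.0, fs_imu=100.0, rel_tremor_slope=0.02,
                noise_sd=0.02, seed=seed,
            )
            seg = segment(resultant(generate_accel(p)), 100.0, 10)
            maxima += [b.max() for b in seg.intervals]
        maxima /= 20
        assert np.all(np.diff(maxima) > -1e-6)

    def test_tremor_above_nyquist_raises(self):
        with pytest.raises(ValueError, match="Nyquist"):
            hf.AccelSynthParams(fs_imu=100.0, tremor_freq=60.0)


class TestCohort:
    def test_study_sized_cohort_has_120_trials(self):
        spec = hf.CohortSpec(
            n_subjects=24,
            semg=hf.SemgSynthParams(duration_s=1.0, fs_emg=400.0, center_freq0=90.0,
                                    bandwidth=30.0),
            accel=hf.AccelSynthParams(duration_s=1.0, fs_imu=50.0),
        )
        trials, truth = hf.generate_cohort(spec)
        assert len(trials) == 120 and truth.shape[0] == 120
        assert truth["subject"].nunique() == 24
        assert truth["activity"].nunique() == 5

    def test_truth_deterministic_under_master_seed(self, small_cohort_spec):
        t1 = cohort_truth(small_cohort_spec)
        t2 = cohort_truth(small_cohort_spec)
        assert t1.equals(t2)

    def test_zero_responder_fraction_means_no_programmed_fatigue(self, small_cohort_spec):
        spec = dataclasses.replace(small_cohort_spec, responder_fraction=0.0)
        truth = cohort_truth(spec)
        for m in hf.MUSCLES:
            assert (truth[f"rel_mnf_slope_{m}"] == 0).all()
            assert not truth[f"fatigue_{m}"].any()

    def test_trials_carry_truth_and_are_deterministic(self, small_cohort_spec):
        trials, truth = hf.generate_cohort(small_cohort_spec)
        trials2, _ = hf.generate_cohort(small_cohort_spec)
        assert trials[0].truth is not None
        assert np.array_equal(
            trials[3].emg["gluteus_medius"].samples,
            trials2[3].emg["gluteus_medius"].samples,
        )

    def test_full_label_recovery_on_strong_cohort(self, small_cohort_spec):
        """End-to-end: all-responder, low-noise cohort -> >= 90% labels recovered."""
        spec = dataclasses.replace(
            small_cohort_spec,
            responder_fraction=1.0,
            fatigue_slope_range=(-0.005, -0.004),
            semg=dataclasses.replace(small_cohort_spec.semg, noise_floor=1e-7),
        )
        from hipfatigue.features import build_feature_table, normalize
        from hipfatigue.pipeline import mnf_trial_regressions

        raw = build_feature_table(hf.iter_cohort(spec), hf.FeatureConfig(normalize=False))
        norm = normalize(raw, "subject")
        regs = mnf_trial_regressions(raw, norm)
        flagged = ((regs["slope"] < 0) & (regs["p_slope"] < 0.05)).mean()
        assert flagged >= 0.9
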