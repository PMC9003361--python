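"""Generator correctness: MUAP shape, voluntary statistics, evoked ground truth."""

import numpy as np
import pandas as pd
import pytest

import flexemg as fx
from flexemg.preprocess import bandpass_filter, notch_filter
from flexemg.synthetic import ParameterError, true_auc


class TestMuapWaveform:
    def test_peak_location_and_value(self):
        """The analytic extremum of t*exp(-t^2) sits at tau/sqrt(2)."""
        tau, fs = 0.003, 10000.0
        w = fx.muap_waveform(fx.MuapShape(tau=tau, amplitude=1.0), fs)
        t_peak = np.argmax(w) / fs
        assert abs(t_peak - tau / np.sqrt(2)) <= 1.0 / fs
        expected_peak = np.exp(-0.5) / np.sqrt(2)
        assert w.max() == pytest.approx(expected_peak, abs=5e-4)
        # support and decay
        assert w[0] == 0.0
        assert abs(w[-1]) < 0.02 * w.max()

    def test_zero_amplitude_and_linearity(self):
        w0 = fx.muap_waveform(fx.MuapShape(tau=0.003, amplitude=0.0), 2000)
        assert np.all(w0 == 0.0)
        w1 = fx.muap_waveform(fx.MuapShape(tau=0.003, amplitude=1.0), 2000)
        w2 = fx.muap_waveform(fx.MuapShape(tau=0.003, amplitude=2.0), 2000)
        np.testing.assert_allclose(w2, 2.0 * w1, rtol=0, atol=0)

    @pytest.mark.parametrize("tau,fs", [(-1e-3, 2000), (0.0, 2000), (3e-3, 500)])
    def test_invalid_parameters(self, tau, fs):
        with pytest.raises(ParameterError):
            fx.muap_waveform(fx.MuapShape(tau=tau, amplitude=1.0), fs)


class TestVoluntaryEmg:
    def test_mu_count_zero_disallowed(self):
        with pytest.raises(ParameterError):
            fx.default_condition("healthy", mu_count=0)

    def test_determinism(self):
        cond = fx.default_condition("healthy")
        a = fx.simulate_voluntary_emg(cond, 2.0, 2000, seed=5)
        b = fx.simulate_voluntary_emg(cond, 2.0, 2000, seed=5)
        np.testing.assert_array_equal(a.data, b.data)

    def test_powerline_dominates_quiet_muscle(self):
        """With no firing and no noise the PSD is a single 50 Hz line."""
        cond = fx.default_condition(
            "healthy", mu_count=1, firing_rate=1e-3, noise_sd=0.0,
            powerline_amp=0.5,
        )
        rec = fx.simulate_voluntary_emg(cond, 4.0, 2000, seed=1)
        from scipy.signal import periodogram

        f, p = periodogram(rec.data[:, 0], fs=2000)
        assert abs(f[np.argmax(p)] - 50.0) < 1.0

    def test_noiseless_signal_linear_in_amplitude_scale(self):
        base = fx.default_condition("healthy", noise_sd=0.0, powerline_amp=0.0)
        scaled = fx.default_condition(
            "healthy", noise_sd=0.0, powerline_amp=0.0, amplitude_scale=3.0
        )
        a = fx.simulate_voluntary_emg(base, 2.0, 2000, seed=7)
        b = fx.simulate_voluntary_emg(scaled, 2.0, 2000, seed=7)
        # rounding inside the FFT convolution leaves ~1e-16 absolute residue
        np.testing.assert_allclose(b.data, 3.0 * a.data, rtol=1e-9, atol=1e-12)

    def test_rms_ordering_with_overlap(self):
        """Post-filter window RMS: nerve < immobilization, distributions overlap."""
        from flexemg.features import WindowingConfig, segment_windows

        def window_rms(label, seed):
            rec = fx.simulate_voluntary_emg(
                fx.default_condition(label), 46.0, 2000, seed=seed
            )
            x = bandpass_filter(notch_filter(rec.data[:, 0], 2000), 2000)
            w, _ = segment_windows(
                x, 2000, WindowingConfig(stable_segment=(1.0, 45.0))
            )
            return np.sqrt(np.mean(w**2, axis=1))

        rms_nerve = window_rms("nerve_injury", 11)
        rms_immob = window_rms("immobilization", 12)
        assert len(rms_nerve) == 100 and len(rms_immob) == 100
        gap = rms_immob.mean() - rms_nerve.mean()
        assert gap > 0
        assert rms_nerve.std() > 0.25 * gap
        assert rms_immob.std() > 0.25 * gap

    def test_spectral_sanity_in_band(self):
        """>= 90 % of post-band-pass power lies inside 20-500 Hz."""
        from scipy.signal import periodogram

        rec = fx.simulate_voluntary_emg(fx.default_condition("healthy"), 10.0, 2000, seed=3)
        x = bandpass_filter(notch_filter(rec.data[:, 0], 2000), 2000)
        f, p = periodogram(x, fs=2000)
        in_band = (f >= 20) & (f <= 500)
        assert p[in_band].sum() / p.sum() >= 0.90


class TestEvokedTrain:
    def test_stimulus_count(self):
        rec, truth = fx.simulate_evoked_train(
            fx.default_condition("healthy"), fx.StimulusConfig(), 10000, seed=1
        )
        assert len(truth) == 60  # 2 Hz x 30 s
        assert rec.duration == pytest.approx(30.0)

    def test_ground_truth_matches_noiseless_synthesis(self):
        """The extractor recovers the recorded ground truth on a clean epoch."""
        ep = fx.synthesize_epoch(1000, 10000, 5.0, 8.0, 8.0)
        p = fx.extract_evoked_parameters(ep, 10000)
        assert p.latency_ms == pytest.approx(5.0, abs=0.1)
        assert p.amplitude_mv == pytest.approx(8.0, rel=0.01)
        assert true_auc(8.0, 8.0) == pytest.approx(8.0 * 8.0 / np.pi)

    def test_group_ordering_over_epochs(self):
        """Mean true amplitude/duration/AUC smaller, latency larger for nerve injury."""
        stim = fx.StimulusConfig()
        _, t_nerve = fx.simulate_evoked_train(
            fx.default_condition("nerve_injury"), stim, 10000, seed=21
        )
        _, t_immob = fx.simulate_evoked_train(
            fx.default_condition("immobilization"), stim, 10000, seed=22
        )
        assert len(t_nerve) >= 50 and len(t_immob) >= 50
        assert t_nerve["amplitude_mv"].mean() < t_immob["amplitude_mv"].mean()
        assert t_nerve["duration_ms"].mean() < t_immob["duration_ms"].mean()
        assert t_nerve["auc_mvms"].mean() < t_immob["auc_mvms"].mean()
        assert t_nerve["latency_ms"].mean() > t_immob["latency_ms"].mean()

    def test_nerve_vs_healthy_ratios(self):
        stim = fx.StimulusConfig()
        _, t_nerve = fx.simulate_evoked_train(
            fx.default_condition("nerve_injury"), stim, 10000, seed=31
        )
        _, t_healthy = fx.simulate_evoked_train(
            fx.default_condition("healthy"), stim, 10000, seed=32
        )
        assert t_nerve["amplitude_mv"].mean() / t_healthy["amplitude_mv"].mean() < 1.0
        assert t_nerve["latency_ms"].mean() / t_healthy["latency_ms"].mean() > 1.0

    def test_artifact_overlapping_response_rejected(self):
        with pytest.raises(ParameterError):
            fx.synthesize_epoch(1000, 10000, 0.8, 5.0, 8.0, artifact_width=1e-3)


class TestRatCohort:
    def test_small_cohort_accounting_and_determinism(self):
        config = fx.default_rat_config(
            groups=(("immobilization", 1), ("nerve_injury", 1)),
            acquisitions_per_subject=2,
            baseline_epochs=2,
        )
        cohort = fx.generate_rat_cohort(config, seed=7)
        assert len(cohort.labels) == 4
        assert (cohort.labels["label"] == 1).sum() == 2
        assert (cohort.labels["label"] == 0).sum() == 2
        again = fx.generate_rat_cohort(config, seed=7)
        pd.testing.assert_frame_equal(cohort.labels, again.labels)
        assert cohort.labels.to_csv() == again.labels.to_csv()
        np.testing.assert_array_equal(
            cohort.acquisitions[0].record.data, again.acquisitions[0].record.data
        )

    def test_wrong_group_label_rejected(self):
        with pytest.raises(ParameterError):
            fx.default_rat_config(groups=(("healthy", 6), ("nerve_injury", 6)))


class TestPatientCohort:
    def test_default_template_accounting(self):
        config = fx.default_patient_config(record_duration=2.0)
        # record_duration > 1 s keeps generation cheap for the shape check
        cohort = fx.generate_patient_cohort(config, seed=3)
        assert len(cohort.records) == 10
        assert (cohort.labels["label"] == 1).sum() == 7
        assert (cohort.labels["label"] == 0).sum() == 3
        rec = cohort.records[0]
        assert rec.n_channels == 4
        assert rec.n_samples == int(2.0 * config.sampling_rate)

    def test_sample_count_at_default_duration(self):
        cfg = fx.default_patient_config()
        assert int(cfg.record_duration * cfg.sampling_rate) == 120000

    def test_channel_count_enforced(self):
        with pytest.raises(ParameterError):
            fx.default_patient_config(channels=("emg",))
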