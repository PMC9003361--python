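"""Feature extraction vs. closed forms and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flexemg as fx
from flexemg.features import (
    FEATURE_COLUMNS,
    SilentWindowError,
    WindowingConfig,
    feature_vector,
)


def enumeration_count(length, window, step):
    """Independent window-count oracle: enumerate starts one by one."""
    count, k = 0, 0
    while k * step + window <= length + 1e-9:
        count += 1
        k += 1
    return count


class TestWindowing:
    @pytest.mark.parametrize(
        "length,expected", [(30.0, 68), (40.0, 91), (0.5, 1), (7.3, 16)]
    )
    def test_counts_match_enumeration_oracle(self, length, expected):
        cfg = WindowingConfig()
        starts = fx.window_starts(length, cfg)
        assert len(starts) == enumeration_count(length, 0.5, 0.4375)
        assert len(starts) == expected

    def test_step_value(self):
        assert WindowingConfig().step == pytest.approx(0.4375)
        assert WindowingConfig(step_is_overlap=True).step == pytest.approx(0.0625)

    def test_random_lengths_match_oracle(self):
        rng = np.random.default_rng(0)
        cfg = WindowingConfig()
        for _ in range(50):
            length = rng.uniform(0.5, 80.0)
            assert len(fx.window_starts(length, cfg)) == enumeration_count(
                length, cfg.window_length, cfg.step
            )

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            fx.window_starts(0.3, WindowingConfig())

    def test_segment_windows_shapes(self):
        fs = 2000.0
        x = np.arange(int(31 * fs), dtype=float)
        w, starts = fx.segment_windows(x, fs, WindowingConfig(stable_segment=(0.5, 30.5)))
        assert w.shape == (68, 1000)
        assert starts[0] == pytest.approx(0.5)


class TestTimeDomain:
    def test_constant_window(self):
        rms, iemg, arv = fx.time_domain_features(np.full(1000, -3.0), 2000.0)
        assert rms == pytest.approx(3.0)
        assert arv == pytest.approx(3.0)
        assert iemg == pytest.approx(3.0 * 0.5)  # |c| x window length

    def test_unit_sine_closed_forms(self):
        fs = 20000.0  # fine sampling keeps the discrete mean near 2/pi
        t = np.arange(int(fs)) / fs  # 1 s, integer cycles of 100 Hz
        x = np.sin(2 * np.pi * 100 * t)
        rms, iemg, arv = fx.time_domain_features(x, fs)
        assert rms == pytest.approx(1 / np.sqrt(2), abs=1e-3)
        assert arv == pytest.approx(2 / np.pi, abs=1e-3)
        assert iemg == pytest.approx(2 / np.pi * 1.0, abs=1e-3)

    def test_two_sample_window(self):
        rms, iemg, arv = fx.time_domain_features(np.array([3.0, -4.0]), 2.0)
        assert rms == pytest.approx(math.sqrt(12.5))
        assert arv == pytest.approx(3.5)
        assert iemg == pytest.approx(3.5)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            fx.time_domain_features(np.array([]), 2000.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False),
            min_size=16,
            max_size=16,
        )
    )
    def test_bruteforce_oracle_equivalence(self, values):
        """Definitions re-computed longhand agree to 1e-12 relative."""
        fs = 2000.0
        x = np.asarray(values)
        rms, iemg, arv = fx.time_domain_features(x, fs)
        brute_rms = math.sqrt(math.fsum(v * v for v in values) / len(values))
        brute_arv = math.fsum(abs(v) for v in values) / len(values)
        brute_iemg = math.fsum(abs(v) for v in values) / fs
        assert rms == pytest.approx(brute_rms, rel=1e-12, abs=1e-12)
        assert arv == pytest.approx(brute_arv, rel=1e-12, abs=1e-12)
        assert iemg == pytest.approx(brute_iemg, rel=1e-12, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=16,
            max_size=16,
        )
    )
    def test_rms_dominates_arv(self, values):
        rms, _, arv = fx.time_domain_features(np.asarray(values), 2000.0)
        assert rms >= arv - 1e-12


class TestSpectral:
    FS = 2000.0

    def window(self, *freqs, n=1000):
        t = np.arange(n) / self.FS
        return sum(np.sin(2 * np.pi * f * t) for f in freqs)

    def test_pure_tone(self):
        mdf, mpf = fx.spectral_features(self.window(100.0), self.FS)
        bin_w = self.FS / 1024
        assert abs(mdf - 100.0) <= 2 * bin_w
        assert abs(mpf - 100.0) <= 2 * bin_w

    def test_two_equal_tones(self):
        mdf, mpf = fx.spectral_features(self.window(100.0, 200.0), self.FS)
        assert abs(mpf - 150.0) <= 2 * self.FS / 1024
        assert 100.0 <= mdf <= 200.0

    def test_flat_noise_midpoint(self):
        """Noise with an exactly flat 20-500 Hz spectrum: MDF, MPF near 260 Hz."""
        rng = np.random.default_rng(5)
        n = int(30 * self.FS)
        freqs = np.fft.rfftfreq(n, 1 / self.FS)
        spectrum = np.where(
            (freqs >= 20) & (freqs <= 500),
            np.exp(2j * np.pi * rng.random(len(freqs))),
            0.0,
        )
        x = np.fft.irfft(spectrum, n)
        w, _ = fx.segment_windows(x, self.FS, WindowingConfig(stable_segment=(2.0, 27.0)))
        mdfs, mpfs = [], []
        for row in w[:50]:
            mdf, mpf = fx.spectral_features(row, self.FS)
            mdfs.append(mdf)
            mpfs.append(mpf)
        assert np.mean(mdfs) == pytest.approx(260.0, abs=10.0)
        assert np.mean(mpfs) == pytest.approx(260.0, abs=10.0)

    def test_silent_window_rejected(self):
        with pytest.raises(SilentWindowError):
            fx.spectral_features(np.zeros(1000), self.FS)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            fx.spectral_features(np.ones(32), self.FS)

    def test_amplitude_equivariance(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(1000)
        f1 = feature_vector(x, self.FS)
        f2 = feature_vector(2.5 * x, self.FS)
        for k in ("rms", "iemg", "arv"):
            assert f2[k] == pytest.approx(2.5 * f1[k], rel=1e-9)
        for k in ("mdf", "mpf"):
            assert f2[k] == pytest.approx(f1[k], rel=1e-9)


class TestFeatureTable:
    def make_record(self, n_channels=4, duration=31.0, fs=2000.0, seed=0):
        rng = np.random.default_rng(seed)
        roles = fx.CANONICAL_ROLES[:n_channels]
        data = rng.standard_normal((int(duration * fs), n_channels))
        return fx.SignalRecord(data, fs, roles, meta={"subject": "s1", "label": "1"})

    def test_row_count_four_channels(self):
        rec = self.make_record()
        table = fx.build_feature_table(
            rec, WindowingConfig(stable_segment=(0.5, 30.5))
        )
        assert len(table) == 4 * 68
        # deterministic ordering: channel role blocks, window index within
        first = table.iloc[:68]
        assert (first["channel_role"] == rec.channel_roles[0]).all()
        assert list(first["window_idx"]) == list(range(68))

    def test_single_window_single_channel(self):
        rng = np.random.default_rng(1)
        rec = fx.SignalRecord(rng.standard_normal(1000), 2000.0, ("emg",))
        table = fx.build_feature_table(rec, WindowingConfig())
        assert len(table) == 1
        assert set(FEATURE_COLUMNS) <= set(table.columns)

    def test_determinism(self):
        rec = self.make_record()
        cfg = WindowingConfig(stable_segment=(0.5, 30.5))
        pd.testing.assert_frame_equal(
            fx.build_feature_table(rec, cfg), fx.build_feature_table(rec, cfg)
        )


class TestRatioNormalize:
    def small_table(self, scale=1.0):
        rows = []
        for role in ("tibialis_affected", "gastrocnemius_affected"):
            for i in range(3):
                rows.append(
                    dict(
                        subject="s1", channel_role=role, window_idx=i,
                        rms=scale * (1 + i), iemg=2.0, arv=0.5, mdf=100.0,
                        mpf=120.0, label="1", normalized="raw",
                    )
                )
        return pd.DataFrame(rows)

    def test_identity_reference_gives_unit_ratios(self):
        t = self.small_table()
        out = fx.ratio_normalize(t, t)
        assert np.allclose(out["iemg"], 1.0)
        assert np.allclose(out["mdf"], 1.0)
        assert (out["normalized"] == "ratio").all()
        # rms has within-table spread; its mean ratio is 1
        assert out["rms"].mean() == pytest.approx(1.0)

    def test_doubled_column_doubles_only_that_ratio(self):
        ref = self.small_table()
        aff = ref.copy()
        aff["rms"] = 2.0 * aff["rms"]
        out = fx.ratio_normalize(aff, ref)
        base = fx.ratio_normalize(ref, ref)
        assert np.allclose(out["rms"], 2.0 * base["rms"])
        assert np.allclose(out["mdf"], base["mdf"])

    def test_near_zero_reference_rejected(self):
        ref = self.small_table()
        ref["mpf"] = 0.0
        with pytest.raises(ValueError, match="mpf"):
            fx.ratio_normalize(self.small_table(), ref)

    def test_contralateral_pairing(self):
        aff = self.small_table()
        ref = self.small_table(scale=2.0)
        ref["channel_role"] = ref["channel_role"].str.replace(
            "_affected", "_unaffected"
        )
        out = fx.ratio_normalize(
            aff, ref, pairing=fx.features.PATIENT_PAIRING
        )
        assert out["iemg"].iloc[0] == pytest.approx(1.0)
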