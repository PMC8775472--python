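"""Preprocessing chain: resampling, zero-phase band-pass, channel repair,
ICA ocular-artifact removal and epoching."""

import numpy as np
import pytest
from scipy import signal as sps

from somnostage import (EEGRecording, bandpass, epoch_record, preprocess,
                        remove_eog_artifacts, repair_channel, resample)
from somnostage.exceptions import (ConfigurationError, DataError,
                                   UnsupportedOperationError)


def _rec(data, channels, rate):
    return EEGRecording(data=np.atleast_2d(data), channels=channels, rate=rate)


def _dominant_freq(x, rate):
    f, p = sps.periodogram(x, fs=rate)
    return f[np.argmax(p)]


class TestResample:
    def test_downsample_length(self):
        rec = _rec(np.zeros(12000), ["C3"], 200.0)
        out = resample(rec, 100.0)
        assert out.n_samples == 6000 and out.rate == 100.0

    def test_identity_at_target_rate(self):
        rec = _rec(np.arange(100.0), ["C3"], 100.0)
        out = resample(rec, 100.0)
        assert np.array_equal(out.data, rec.data)

    def test_sine_frequency_preserved(self):
        t = np.arange(30 * 500) / 500.0
        rec = _rec(np.sin(2 * np.pi * 10 * t), ["C3"], 500.0)
        out = resample(rec, 100.0)
        assert abs(out.duration_s - rec.duration_s) <= 1.0 / 100.0
        assert _dominant_freq(out.data[0], 100.0) == pytest.approx(10.0, abs=0.1)

    def test_upsampling_rejected(self):
        with pytest.raises(UnsupportedOperationError):
            resample(_rec(np.zeros(100), ["C3"], 50.0), 100.0)


class TestBandpass:
    def _attenuation_db(self, freq, rate=100.0, seconds=120):
        t = np.arange(int(seconds * rate)) / rate
        rec = _rec(np.sin(2 * np.pi * freq * t), ["C3"], rate)
        out = bandpass(rec)[0] if False else bandpass(rec)
        x = out.data[0][int(10 * rate):-int(10 * rate)]  # drop edges
        ref = np.sqrt(0.5)  # rms of unit sine
        return 20 * np.log10(np.sqrt(np.mean(x ** 2)) / ref)

    def test_passband_flat_at_10hz(self):
        assert abs(self._attenuation_db(10.0)) < 1.0

    def test_stopband_low_edge(self):
        assert self._attenuation_db(0.1, seconds=300) < -20.0

    def test_stopband_high_edge(self):
        assert self._attenuation_db(49.0) < -20.0

    def test_zero_in_zero_out(self):
        out = bandpass(_rec(np.zeros(5000), ["C3"], 100.0))
        assert np.allclose(out.data, 0.0)

    def test_edge_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            bandpass(_rec(np.zeros(5000), ["C3"], 100.0), 0.5, 60.0)


class TestRepair:
    def test_uniform_mean_of_two_neighbors(self):
        data = np.vstack([np.zeros(100), np.full(100, 2.0), np.full(100, 4.0)])
        rec = _rec(data, ["X", "Y", "Z"], 100.0)  # no known positions
        out = repair_channel(rec, "X", adjacency={"X": ["Y", "Z"]})
        assert np.allclose(out.channel("X"), 3.0)
        assert np.array_equal(out.channel("Y"), rec.channel("Y"))

    def test_single_neighbor_copies(self):
        data = np.vstack([np.zeros(10), np.arange(10.0)])
        rec = _rec(data, ["Pz", "Cz"], 100.0)
        out = repair_channel(rec, "Pz", adjacency={"Pz": ["Cz"]})
        assert np.array_equal(out.channel("Pz"), rec.channel("Cz"))

    def test_explicit_weights(self):
        data = np.vstack([np.zeros(10), np.full(10, 4.0), np.zeros(10)])
        rec = _rec(data, ["A", "B", "C"], 100.0)
        out = repair_channel(rec, "A", adjacency={"A": ["B", "C"]},
                             weights={"B": 0.75, "C": 0.25})
        assert np.allclose(out.channel("A"), 3.0)

    def test_no_neighbors_is_error(self):
        rec = _rec(np.zeros((2, 10)), ["A", "B"], 100.0)
        with pytest.raises(DataError):
            repair_channel(rec, "A", adjacency={"A": ["missing"]})


class TestEOGRemoval:
    def _mixture(self, seed=0, eog_gain=8.0):
        rng = np.random.default_rng(seed)
        n = 6000
        sos = sps.butter(4, [1, 30], btype="bandpass", fs=100, output="sos")
        neural = sps.sosfiltfilt(sos, rng.standard_normal((3, n)), axis=1)
        eog_src = sps.sosfiltfilt(
            sps.butter(4, 3, btype="lowpass", fs=100, output="sos"),
            rng.standard_normal(n))
        eog_src /= eog_src.std()
        A = rng.uniform(0.5, 1.5, size=(4, 3))
        eeg = A @ neural + eog_gain * np.outer(rng.uniform(0.8, 1.2, 4),
                                               eog_src)
        data = np.vstack([eeg, eog_src])
        return _rec(data, ["C3", "C4", "Pz", "Oz", "EOG1"], 100.0)

    def test_removes_ocular_component(self):
        rec = self._mixture()
        out = remove_eog_artifacts(rec, threshold=0.8, seed=1)
        eog = rec.channel("EOG1")
        before = max(abs(np.corrcoef(rec.channel(c), eog)[0, 1])
                     for c in ("C3", "C4", "Pz", "Oz"))
        after = max(abs(np.corrcoef(out.channel(c), eog)[0, 1])
                    for c in ("C3", "C4", "Pz", "Oz"))
        assert before > 0.9 and after < 0.8

    def test_variance_never_increases(self):
        rec = self._mixture(seed=3)
        out = remove_eog_artifacts(rec, threshold=0.8, seed=1)
        v_in = rec.data.var(axis=1)
        v_out = out.data.var(axis=1)
        assert np.all(v_out <= v_in * (1 + 1e-8))

    def test_clean_record_untouched(self):
        rec = self._mixture(eog_gain=0.0)
        out = remove_eog_artifacts(rec, threshold=0.8, seed=1)
        assert np.array_equal(out.data, rec.data)

    def test_idempotent(self):
        rec = self._mixture(seed=5)
        once = remove_eog_artifacts(rec, threshold=0.8, seed=1)
        twice = remove_eog_artifacts(once, threshold=0.8, seed=1)
        scale = np.abs(once.data).max()
        assert np.allclose(twice.data, once.data, atol=0.05 * scale)

    def test_needs_eeg_and_eog(self):
        rec = _rec(np.random.default_rng(0).standard_normal((2, 500)),
                   ["C3", "C4"], 100.0)
        with pytest.raises(DataError):
            remove_eog_artifacts(rec)


class TestEpoching:
    def test_nine_hour_night(self):
        rec = _rec(np.zeros(9 * 3600 * 100), ["Pz-Oz"], 100.0)
        epochs = epoch_record(rec, "Pz-Oz")
        assert epochs.shape == (1080, 3000)

    def test_trailing_partial_dropped(self):
        rec = _rec(np.zeros(6100), ["C3"], 100.0)  # 61 s
        assert epoch_record(rec, "C3").shape[0] == 2

    def test_partition_property(self):
        x = np.random.default_rng(0).standard_normal(9000)
        rec = _rec(x, ["C3"], 100.0)
        epochs = epoch_record(rec, "C3")
        assert np.array_equal(np.concatenate(epochs[:3]), x[:9000])

    def test_too_short_record(self):
        with pytest.raises(DataError):
            epoch_record(_rec(np.zeros(100), ["C3"], 100.0), "C3")


def test_pipeline_order_recorded():
    rng = np.random.default_rng(0)
    rec = _rec(rng.standard_normal((2, 200 * 60)), ["Pz-Oz", "Cz"], 200.0)
    out = preprocess(rec, target_rate=100.0)
    assert out.meta["preprocessing"] == ["resample:100Hz", "bandpass:0.5-40Hz"]
    assert out.rate == 100.0 and out.n_channels == 2
    assert np.isfinite(out.data).all()
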