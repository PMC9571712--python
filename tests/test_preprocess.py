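"""Filtering, resampling, mBLL and segmentation contracts."""

import numpy as np
import pytest
from scipy import signal as sps

from neurofuse.preprocess import (
    DEFAULT_EXTINCTION,
    baseline_correct,
    butter_filter,
    butter_sos,
    filter_array,
    mbll,
    resample,
    sliding_segments,
)

from conftest import make_events, make_recording


class TestButterFilter:
    def test_dc_removed_by_bandpass(self):
        rec = make_recording(np.ones((2, 2000)))
        out = butter_filter(rec, "bandpass", (1.0, 45.0), order=3)
        steady = out.data[:, 200:-200]  # past the edge transient
        assert np.abs(steady).max() < 0.01

    def test_inband_sine_preserved(self):
        t = np.arange(0, 10, 1 / 200)
        rec = make_recording(np.sin(2 * np.pi * 10 * t))
        out = butter_filter(rec, "bandpass", (1.0, 45.0), order=3)
        steady = out.data[0, 400:-400]
        assert np.abs(steady).max() == pytest.approx(1.0, rel=0.05)

    def test_single_pass_half_power_at_cutoff(self):
        # |H(fc)| = 2^(-1/2) for a Butterworth design, any order
        sos = butter_sos("lowpass", 20.0, 3, 200.0)
        _, h = sps.sosfreqz(sos, worN=[20.0], fs=200.0)
        assert np.abs(h[0]) == pytest.approx(2 ** -0.5, abs=0.01)

    def test_time_reversal_symmetry(self, rng):
        x = rng.standard_normal(2000)
        a = filter_array(x, "bandpass", (1.0, 45.0), 3, 200.0)
        b = filter_array(x[::-1], "bandpass", (1.0, 45.0), 3, 200.0)[::-1]
        assert np.abs(a - b).max() < 1e-8

    def test_inband_idempotence(self):
        t = np.arange(0, 10, 1 / 200)
        x = np.sin(2 * np.pi * 10 * t)
        once = filter_array(x, "bandpass", (1.0, 45.0), 3, 200.0)
        twice = filter_array(once, "bandpass", (1.0, 45.0), 3, 200.0)
        mid = slice(400, -400)
        assert (np.abs(twice[mid]).max()
                == pytest.approx(np.abs(once[mid]).max(), rel=0.10))

    def test_invalid_edges_and_order(self):
        rec = make_recording(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            butter_filter(rec, "bandpass", (1.0, 150.0), order=3)
        with pytest.raises(ValueError):
            butter_filter(rec, "lowpass", 10.0, order=0)


class TestResample:
    def test_identity(self):
        rec = make_recording(np.arange(100.0))
        out = resample(rec, 200.0)
        assert out.rate == 200.0 and np.array_equal(out.data, rec.data)

    def test_sample_count(self):
        rec = make_recording(np.zeros(2000), rate=200.0)  # 10 s
        out = resample(rec, 50.0)
        assert out.n_samples == round(10 * 50.0)

    def test_downsampled_sine_matches_analytic(self):
        t_in = np.arange(0, 4, 1 / 1000)
        rec = make_recording(np.sin(2 * np.pi * 5 * t_in), rate=1000.0)
        out = resample(rec, 200.0)
        t_out = np.arange(out.n_samples) / 200.0
        ref = np.sin(2 * np.pi * 5 * t_out)
        r = np.corrcoef(out.data[0, 50:-50], ref[50:-50])[0, 1]
        assert r > 0.999

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            resample(make_recording(np.zeros(10)), -1.0)


class TestMBLL:
    def _od(self, data):
        return make_recording(data, rate=10.0, modality="od")

    def test_zero_od_gives_zero_concentration(self):
        hbo, hbr = mbll(self._od(np.zeros((3, 50))), self._od(np.zeros((3, 50))))
        assert np.all(hbo.data == 0) and np.all(hbr.data == 0)

    def test_round_trip_recovery(self, rng):
        hbo_true = rng.standard_normal((4, 200))
        hbr_true = rng.standard_normal((4, 200))
        d, dpf = 3.0, (6.0, 6.0)
        A = DEFAULT_EXTINCTION * (d * np.asarray(dpf)[:, None])
        od = np.einsum("ij,jcn->icn", A, np.stack([hbo_true, hbr_true]))
        hbo, hbr = mbll(self._od(od[0]), self._od(od[1]), distance_cm=d, dpf=dpf)
        assert np.allclose(hbo.data, hbo_true, rtol=1e-10, atol=1e-12)
        assert np.allclose(hbr.data, hbr_true, rtol=1e-10, atol=1e-12)

    def test_matches_adjugate_formula(self, rng):
        od1 = rng.standard_normal((2, 30))
        od2 = rng.standard_normal((2, 30))
        d, dpf = 2.5, (5.5, 6.5)
        hbo, hbr = mbll(self._od(od1), self._od(od2), distance_cm=d, dpf=dpf)
        A = DEFAULT_EXTINCTION * (d * np.asarray(dpf)[:, None])
        det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
        hbo_ref = (A[1, 1] * od1 - A[0, 1] * od2) / det
        hbr_ref = (-A[1, 0] * od1 + A[0, 0] * od2) / det
        assert np.allclose(hbo.data, hbo_ref, atol=1e-12)
        assert np.allclose(hbr.data, hbr_ref, atol=1e-12)

    def test_singular_extinction_rejected(self):
        with pytest.raises(ValueError):
            mbll(self._od(np.zeros((1, 5))), self._od(np.zeros((1, 5))),
                 extinction=np.ones((2, 2)))


class TestBaselineAndSegments:
    def _rec_with_events(self, data, onsets, duration=10.0):
        rec = make_recording(data, rate=10.0, modality="hbo")
        return rec, make_events(onsets, ["0-back"] * len(onsets), duration)

    def test_constant_signal_baselines_to_zero(self):
        rec, ev = self._rec_with_events(np.full((2, 300), 3.7), [10.0])
        seg = sliding_segments(rec, ev, 5.0, baseline_interval=(-5.0, 0.0))[0]
        assert np.all(seg.data == 0)

    def test_median_robust_to_baseline_outlier(self):
        data = np.zeros((1, 200))
        data[0, 97:100] = [1.0, 1.0, 100.0]  # 3-sample baseline window
        rec = make_recording(data, rate=1.0, modality="hbo")
        ev = make_events([100.0], ["0-back"], duration=20.0)
        seg = sliding_segments(rec, ev, 5.0)[0]
        corrected = baseline_correct(seg, (-3.0, 0.0))
        assert np.all(corrected.data == -1.0)  # median(1, 1, 100) = 1

    def test_zero_median_baseline_is_noop(self, rng):
        data = rng.standard_normal((2, 300))
        med = np.median(data[:, 50:100], axis=1, keepdims=True)
        rec = make_recording(data - med, rate=10.0, modality="hbo")
        ev = make_events([10.0], ["0-back"], duration=10.0)
        raw = sliding_segments(rec, ev, 5.0)[0]
        corrected = sliding_segments(rec, ev, 5.0,
                                     baseline_interval=(-5.0, 0.0))[0]
        assert np.allclose(corrected.data, raw.data)

    def test_empty_baseline_rejected(self):
        rec, ev = self._rec_with_events(np.zeros((1, 300)), [10.0])
        seg = sliding_segments(rec, ev, 5.0)[0]
        with pytest.raises(ValueError):
            baseline_correct(seg, (0.0, 0.0))

    def test_window_counts(self):
        rec = make_recording(np.zeros((1, 200 * 63)), rate=200.0)
        ev = make_events([2.0], ["0-back"], duration=40.0)
        assert len(sliding_segments(rec, ev, 5.0, 1.0, (0.0, 35.0))) == 36
        assert len(sliding_segments(rec, ev, 40.0, 1.0, (0.0, 0.0))) == 1

    def test_one_window_per_task_gives_one_segment_each(self, tiny_config):
        from neurofuse.simulate import generate_session

        eeg, _, _, ev = generate_session(tiny_config, 0, 0)
        segs = sliding_segments(eeg, ev, 5.0, 1.0, (0.0, 0.0))
        assert len(segs) == len(ev)

    def test_overrunning_window_skipped_with_warning(self, caplog):
        rec = make_recording(np.zeros((1, 100)), rate=10.0)
        ev = make_events([2.0], ["0-back"], duration=5.0)
        with caplog.at_level("WARNING"):
            segs = sliding_segments(rec, ev, 5.0, 1.0, (0.0, 10.0))
        assert len(segs) < 11 and "skipped" in caplog.text

    def test_segment_data_equals_recording_slice(self, rng):
        data = rng.standard_normal((3, 400))
        rec = make_recording(data, rate=10.0)
        ev = make_events([5.0, 20.0], ["0-back", "2-back"], duration=10.0)
        for seg in sliding_segments(rec, ev, 4.0, 2.0, (0.0, 6.0)):
            i0 = round((seg.task_onset + seg.start) * 10.0)
            assert np.array_equal(seg.data, data[:, i0:i0 + 40])
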