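"""Estimator limiting cases, independent oracles and range invariants."""

import numpy as np
import pytest
from scipy import signal as sps

from neurofuse.datatypes import BANDS, FeatureDescriptor, Segment
from neurofuse.features import (
    assemble,
    band_power,
    connectivity_matrix,
    default_bins,
    fnirs_window_feature,
    mi_entropy_terms,
    msc,
    mutual_information,
    pcc,
    plv,
    window_id,
)
from neurofuse.preprocess import filter_array
from neurofuse.simulate import hrf

RATE = 200.0
ALPHA, DELTA, THETA = BANDS["alpha"], BANDS["delta"], BANDS["theta"]


def brute_force_mi(x, y, n_bins, base=2.0):
    """Independent oracle: sum over joint-histogram cells of p log p/(px py)."""
    counts, _, _ = np.histogram2d(x, y, bins=n_bins)
    p = counts / counts.sum()
    px, py = p.sum(axis=1), p.sum(axis=0)
    total = 0.0
    for i in range(n_bins):
        for j in range(n_bins):
            if p[i, j] > 0:
                total += p[i, j] * np.log(p[i, j] / (px[i] * py[j]))
    return total / np.log(base)


def make_segment(data, rate=RATE):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return Segment(data, rate, [f"ch{i}" for i in range(data.shape[0])],
                   0.0, data.shape[1] / rate, "0-back", 0, 0, 0)


class TestBandPower:
    def test_zero_signal_zero_power(self):
        for band in BANDS.values():
            assert band_power(np.zeros(2000), RATE, band)[0] == 0.0

    def test_pure_alpha_tone_concentrates_in_alpha(self):
        t = np.arange(0, 10, 1 / RATE)
        x = np.sin(2 * np.pi * 10 * t)
        ratio = band_power(x, RATE, ALPHA)[0] / band_power(x, RATE, DELTA)[0]
        assert ratio > 100

    def test_parseval_total_power(self, rng):
        x = rng.standard_normal(4000)
        from neurofuse.datatypes import BandSpec
        wide = BandSpec("wide", 0.5, RATE / 2 - 1e-9)
        assert band_power(x, RATE, wide)[0] == pytest.approx(x.var(), rel=0.10)

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            band_power(np.zeros(200), RATE, DELTA)  # 1 s < 2 / 0.5 Hz


class TestPCC:
    def test_limiting_cases(self, rng):
        x = rng.standard_normal(100)
        assert pcc(x, x) == pytest.approx(1.0)
        assert pcc(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pcc([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pcc([1, 1, 1], [1, 2, 3])


class TestMSC:
    def test_identical_signals_give_unity(self, rng):
        x = rng.standard_normal(4000)
        assert msc(x, x, RATE, ALPHA) == pytest.approx(1.0)

    def test_independent_noise_low_coherence(self, rng):
        x, y = rng.standard_normal(4000), rng.standard_normal(4000)
        assert msc(x, y, RATE, ALPHA, n_segments=8) < 0.3

    def test_invariant_to_pure_phase_shift(self, rng):
        x = filter_array(rng.standard_normal(4000), "bandpass",
                         (ALPHA.low, ALPHA.high), 3, RATE)
        y = np.real(sps.hilbert(x) * np.exp(1j * np.pi / 3))
        assert msc(x, y, RATE, ALPHA) > 0.95

    def test_matches_scipy_coherence(self, rng):
        x = rng.standard_normal(4000)
        y = 0.5 * x + rng.standard_normal(4000)
        n_segments = 8
        nperseg = max(int(2 * 4000 / (n_segments + 1)), 2)
        f, C = sps.coherence(x, y, fs=RATE, nperseg=nperseg,
                             noverlap=nperseg // 2)
        mask = (f >= ALPHA.low) & (f <= ALPHA.high)
        assert msc(x, y, RATE, ALPHA, n_segments) == pytest.approx(
            C[mask].mean(), abs=1e-10)

    def test_single_segment_rejected(self, rng):
        with pytest.raises(ValueError):
            msc(rng.standard_normal(100), rng.standard_normal(100),
                RATE, ALPHA, n_segments=1)


class TestMutualInformation:
    def test_identical_uniform_four_levels_is_two_bits(self):
        x = np.repeat([0.0, 1.0, 2.0, 3.0], 25)
        assert mutual_information(x, x, n_bins=4) == pytest.approx(2.0)

    def test_outer_product_joint_gives_zero(self):
        # joint histogram factorises exactly -> MI = 0
        x = np.repeat([0.0, 1.0, 2.0, 3.0], 16)
        y = np.tile([0.0, 1.0, 2.0, 3.0], 16)
        assert mutual_information(x, y, n_bins=4) == pytest.approx(0.0, abs=1e-12)

    def test_entropy_identity(self, rng):
        x = rng.standard_normal(500)
        y = 0.3 * x + rng.standard_normal(500)
        h = mi_entropy_terms(x, y)
        lhs = h["H(x)"] + h["H(y)"] - h["H(x,y)"]
        rhs = h["H(y)"] - h["H(y|x)"]
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_brute_force_oracle_on_fuzzed_inputs(self):
        worst = 0.0
        for i in range(1000):
            r = np.random.default_rng(i)
            n = int(r.integers(30, 300))
            x = r.standard_normal(n) * r.uniform(0.1, 5.0)
            y = r.uniform(-1, 1) * x + r.standard_normal(n)
            nb = default_bins(n)
            dev = abs(mutual_information(x, y) - max(brute_force_mi(x, y, nb), 0.0))
            worst = max(worst, dev)
        assert worst <= 1e-10

    def test_added_noise_never_raises_median_mi(self):
        base, noisy = [], []
        for i in range(50):
            r = np.random.default_rng(1000 + i)
            x = r.standard_normal(500)
            y = x + 0.5 * r.standard_normal(500)
            base.append(mutual_information(x, y))
            noisy.append(mutual_information(x, y + r.standard_normal(500)))
        assert np.median(noisy) <= np.median(base)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mutual_information([], [])


class TestPLV:
    def _alpha_noise(self, rng, n=4000):
        return filter_array(rng.standard_normal(n), "bandpass",
                            (ALPHA.low, ALPHA.high), 3, RATE)

    def test_identical_signals_lock(self, rng):
        x = self._alpha_noise(rng)
        assert plv(x, x, RATE) == pytest.approx(1.0)

    def test_constant_phase_offset_locks(self, rng):
        x = self._alpha_noise(rng)
        y = np.real(sps.hilbert(x) * np.exp(1j * np.pi / 4))
        assert plv(x, y, RATE) == pytest.approx(1.0, abs=0.02)

    def test_independent_noise_low_plv(self, rng):
        x, y = self._alpha_noise(rng), self._alpha_noise(rng)
        assert plv(x, y, RATE) < 0.2

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            plv(np.zeros(400), np.zeros(400), RATE, DELTA)  # 2 s < 3 / 0.5 Hz


class TestEstimatorProperties:
    @pytest.mark.parametrize("n_cases", [200])
    def test_ranges_and_symmetry_on_fuzzed_inputs(self, n_cases):
        for i in range(n_cases):
            r = np.random.default_rng(i)
            x = r.standard_normal(512) * r.uniform(0.1, 10)
            y = r.standard_normal(512) + r.uniform(-1, 1) * x
            assert -1.0 <= pcc(x, y) <= 1.0
            assert abs(pcc(x, y) - pcc(y, x)) <= 1e-10
            m = msc(x, y, RATE, ALPHA, 4)
            assert 0.0 <= m <= 1.0
            assert abs(m - msc(y, x, RATE, ALPHA, 4)) <= 1e-10
            mi = mutual_information(x, y)
            assert mi >= 0.0
            assert abs(mi - mutual_information(y, x)) <= 1e-10
            p = plv(x, y, RATE)
            assert 0.0 <= p <= 1.0
            assert abs(p - plv(y, x, RATE)) <= 1e-10


@pytest.fixture(scope="module")
def seg():
    r = np.random.default_rng(5)
    shared = r.standard_normal(2000)
    data = r.standard_normal((4, 2000)) + 0.5 * shared
    return make_segment(data)


class TestConnectivityMatrix:
    @pytest.mark.parametrize("estimator", ["pcc", "msc", "mi", "plv"])
    def test_symmetric_and_consistent_with_pairwise(self, seg, estimator):
        cm = connectivity_matrix(seg, estimator, THETA)
        assert np.array_equal(cm.values, cm.values.T)
        filt = filter_array(seg.data, "bandpass", (THETA.low, THETA.high),
                            3, RATE)
        x, y = filt[0], filt[1]
        if estimator == "pcc":
            ref = pcc(x, y)
        elif estimator == "mi":
            ref = mutual_information(x, y)
        elif estimator == "plv":
            ref = plv(x, y, RATE)  # already band-filtered
        else:
            ref = msc(seg.data[0], seg.data[1], RATE, THETA)
        assert cm.values[0, 1] == pytest.approx(ref, abs=1e-9)

    @pytest.mark.parametrize("estimator,diag", [
        ("pcc", 1.0), ("msc", 1.0), ("plv", 1.0)])
    def test_unit_diagonals(self, seg, estimator, diag):
        cm = connectivity_matrix(seg, estimator, THETA)
        assert np.allclose(np.diag(cm.values), diag)

    def test_mi_diagonal_is_marginal_entropy(self, seg):
        cm = connectivity_matrix(seg, "mi", THETA)
        filt = filter_array(seg.data, "bandpass", (THETA.low, THETA.high),
                            3, RATE)
        h = mi_entropy_terms(filt[0], filt[0])["H(x)"]
        assert cm.values[0, 0] == pytest.approx(h, abs=1e-9)

    def test_duplicated_channel_pair_saturates(self):
        r = np.random.default_rng(6)
        row = r.standard_normal(2000)
        seg = make_segment(np.vstack([row, row, r.standard_normal(2000)]))
        for est in ("pcc", "msc", "plv"):
            cm = connectivity_matrix(seg, est, THETA)
            assert cm.values[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            connectivity_matrix(make_segment(np.zeros((1, 1000))), "pcc", THETA)


class TestFnirsWindowFeature:
    def test_constant_and_mean(self):
        seg = make_segment(np.full((2, 10), 4.2), rate=10.0)
        assert np.allclose(fnirs_window_feature(seg), 4.2)
        seg = make_segment(np.array([[0.0, 1.0, 2.0, 3.0]]), rate=10.0)
        assert fnirs_window_feature(seg)[0] == pytest.approx(1.5)

    def test_peak_window_exceeds_pre_onset_window(self):
        rate = 10.0
        t = np.arange(0, 60, 1 / rate)
        box = ((t >= 20) & (t < 40)).astype(float)
        kern = hrf(np.arange(0, 30, 1 / rate), 6.0)
        resp = np.convolve(box, kern)[: t.size] / rate
        peak = make_segment(resp[None, 260:310], rate)   # around onset + 6 s
        pre = make_segment(resp[None, 150:200], rate)    # before onset
        assert fnirs_window_feature(peak)[0] > fnirs_window_feature(pre)[0]


class TestAssemble:
    def test_column_counts_for_small_configuration(self, rng):
        n_samples, chans = 4, ["a", "b", "c", "d"]
        pairs = [(x, y) for i, x in enumerate(chans) for y in chans[i + 1:]]
        bands = ["delta", "theta", "alpha"]
        psd = (rng.random((n_samples, 12)),
               [FeatureDescriptor("eeg-psd", b, (c,), "", "psd")
                for b in bands for c in chans])
        fbc = (rng.random((n_samples, 72)),
               [FeatureDescriptor("eeg-fbc", b, p, "", e)
                for b in bands for e in ("pcc", "msc", "mi", "plv")
                for p in pairs])
        win = (rng.random((n_samples, 6)),
               [FeatureDescriptor("fnirs-hbo", "", (c,), window_id(s), "mean")
                for c in ("u", "v", "w") for s in (0.0, 5.0)])
        fm = assemble([psd, fbc, win], ["0-back"] * n_samples)
        assert fm.n_features == 12 + 72 + 6

    def test_column_order_deterministic(self, rng):
        d1 = FeatureDescriptor("eeg-psd", "alpha", ("a",), "", "psd")
        d2 = FeatureDescriptor("eeg-psd", "delta", ("a",), "", "psd")
        vals = rng.random((2, 2))
        fm_fwd = assemble([(vals, [d1, d2])], ["0-back", "2-back"])
        fm_rev = assemble([(vals[:, ::-1], [d2, d1])], ["0-back", "2-back"])
        assert list(fm_fwd.descriptors) == list(fm_rev.descriptors)
        assert np.array_equal(fm_fwd.values, fm_rev.values)

    def test_duplicate_descriptors_rejected(self, rng):
        d = FeatureDescriptor("eeg-psd", "alpha", ("a",), "", "psd")
        with pytest.raises(ValueError):
            assemble([(rng.random((2, 2)), [d, d])], ["0-back", "2-back"])

    def test_ragged_blocks_rejected(self, rng):
        d1 = FeatureDescriptor("eeg-psd", "alpha", ("a",), "", "psd")
        d2 = FeatureDescriptor("eeg-psd", "delta", ("a",), "", "psd")
        with pytest.raises(ValueError):
            assemble([(rng.random((2, 1)), [d1]),
                      (rng.random((3, 1)), [d2])], ["0-back", "2-back"])
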