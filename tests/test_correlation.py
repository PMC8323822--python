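import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikeconn.correlation import (
    CorrelationFunction,
    SpikeSignal,
    all_pairwise_peaks,
    bin_spikes,
    cross_correlation,
    detect_peaks,
    smooth,
    suggest_epsilon,
    _bin_indices,
    _pearson_from_sparse,
    _sparse_raw_window,
)
from spikeconn.synthetic import SpikeTrainSet


def brute_force_raw(x, y, max_lag):
    """O(S^2) definition: R[l] = sum_t x[t] * y[t + l]."""
    S = len(x)
    out = np.zeros(2 * max_lag + 1)
    for i, lag in enumerate(range(-max_lag, max_lag + 1)):
        for t in range(S):
            if 0 <= t + lag < S:
                out[i] += x[t] * y[t + lag]
    return out


class TestBinSpikes:
    def test_isolated_spikes_land_in_their_bins(self):
        tr = SpikeTrainSet(1, [np.array([1.0, 2.0])], 3.0)
        sig = bin_spikes(tr, 1.0)[0]
        assert sig.values[1000] == 1 and sig.values[2000] == 1
        assert sig.values.sum() == 2

    def test_coincident_spikes_stack(self):
        tr = SpikeTrainSet(1, [np.array([1.0000, 1.0004])], 2.0)
        sig = bin_spikes(tr, 1.0)[0]
        assert sig.values.max() == 2

    def test_count_conservation(self, random_trains):
        sigs = bin_spikes(random_trains, 0.7)
        for sig, times in zip(sigs, random_trains.spike_times):
            assert sig.values.sum() == times.size
        assert len({s.n_samples for s in sigs}) == 1


class TestCrossCorrelation:
    def test_autocorrelation_peaks_at_zero(self):
        x = SpikeSignal(np.array([0, 1, 0, 2, 1, 0]), 1.0)
        corr = cross_correlation(x, x, "raw")
        centre = corr.values.size // 2
        assert corr.lags[centre] == 0
        assert corr.values[centre] == np.sum(x.values**2)
        assert corr.values.argmax() == centre

    def test_shift_identity(self):
        v = np.zeros(64)
        v[[5, 20, 33]] = 1
        w = np.roll(v, 5)
        corr = cross_correlation(SpikeSignal(v, 1.0), SpikeSignal(w, 1.0),
                                 "raw")
        assert corr.lags[corr.values.argmax()] == 5.0

    def test_fft_equals_brute_force(self, random_trains):
        sigs = bin_spikes(random_trains, 2.0)
        corr = cross_correlation(sigs[0], sigs[1], "raw", max_lag_ms=40)
        expect = brute_force_raw(sigs[0].values.astype(float),
                                 sigs[1].values.astype(float), 20)
        np.testing.assert_allclose(corr.values, expect, atol=1e-8)

    def test_sparse_window_equals_fft(self, random_trains):
        dt = 0.5
        sigs = bin_spikes(random_trains, dt)
        bj, cj = _bin_indices(random_trains.spike_times[0], dt)
        bk, ck = _bin_indices(random_trains.spike_times[2], dt)
        L = 30
        sparse = _sparse_raw_window(bj, cj, bk, ck, L)
        dense = cross_correlation(sigs[0], sigs[2], "raw",
                                  max_lag_ms=L * dt)
        np.testing.assert_allclose(sparse, dense.values, atol=1e-7)

    def test_sparse_pearson_equals_dense(self, random_trains):
        dt = 1.0
        sigs = bin_spikes(random_trains, dt)
        bj, cj = _bin_indices(random_trains.spike_times[1], dt)
        bk, ck = _bin_indices(random_trains.spike_times[3], dt)
        L = 25
        raw = _sparse_raw_window(bj, cj, bk, ck, L)
        sparse = _pearson_from_sparse(raw, bj, cj, bk, ck,
                                      sigs[0].n_samples, L)
        dense = cross_correlation(sigs[1], sigs[3], "pearson",
                                  max_lag_ms=L * dt)
        np.testing.assert_allclose(sparse, dense.values, atol=1e-12)

    def test_symmetry_r_jk_equals_r_kj_negated(self, random_trains):
        sigs = bin_spikes(random_trains, 1.0)
        ab = cross_correlation(sigs[0], sigs[1], "raw", max_lag_ms=30)
        ba = cross_correlation(sigs[1], sigs[0], "raw", max_lag_ms=30)
        np.testing.assert_allclose(ab.values, ba.values[::-1], atol=1e-8)

    def test_pearson_rejects_constant_signal(self):
        flat = SpikeSignal(np.zeros(32), 1.0)
        spiky = SpikeSignal(np.arange(32) % 2, 1.0)
        with pytest.raises(ValueError):
            cross_correlation(flat, spiky, "pearson")

    def test_mismatched_signals_rejected(self):
        a = SpikeSignal(np.zeros(10), 1.0)
        b = SpikeSignal(np.zeros(12), 1.0)
        with pytest.raises(ValueError):
            cross_correlation(a, b, "raw")


class TestSmooth:
    def _corr(self, values, dt=1.0):
        n = len(values)
        lags = (np.arange(n) - n // 2) * dt
        return CorrelationFunction(lags, np.asarray(values, float))

    def test_zero_sigma_is_identity(self):
        c = self._corr(np.random.default_rng(0).random(21))
        out = smooth(c, 0.0)
        np.testing.assert_array_equal(out.values, c.values)

    def test_subsample_kernel_is_identity(self):
        c = self._corr(np.random.default_rng(1).random(21), dt=1.0)
        out = smooth(c, 0.013)  # 4 sigma << one sample
        np.testing.assert_array_equal(out.values, c.values)

    def test_constant_function_unchanged(self):
        c = self._corr(np.full(31, 2.5))
        out = smooth(c, 2.0)
        np.testing.assert_allclose(out.values, 2.5, atol=1e-9)

    def test_delta_becomes_gaussian_with_preserved_mass(self):
        v = np.zeros(201)
        v[100] = 1.0
        c = self._corr(v)
        out = smooth(c, 3.0)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-6)
        # profile matches the analytic kernel truncated at 4 sigma
        x = c.lags
        expect = np.where(np.abs(x) <= 12.0, np.exp(-0.5 * (x / 3.0) ** 2),
                          0.0)
        expect /= expect.sum()
        np.testing.assert_allclose(out.values, expect, atol=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_mass_preservation_random_interior(self, seed):
        rng = np.random.default_rng(seed)
        v = np.zeros(101)
        v[30:71] = rng.random(41)
        c = self._corr(v)
        out = smooth(c, 2.0)
        assert out.values.sum() == pytest.approx(v.sum(), rel=1e-9)


class TestDetectPeaks:
    def _gauss(self, lags, mu, sd, amp=1.0):
        return amp * np.exp(-0.5 * ((lags - mu) / sd) ** 2)

    def test_single_bump_located(self):
        lags = np.arange(-100, 101) * 0.1
        c = CorrelationFunction(lags, self._gauss(lags, 3.0, 0.5))
        peaks = detect_peaks(c, 8.0, 0.2)
        assert len(peaks) == 1
        assert peaks[0].tau == pytest.approx(3.0, abs=0.1)
        # width at half prominence ~ FWHM = 2.355 sd
        assert peaks[0].width == pytest.approx(2.355 * 0.5, rel=0.15)

    def test_two_separated_bumps(self):
        lags = np.arange(-100, 101) * 0.1
        v = self._gauss(lags, -4.0, 0.4) + self._gauss(lags, 6.0, 0.4, 0.8)
        peaks = detect_peaks(CorrelationFunction(lags, v), 8.0, 0.2)
        assert sorted(round(p.tau) for p in peaks) == [-4, 6]

    def test_flat_window_yields_nothing(self):
        lags = np.arange(-50, 51) * 0.1
        c = CorrelationFunction(lags, np.ones_like(lags))
        assert detect_peaks(c, 4.0, 0.2) == []

    def test_window_restricts_search(self):
        lags = np.arange(-100, 101) * 0.1
        v = self._gauss(lags, 6.0, 0.4)
        peaks = detect_peaks(CorrelationFunction(lags, v), 3.0, 0.2)
        assert peaks == []

    def test_zero_lag_peak_kept_but_directionless(self):
        lags = np.arange(-50, 51) * 0.1
        peaks = detect_peaks(
            CorrelationFunction(lags, self._gauss(lags, 0.0, 0.5)), 4.0, 0.2
        )
        assert len(peaks) == 1
        assert peaks[0].tau == 0.0
        assert peaks[0].directionless


class TestAllPairwisePeaks:
    def test_chain_delay_composition(self, chain_fixture):
        trains, _ = chain_fixture
        pg = all_pairwise_peaks(trains, dt=0.1, T=7.0, sigma=0.1)
        taus = {p.pair: p.tau for p in pg.peaks}
        assert taus[(0, 1)] == pytest.approx(2.0, abs=0.1)
        assert taus[(1, 2)] == pytest.approx(3.0, abs=0.1)
        assert taus[(0, 2)] == pytest.approx(5.0, abs=0.1)

    def test_pair_count_is_n_choose_2(self, random_trains):
        pg = all_pairwise_peaks(random_trains, dt=1.0, T=10.0, sigma=0.5)
        pairs = {p.pair for p in pg.peaks}
        assert pairs <= {(j, k) for j in range(4) for k in range(j + 1, 4)}
        assert all(j < k for j, k in pairs)

    def test_silent_neurons_yield_no_peaks(self):
        trains = SpikeTrainSet(
            3,
            [np.linspace(0.1, 9.0, 40), np.linspace(0.105, 9.005, 40),
             np.array([])],
            10.0,
        )
        pg = all_pairwise_peaks(trains, dt=1.0, T=10.0, sigma=0.5)
        assert all(2 not in p.pair for p in pg.peaks)

    def test_indirect_peak_lower_and_wider(self, jittered_chain_fixture):
        trains, _ = jittered_chain_fixture
        pg = all_pairwise_peaks(trains, dt=0.1, T=8.0, sigma=0.3)
        by_pair = {}
        for p in pg.peaks:
            best = by_pair.get(p.pair)
            if best is None or p.amplitude > best.amplitude:
                by_pair[p.pair] = p
        indirect = by_pair[(0, 2)]
        assert indirect.amplitude < by_pair[(0, 1)].amplitude
        assert indirect.amplitude < by_pair[(1, 2)].amplitude
        assert indirect.width > by_pair[(0, 1)].width


class TestSuggestEpsilon:
    def test_mean_of_widths(self, chain_fixture):
        trains, _ = chain_fixture
        pg = all_pairwise_peaks(trains, dt=0.1, T=7.0, sigma=0.1)
        widths = [p.width for p in pg.peaks]
        assert suggest_epsilon(pg) == pytest.approx(np.mean(widths))

    def test_rejects_empty_graph(self):
        from spikeconn.correlation import PeakGraph

        with pytest.raises(ValueError):
            suggest_epsilon(PeakGraph(3, []))
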