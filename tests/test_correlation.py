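import numpy as np
import pytest

from spikeconn.correlation import (
    CorrelationParams,
    _window_starts,
    cross_correlation_freq,
    cross_correlation_time,
    cross_correlograms,
    partial_correlation,
    partialize,
    spectral_matrices,
    write_correlation_files,
)
from spikeconn.io import SpikeTrain, bin_trains
from spikeconn.network import extract_connectivity
from spikeconn.simulate import generate_poisson_trains, make_motif_fixture

PARAMS = CorrelationParams(window_ms=20.0, bin_ms=1.0, peak_ms=10.0)


def brute_force_correlogram(x: SpikeTrain, y: SpikeTrain, params: CorrelationParams):
    """Direct lag-summation oracle: per correlation window, count spike pairs
    of the binned trains at every lag and normalize by the geometric mean of
    the zero-lag autocorrelation sums.  Independent of the FFT/searchsorted
    implementation paths."""
    binned = bin_trains([x, y], params.bin_ms)
    xb, yb = binned.counts.toarray().astype(float)
    w = params.half_width_bins
    seg = params.seg_len
    acc = np.zeros(2 * w + 1)
    ax = ay = 0.0
    for s in _window_starts(binned.n_bins, params):
        xs, ys = xb[s : s + seg], yb[s : s + seg]
        ax += np.sum(xs**2)
        ay += np.sum(ys**2)
        for lag in range(-w, w + 1):
            total = 0.0
            for b in range(len(xs)):
                if 0 <= b + lag < len(ys):
                    total += xs[b] * ys[b + lag]
            acc[lag + w] += total
    return acc / np.sqrt(ax * ay)


class TestCrossCorrelation:
    def test_matches_direct_summation_oracle(self):
        x, y = generate_poisson_trains(2, 8.0, 5.0, 1000.0, seed=11)
        expected = brute_force_correlogram(x, y, PARAMS)
        got_t = cross_correlation_time(x, y, PARAMS).values
        got_f = cross_correlation_freq(x, y, PARAMS).values
        np.testing.assert_allclose(got_t, expected, atol=1e-12)
        np.testing.assert_allclose(got_f, expected, atol=1e-9)

    def test_single_shifted_spike_pair(self):
        # reference spike in bin 2, target in bin 3 -> 1.0 at lag +1
        x = SpikeTrain(n_samples=200, spikes=np.array([2]), fs=1000.0, label="x")
        y = SpikeTrain(n_samples=200, spikes=np.array([3]), fs=1000.0, label="y")
        p = CorrelationParams(window_ms=5.0, bin_ms=1.0, peak_ms=5.0)
        for fn in (cross_correlation_time, cross_correlation_freq):
            c = fn(x, y, p)
            assert c.value_at(1) == pytest.approx(1.0)
            assert np.sum(np.abs(c.values)) == pytest.approx(1.0)

    def test_autocorrelogram_peaks_at_one(self, poisson_pair):
        for fn in (cross_correlation_time, cross_correlation_freq):
            c = fn(poisson_pair[0], poisson_pair[0], PARAMS)
            assert c.value_at(0) == pytest.approx(1.0, abs=1e-12)
            assert np.max(c.values) == pytest.approx(1.0, abs=1e-12)

    def test_values_normalized_to_unit_interval(self, poisson_pair):
        c = cross_correlation_time(*poisson_pair, PARAMS)
        assert np.all(c.values >= 0) and np.all(c.values <= 1)

    def test_reference_target_symmetry(self, poisson_pair):
        x, y = poisson_pair
        cxy = cross_correlation_time(x, y, PARAMS).values
        cyx = cross_correlation_time(y, x, PARAMS).values
        np.testing.assert_allclose(cxy, cyx[::-1], atol=1e-14)

    def test_time_frequency_equivalence(self):
        trains = generate_poisson_trains(10, 4.0, 20.0, 10000.0, seed=3)
        for k in range(0, 10, 2):
            ct = cross_correlation_time(trains[k], trains[k + 1], PARAMS).values
            cf = cross_correlation_freq(trains[k], trains[k + 1], PARAMS).values
            np.testing.assert_allclose(ct, cf, atol=1e-9)

    def test_equivalence_with_window_overlap(self):
        x, y = generate_poisson_trains(2, 5.0, 10.0, 1000.0, seed=5)
        p = CorrelationParams(window_ms=20.0, bin_ms=1.0, peak_ms=10.0, overlap_frac=0.5)
        ct = cross_correlation_time(x, y, p).values
        cf = cross_correlation_freq(x, y, p).values
        np.testing.assert_allclose(ct, cf, atol=1e-9)

    def test_empty_train_rejected(self):
        x = SpikeTrain(n_samples=100000, spikes=np.array([10]), fs=1000.0)
        e = SpikeTrain(n_samples=100000, spikes=np.array([], dtype=np.int64), fs=1000.0)
        with pytest.raises(ValueError, match="empty"):
            cross_correlation_time(x, e, PARAMS)

    def test_window_longer_than_recording_rejected(self):
        x = SpikeTrain(n_samples=300, spikes=np.array([10, 50]), fs=10000.0)
        y = SpikeTrain(n_samples=300, spikes=np.array([20, 60]), fs=10000.0)
        with pytest.raises(ValueError, match="longer than the recording"):
            cross_correlation_freq(x, y, CorrelationParams(window_ms=100.0, bin_ms=1.0))


class TestPartialCorrelation:
    def test_two_electrodes_reduce_to_cross_correlation(self):
        # empty conditioning population: partialization subtracts nothing
        trains = generate_poisson_trains(2, 5.0, 10.0, 1000.0, seed=2)
        binned = bin_trains(trains, 1.0)
        cc = cross_correlograms(binned, PARAMS)
        pc = partial_correlation(binned, PARAMS)
        np.testing.assert_allclose(pc.values[0, 1], cc.values[0, 1], atol=1e-10)

    def test_inverse_route_equals_direct_partialization(self):
        # n=3: S_xy|P = S_xy - S_xP S_PP^-1 S_Py, P the remaining electrode
        trains = generate_poisson_trains(3, 5.0, 10.0, 1000.0, seed=4)
        spec = spectral_matrices(bin_trains(trains, 1.0), PARAMS)
        s = spec.s
        sp = partialize(s)
        for x, y in [(0, 1), (0, 2), (1, 2)]:
            p = 3 - x - y
            direct = s[:, x, y] - s[:, x, p] / s[:, p, p] * s[:, p, y]
            np.testing.assert_allclose(sp[:, x, y], direct, atol=1e-8)

    def test_common_source_peak_suppressed(self, motif):
        net, trains = motif
        binned = bin_trains(trains, 1.0)
        cc_cm = extract_connectivity(cross_correlograms(binned, PARAMS), 10.0).symmetric_cm
        pc_cm = extract_connectivity(partial_correlation(binned, PARAMS), 10.0).symmetric_cm
        # pair (1,2) shares only the common source 0: partialization on
        # electrode 0 must strictly lower its peak
        assert pc_cm[1, 2] < cc_cm[1, 2]

    def test_hermitian_spectra(self, poisson_pair):
        spec = spectral_matrices(bin_trains(list(poisson_pair), 1.0), PARAMS)
        np.testing.assert_allclose(
            spec.s, np.conj(np.swapaxes(spec.s, 1, 2)), atol=1e-12
        )

    def test_symmetry(self):
        trains = generate_poisson_trains(4, 5.0, 10.0, 1000.0, seed=6)
        pc = partial_correlation(bin_trains(trains, 1.0), PARAMS)
        for i in range(4):
            for j in range(i + 1, 4):
                np.testing.assert_allclose(
                    pc.values[i, j], pc.values[j, i][::-1], atol=1e-10
                )

    def test_single_electrode_rejected(self):
        (t,) = generate_poisson_trains(1, 5.0, 10.0, 1000.0, seed=1)
        with pytest.raises(ValueError, match="at least 2"):
            partial_correlation(bin_trains([t], 1.0), PARAMS)


def test_correlation_file_output(tmp_path, poisson_pair):
    binned = bin_trains(list(poisson_pair), 1.0)
    cset = cross_correlograms(binned, PARAMS)
    files = write_correlation_files(cset, tmp_path)
    assert len(files) == 2
    lines = files[0].read_text().strip().splitlines()
    assert len(lines) == 1  # one record per target electrode
    rec = lines[0].split()
    assert int(rec[0]) == 1  # target index precedes the correlogram
    np.testing.assert_allclose(
        np.array(rec[1:], dtype=float), cset.values[0, 1], rtol=1e-9
    )
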