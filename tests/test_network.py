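import numpy as np
import pytest

from spikeconn.correlation import CorrelationParams, Correlogram, CorrelogramSet, cross_correlation_time
from spikeconn.io import SpikeTrain
from spikeconn.network import (
    ThresholdSpec,
    dither_train,
    extract_connectivity,
    hard_threshold,
    pairwise_matrix,
    surrogate_significance,
    write_edge_list,
    write_matrix,
)
from spikeconn.simulate import generate_poisson_trains


def _cset(values, lags, bin_ms=0.1, n=2):
    full = np.zeros((n, n, len(lags)))
    full[0, 1] = values
    full[1, 0] = values[::-1]
    return CorrelogramSet(
        lags=np.asarray(lags), values=full, bin_ms=bin_ms,
        labels=tuple(str(i) for i in range(n)),
    )


class TestExtractConnectivity:
    LAGS = np.arange(-5, 6)

    def test_positive_lag_peak_sets_direction_and_delay(self):
        vals = np.zeros(11)
        vals[5 + 2] = 0.7  # unique max at lag +2, bin 0.1 ms
        bundle = extract_connectivity(_cset(vals, self.LAGS), peak_ms=0.5)
        assert bundle.symmetric_cm[0, 1] == bundle.symmetric_cm[1, 0] == 0.7
        assert bundle.directional_cm[0, 1] == 0.7
        assert bundle.directional_cm[1, 0] == 0.0
        assert bundle.delay_ms[0, 1] == pytest.approx(0.2)
        assert bundle.delay_ms[1, 0] == pytest.approx(-0.2)

    def test_central_peak_gives_no_direction(self):
        vals = np.zeros(11)
        vals[5] = 0.9
        bundle = extract_connectivity(_cset(vals, self.LAGS), peak_ms=0.5)
        assert bundle.symmetric_cm[0, 1] == 0.9
        assert np.all(bundle.directional_cm == 0)
        assert np.all(bundle.delay_ms == 0)

    def test_flat_correlogram_ties_to_zero_lag(self):
        vals = np.full(11, 0.2)
        bundle = extract_connectivity(_cset(vals, self.LAGS), peak_ms=0.5)
        assert np.all(bundle.directional_cm == 0)
        assert np.all(bundle.delay_ms == 0)

    def test_tie_between_signs_prefers_positive_lag(self):
        vals = np.zeros(11)
        vals[5 - 3] = vals[5 + 3] = 0.4
        bundle = extract_connectivity(_cset(vals, self.LAGS), peak_ms=0.5)
        assert bundle.delay_ms[0, 1] == pytest.approx(0.3)

    def test_peak_search_respects_window(self):
        vals = np.zeros(11)
        vals[0] = 0.9  # at lag -5, outside the +-3-bin search
        vals[5 + 1] = 0.3
        bundle = extract_connectivity(_cset(vals, self.LAGS), peak_ms=0.3)
        assert bundle.symmetric_cm[0, 1] == 0.3

    def test_peak_window_wider_than_correlogram_rejected(self):
        with pytest.raises(ValueError, match="half-width"):
            extract_connectivity(_cset(np.zeros(11), self.LAGS), peak_ms=2.0)

    def test_matches_full_scan_oracle(self, rng):
        # cross-check the peak search against a literal scan over all lags
        for _ in range(20):
            vals = np.round(rng.random(11), 2)
            bundle = extract_connectivity(_cset(vals, self.LAGS), peak_ms=0.5)
            assert bundle.symmetric_cm[0, 1] == vals.max()
            peak_lag = bundle.delay_ms[0, 1] / 0.1
            assert vals[int(peak_lag) + 5] == vals.max()


class TestPairwiseMatrix:
    def test_motif_te_highest_for_true_couples(self, motif):
        net, trains = motif
        m = pairwise_matrix(trains, "te", bin_ms=1.0)
        off = ~np.eye(3, dtype=bool)
        true_vals = {m[0, 1], m[0, 2]}
        assert min(true_vals) > max(m[off][~np.isin(m[off], list(true_vals))])

    def test_motif_je_lowest_for_true_couples(self, motif):
        net, trains = motif
        m = pairwise_matrix(trains, "je", bin_ms=1.0, max_cisi_bins=50)
        off = ~np.eye(3, dtype=bool)
        true_vals = {m[0, 1], m[0, 2]}
        assert max(true_vals) < min(m[off][~np.isin(m[off], list(true_vals))])

    def test_single_electrode_rejected(self, motif):
        with pytest.raises(ValueError, match="at least 2"):
            pairwise_matrix(motif[1][:1], "te", bin_ms=1.0)

    def test_unknown_method_rejected(self, motif):
        with pytest.raises(ValueError, match="unknown method"):
            pairwise_matrix(motif[1], "xcorr", bin_ms=1.0)


class TestHardThreshold:
    def test_one_sigma_keeps_top_entry(self):
        cm = np.array([[0, 0.1, 0.2], [0.3, 0, 0.4], [0, 0, 0]])
        # nonzeros {0.1,0.2,0.3,0.4}: mu=0.25, sample sd~0.129 -> thr~0.379
        tcm = hard_threshold(cm, 1.0)
        assert tcm.threshold == pytest.approx(0.25 + np.std([0.1, 0.2, 0.3, 0.4], ddof=1))
        assert tcm.edges == [(1, 2, 0.4)]

    def test_equal_entries_all_removed(self):
        cm = np.full((3, 3), 0.5)
        np.fill_diagonal(cm, 0)
        tcm = hard_threshold(cm, 1.0)
        assert len(tcm.edges) == 0  # sigma=0, strict inequality at mu

    def test_zero_sigma_multiplier_keeps_above_mean(self):
        cm = np.array([[0, 0.1], [0.9, 0]])
        tcm = hard_threshold(cm, 0.0)
        assert tcm.edges == [(1, 0, 0.9)]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            hard_threshold(np.zeros((3, 3)), 1.0)

    def test_monotone_pruning(self, rng):
        cm = rng.random((8, 8))
        np.fill_diagonal(cm, 0)
        kept = [len(hard_threshold(cm, s).edges) for s in [0.0, 0.5, 1.0, 2.0]]
        assert kept == sorted(kept, reverse=True)
        # survivors are always a subset of the source nonzeros
        tcm = hard_threshold(cm, 1.0)
        assert np.all(cm[tcm.tcm > 0] == tcm.tcm[tcm.tcm > 0])


class TestDitherTrain:
    def _train(self, rng, n_spikes=300, n_samples=600000):
        spikes = np.sort(rng.choice(n_samples, size=n_spikes, replace=False))
        return SpikeTrain(n_samples=n_samples, spikes=spikes, fs=10000.0, label="d")

    def test_zero_window_is_identity(self, rng):
        t = self._train(rng)
        assert dither_train(t, 0.0, seed=1) == t

    def test_displacement_bounded_and_count_preserved(self, rng):
        t = self._train(rng)
        w_ms = 10.0
        w = int(round(w_ms * t.fs / 1000.0))
        d = dither_train(t, w_ms, seed=2)
        assert d.n_spikes == t.n_spikes
        assert d.mfr == t.mfr
        # each output spike lies within +-w of its source spike
        assert np.all(np.abs(np.sort(d.spikes) - np.sort(t.spikes)) <= 2 * w)
        # stricter per-spike check via the order-preserving construction
        for orig, new in zip(t.spikes, np.sort(d.spikes)):
            assert abs(new - orig) <= 2 * w

    def test_boundary_clipping(self):
        t = SpikeTrain(n_samples=100, spikes=np.array([0, 99]), fs=1000.0)
        d = dither_train(t, 50.0, seed=3)
        assert d.n_spikes == 2
        assert np.all((d.spikes >= 0) & (d.spikes < 100))

    def test_destroys_fine_timing_of_locked_pair(self):
        params = CorrelationParams(window_ms=20.0, bin_ms=1.0, peak_ms=10.0)
        drops = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = self._train(rng, n_spikes=400, n_samples=300000)
            y = SpikeTrain(
                n_samples=x.n_samples, spikes=np.clip(x.spikes + 20, 0, x.n_samples - 1),
                fs=x.fs, label="y",
            )  # locked copy at +2 ms
            peak0 = cross_correlation_time(x, y, params).values.max()
            yd = dither_train(y, 20.0, seed=seed + 100)  # w = 10x the delay
            peak1 = cross_correlation_time(x, yd, params).values.max()
            drops += peak1 < peak0
        assert drops >= 18  # dithering lowers the peak almost surely


class TestSurrogateSignificance:
    PARAMS = CorrelationParams(window_ms=20.0, bin_ms=1.0, peak_ms=10.0)

    def _locked_pair(self, seed):
        rng = np.random.default_rng(seed)
        n_samples = 300000
        spikes = np.sort(rng.choice(n_samples - 100, size=300, replace=False))
        x = SpikeTrain(n_samples=n_samples, spikes=spikes, fs=10000.0, label="x")
        y = SpikeTrain(n_samples=n_samples, spikes=spikes + 20, fs=10000.0, label="y")
        return x, y

    def test_locked_pair_retained(self):
        x, y = self._locked_pair(0)
        spec = ThresholdSpec(mode="surrogate", w_ms=20.0, n_surrogates=20, seed=1)
        tcm = surrogate_significance([x, y], "cc", self.PARAMS, spec)
        assert tcm.tcm[0, 1] > 0

    def test_independent_pair_rejected(self):
        trains = generate_poisson_trains(2, 3.0, 30.0, 10000.0, seed=5)
        spec = ThresholdSpec(mode="surrogate", w_ms=20.0, n_surrogates=20, seed=2)
        tcm = surrogate_significance(trains, "cc", self.PARAMS, spec)
        assert tcm.tcm[0, 1] == 0

    def test_je_direction_inverted(self):
        x, y = self._locked_pair(3)
        spec = ThresholdSpec(mode="surrogate", w_ms=20.0, n_surrogates=10, seed=4)
        tcm = surrogate_significance([x, y], "je", self.PARAMS, spec, max_cisi_bins=20)
        assert tcm.tcm[0, 1] != 0  # low JE accepted via the mean - 2SD rule

    def test_zero_surrogates_rejected(self):
        with pytest.raises(ValueError, match="n_surrogates"):
            ThresholdSpec(mode="surrogate", n_surrogates=0)


def test_matrix_and_edge_list_output(tmp_path):
    cm = np.array([[0, 0.9], [0.2, 0]])
    tcm = hard_threshold(cm, 0.0)
    p = write_matrix(tcm.tcm, tmp_path / "tcm.txt")
    np.testing.assert_allclose(np.loadtxt(p), tcm.tcm)
    e = write_edge_list(tcm, tmp_path / "edges.txt", delay_ms=np.array([[0, 1.5], [-1.5, 0]]))
    body = [l for l in e.read_text().splitlines() if not l.startswith("#")]
    assert body == ["0 1 0.9 1.5"]
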