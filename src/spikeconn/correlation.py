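"""Cross-correlation (time and frequency domains) and partial correlation.

The cross-correlogram of a reference train x and a target train y is the
lag histogram

    C_xy(tau) ~ sum_b x[b] * y[b + tau],   tau = -W .. +W bins,

accumulated over correlation windows that tile the binned recording, and
normalized by the geometric mean of the two zero-lag autocorrelation sums so
that an autocorrelogram peaks at exactly 1 and all values lie in [0, 1]
(Cauchy-Schwarz).  For trains with at most one spike per bin and
non-overlapping windows this normalization equals 1/sqrt(Nx*Ny), the usual
spike-count form.  Positive lag means the target fires after the reference,
and C_xy(tau) = C_yx(-tau).

The frequency-domain path computes the same quantity as the inverse FFT of
the window-averaged cross-spectrum; each window is zero-padded to a power of
two >= 2*len - 1 so the circular correlation equals the linear one, which
makes the two paths agree to floating-point precision.

Partial correlation removes the linear influence of all other electrodes P
from each pairwise cross-spectrum,

    S_xy|P = S_xy - S_xP S_PP^{-1} S_Py,

evaluated per frequency through the SVD pseudo-inverse G of the full n x n
spectral matrix via the exact conditional-spectrum identity
S_xy|P = -G_xy / (G_xx G_yy - G_xy G_yx); the partial correlogram is the
inverse FFT of S_xy|P scaled by the same autocorrelation-peak normalization
as the cross-correlogram, so that for n = 2 (empty conditioning population)
partial and cross-correlograms coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BinnedActivity, SpikeTrain, bin_trains

__all__ = [
    "CorrelationParams",
    "Correlogram",
    "CorrelogramSet",
    "SpectralMatrices",
    "spectral_matrices",
    "cross_correlation_time",
    "cross_correlation_freq",
    "cross_correlograms",
    "partial_correlation",
    "write_correlation_files",
]

# relative singular-value cutoff for the spectral pseudo-inverse
_PINV_RCOND = 1e-12


@dataclass(frozen=True)
class CorrelationParams:
    """Parameters shared by the correlation estimators.

    window_ms
        Correlogram half-width T: lags span -T..+T.
    bin_ms
        Bin width (lag resolution).
    overlap_frac
        Fractional overlap of adjacent correlation windows in [0, 1).
    peak_ms
        Half-width of the peak-search range around zero lag used when
        building connectivity matrices.
    """

    window_ms: float = 100.0
    bin_ms: float = 1.0
    overlap_frac: float = 0.0
    peak_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.window_ms <= 0 or self.bin_ms <= 0:
            raise ValueError("window_ms and bin_ms must be positive")
        if not 0.0 <= self.overlap_frac < 1.0:
            raise ValueError("overlap_frac must lie in [0, 1)")
        if self.peak_ms > self.window_ms:
            raise ValueError("peak_ms must not exceed window_ms")
        if self.half_width_bins < 1:
            raise ValueError("window_ms/bin_ms must round to at least one bin")

    @property
    def half_width_bins(self) -> int:
        """W: correlogram half-width in bins."""
        return int(round(self.window_ms / self.bin_ms))

    @property
    def seg_len(self) -> int:
        """Correlation-window length in bins (2W+1, covering lags -W..+W)."""
        return 2 * self.half_width_bins + 1

    @property
    def nfft(self) -> int:
        """FFT length: next power of two >= 2*seg_len - 1 (no circular wrap)."""
        n = 1
        while n < 2 * self.seg_len - 1:
            n *= 2
        return n

    @property
    def peak_bins(self) -> int:
        return int(round(self.peak_ms / self.bin_ms))

    @property
    def lags(self) -> np.ndarray:
        w = self.half_width_bins
        return np.arange(-w, w + 1)


@dataclass(frozen=True)
class Correlogram:
    """Correlation values over integer bin lags -W..+W for one ordered pair."""

    lags: np.ndarray
    values: np.ndarray
    bin_ms: float
    pair: tuple = ("", "")
    normalized: bool = True

    def __post_init__(self) -> None:
        if len(self.lags) != len(self.values):
            raise ValueError("lags and values must have equal length")

    @property
    def lag_ms(self) -> np.ndarray:
        return self.lags * self.bin_ms

    def value_at(self, lag: int) -> float:
        w = (len(self.lags) - 1) // 2
        return float(self.values[lag + w])


@dataclass(frozen=True)
class CorrelogramSet:
    """Correlograms for all ordered electrode pairs as an (n, n, 2W+1) array."""

    lags: np.ndarray
    values: np.ndarray
    bin_ms: float
    labels: tuple
    method: str = "cc"
    flagged: np.ndarray | None = None

    def pair(self, i: int, j: int) -> Correlogram:
        return Correlogram(
            lags=self.lags,
            values=self.values[i, j],
            bin_ms=self.bin_ms,
            pair=(self.labels[i], self.labels[j]),
        )


@dataclass(frozen=True)
class SpectralMatrices:
    """Window-summed cross-spectral tensor S[f, x, y] (Hermitian per frequency)."""

    s: np.ndarray  # (n_freq, n, n) complex, rfft frequencies
    nfft: int
    n_windows: int
    bin_ms: float
    labels: tuple = ()

    @property
    def freq_axis(self) -> np.ndarray:
        return np.fft.rfftfreq(self.nfft, d=self.bin_ms / 1000.0)


def _window_starts(n_bins: int, params: CorrelationParams) -> np.ndarray:
    seg = params.seg_len
    if n_bins < seg:
        raise ValueError(
            f"correlation window ({seg} bins) is longer than the recording ({n_bins} bins)"
        )
    hop = max(1, int(round((1.0 - params.overlap_frac) * seg)))
    return np.arange(0, n_bins, hop, dtype=np.int64)


def _row_spikes(binned: BinnedActivity, row: int):
    """(occupied bin indices, counts) of one electrode."""
    start, stop = binned.counts.indptr[row], binned.counts.indptr[row + 1]
    return (
        binned.counts.indices[start:stop].astype(np.int64),
        binned.counts.data[start:stop].astype(np.float64),
    )


def _time_domain_pair(bx, cx, by, cy, params: CorrelationParams, n_bins: int):
    """Windowed lag sums by direct counting; returns (acc_xy, auto0_x, auto0_y)."""
    w = params.half_width_bins
    seg = params.seg_len
    acc = np.zeros(2 * w + 1)
    auto_x = 0.0
    auto_y = 0.0
    for s in _window_starts(n_bins, params):
        i0, i1 = np.searchsorted(bx, [s, s + seg])
        j0, j1 = np.searchsorted(by, [s, s + seg])
        auto_x += float(np.sum(cx[i0:i1] ** 2))
        auto_y += float(np.sum(cy[j0:j1] ** 2))
        for i in range(i0, i1):
            b = bx[i]
            k0 = max(int(np.searchsorted(by, b - w, side="left")), j0)
            k1 = min(int(np.searchsorted(by, b + w, side="right")), j1)
            if k1 > k0:
                np.add.at(acc, by[k0:k1] - b + w, cx[i] * cy[k0:k1])
    return acc, auto_x, auto_y


def _pair_binned(x: SpikeTrain, y: SpikeTrain, params: CorrelationParams) -> BinnedActivity:
    if x.n_spikes == 0 or y.n_spikes == 0:
        raise ValueError("cross-correlation of an empty train has undefined normalization")
    return bin_trains([x, y], params.bin_ms)


def cross_correlation_time(
    x: SpikeTrain, y: SpikeTrain, params: CorrelationParams
) -> Correlogram:
    """Time-domain cross-correlogram: spikes of y tallied per lag bin around
    each spike of x, window by window, then normalized."""
    binned = _pair_binned(x, y, params)
    bx, cx = _row_spikes(binned, 0)
    by, cy = _row_spikes(binned, 1)
    acc, ax, ay = _time_domain_pair(bx, cx, by, cy, params, binned.n_bins)
    norm = np.sqrt(ax * ay)
    values = acc / norm if norm > 0 else acc
    return Correlogram(
        lags=params.lags, values=values, bin_ms=params.bin_ms, pair=(x.label, y.label)
    )


def spectral_matrices(
    binned: BinnedActivity, params: CorrelationParams, chunk: int = 64
) -> SpectralMatrices:
    """Cross-spectral tensor summed over correlation windows.

    Each window of every electrode is zero-padded to ``params.nfft`` and
    transformed with the real FFT; S[f, x, y] = sum_w conj(X_x) X_y, so the
    inverse FFT of S[:, x, y] recovers the window-summed lag products with
    positive lag meaning y after x.
    """
    n = binned.n_electrodes
    nfft = params.nfft
    seg = params.seg_len
    starts = _window_starts(binned.n_bins, params)
    nf = nfft // 2 + 1
    s = np.zeros((nf, n, n), dtype=np.complex128)
    csc = binned.counts.tocsc()
    for c0 in range(0, len(starts), chunk):
        batch = starts[c0 : c0 + chunk]
        segs = np.zeros((len(batch), n, seg))
        for k, st in enumerate(batch):
            block = csc[:, st : min(st + seg, binned.n_bins)].toarray()
            segs[k, :, : block.shape[1]] = block
        spec = np.fft.rfft(segs, n=nfft, axis=-1)  # (w, n, nf)
        b = spec.transpose(2, 0, 1)  # (nf, w, n)
        s += np.conj(b).transpose(0, 2, 1) @ b
    return SpectralMatrices(
        s=s, nfft=nfft, n_windows=len(starts), bin_ms=params.bin_ms, labels=binned.labels
    )


def _gather_lags(c_full: np.ndarray, w: int, nfft: int) -> np.ndarray:
    """Reorder a circular-lag axis 0 of length nfft into linear lags -w..+w (last axis)."""
    idx = np.concatenate([np.arange(nfft - w, nfft), np.arange(0, w + 1)])
    out = c_full[idx]
    return np.moveaxis(out, 0, -1)


def _normalized_from_spectra(spec: SpectralMatrices, params: CorrelationParams):
    """(lag-gathered raw correlograms, zero-lag autocorrelation sums)."""
    w = params.half_width_bins
    c_full = np.fft.irfft(spec.s, n=spec.nfft, axis=0)  # (nfft, n, n)
    auto0 = np.einsum("ii->i", c_full[0]).copy()
    values = _gather_lags(c_full, w, spec.nfft)  # (n, n, 2W+1)
    return values, auto0


def _apply_norm(values: np.ndarray, auto0: np.ndarray) -> np.ndarray:
    norm = np.sqrt(np.outer(auto0, auto0))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = values / norm[:, :, None]
    out[~np.isfinite(out)] = 0.0
    return out


def cross_correlograms(binned: BinnedActivity, params: CorrelationParams) -> CorrelogramSet:
    """Frequency-domain cross-correlograms for all ordered pairs."""
    spec = spectral_matrices(binned, params)
    values, auto0 = _normalized_from_spectra(spec, params)
    return CorrelogramSet(
        lags=params.lags,
        values=_apply_norm(values, auto0),
        bin_ms=params.bin_ms,
        labels=binned.labels,
        method="cc",
    )


def cross_correlation_freq(
    x: SpikeTrain, y: SpikeTrain, params: CorrelationParams
) -> Correlogram:
    """Frequency-domain cross-correlogram of one pair (IFFT of the averaged
    cross-spectrum); agrees with :func:`cross_correlation_time` to numerical
    precision."""
    binned = _pair_binned(x, y, params)
    cset = cross_correlograms(binned, params)
    return cset.pair(0, 1)


def partialize(s: np.ndarray) -> np.ndarray:
    """Conditional (partialized) cross-spectra for every pair, per frequency.

    Given the stacked Hermitian spectral matrices ``s`` of shape (nf, n, n),
    returns S_xy|P for all ordered pairs using the pseudo-inverse identity;
    diagonal entries are zeroed.
    """
    g = np.linalg.pinv(s, rcond=_PINV_RCOND, hermitian=True)
    d = np.einsum("fii->fi", g)
    det2 = d[:, :, None] * d[:, None, :] - g * np.swapaxes(g, 1, 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        sp = -g / det2
    sp[~np.isfinite(sp)] = 0.0
    n = s.shape[1]
    sp[:, np.arange(n), np.arange(n)] = 0.0
    return sp


def partial_correlation(binned: BinnedActivity, params: CorrelationParams) -> CorrelogramSet:
    """Partial correlograms for all ordered pairs.

    The pairwise cross-spectrum is partialized on all remaining electrodes
    per frequency, inverse-transformed, and scaled by the square root of the
    product of the two (raw) autocorrelation peaks.  Pairs whose spectra are
    identically zero are flagged and reported as zeros.
    """
    if binned.n_electrodes < 2:
        raise ValueError("partial correlation requires at least 2 active electrodes")
    spec = spectral_matrices(binned, params)
    _, auto0 = _normalized_from_spectra(spec, params)
    sp = partialize(spec.s)
    c_full = np.fft.irfft(sp, n=spec.nfft, axis=0)
    values = _gather_lags(c_full, params.half_width_bins, spec.nfft)
    flagged = auto0 <= 0
    return CorrelogramSet(
        lags=params.lags,
        values=_apply_norm(values, auto0),
        bin_ms=params.bin_ms,
        labels=binned.labels,
        method="pc",
        flagged=np.asarray(flagged),
    )


def write_correlation_files(cset: CorrelogramSet, out_dir) -> list:
    """One correlation file per reference electrode: each line holds the
    target electrode's index followed by the 2W+1 correlogram values."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    n = len(cset.labels)
    for i in range(n):
        path = out_dir / f"{cset.labels[i] or i}_{cset.method}.txt"
        with open(path, "w") as fh:
            for j in range(n):
                if j == i:
                    continue
                vals = " ".join(f"{v:.10g}" for v in cset.values[i, j])
                fh.write(f"{j} {vals}\n")
        written.append(path)
    return written
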