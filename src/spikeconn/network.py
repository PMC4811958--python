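"""Connectivity matrices from correlograms or pairwise scores, and thresholding.

Correlation-based methods yield three n x n matrices per recording: the
symmetric connectivity matrix (peak of each pair's correlogram within a
search range around zero lag), the directional matrix (the same peak
attributed to the ordered pair it supports: a peak at positive lag for
reference i / target j means i fires before j, i.e. i -> j), and the delay
matrix (signed peak lag in ms).  A peak exactly at lag zero carries no
direction information; ties are broken toward the smallest absolute lag,
then toward the positive lag.

Thresholding keeps either entries above the hard threshold mu + n*sigma of
the nonzero off-diagonal entries, or entries that beat a surrogate ensemble
built by spike-time dithering (mean + 2 SD of the surrogate statistic; the
rule is inverted for joint entropy, where low values indicate coupling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import infotheory
from .correlation import CorrelationParams, CorrelogramSet, cross_correlograms, partial_correlation
from .io import BinnedActivity, SpikeTrain, bin_trains, filter_active

__all__ = [
    "ConnectivityBundle",
    "ThresholdSpec",
    "ThresholdedCM",
    "extract_connectivity",
    "pairwise_matrix",
    "hard_threshold",
    "dither_train",
    "surrogate_significance",
    "write_matrix",
    "write_edge_list",
]


@dataclass(frozen=True)
class ConnectivityBundle:
    """Symmetric CM, directional CM and signed delay matrix for one method."""

    symmetric_cm: np.ndarray
    directional_cm: np.ndarray
    delay_ms: np.ndarray
    method: str = ""
    labels: tuple = ()
    params: CorrelationParams | None = None


@dataclass(frozen=True)
class ThresholdSpec:
    """How to prune a connectivity matrix.

    mode
        ``"hard"`` (mu + n_sigma * sigma of the nonzero entries) or
        ``"surrogate"`` (spike-time dithering significance test).
    n_sigma
        Multiplier for the hard threshold.
    w_ms
        Dither half-window: each spike is displaced uniformly within +-w_ms.
    n_surrogates
        Number of dithered surrogates per pair (surrogate mode).
    """

    mode: str = "hard"
    n_sigma: float = 2.0
    w_ms: float = 10.0
    n_surrogates: int = 20
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("hard", "surrogate"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "surrogate" and self.n_surrogates < 1:
            raise ValueError("surrogate mode needs n_surrogates >= 1")


@dataclass(frozen=True)
class ThresholdedCM:
    """A connectivity matrix with sub-threshold entries zeroed."""

    tcm: np.ndarray
    threshold: float | np.ndarray
    labels: tuple = ()
    method: str = ""

    @property
    def edges(self) -> list:
        """Surviving edges as (source index, target index, weight)."""
        out = []
        for i, j in zip(*np.nonzero(self.tcm)):
            out.append((int(i), int(j), float(self.tcm[i, j])))
        return out


def _peak_order(lags: np.ndarray, peak_bins: int):
    """Indices of lags |lag| <= peak_bins ordered by (|lag|, negative sign last)
    so that argmax tie-breaks toward the smallest |lag|, then positive lag."""
    sel = np.flatnonzero(np.abs(lags) <= peak_bins)
    key = sorted(sel, key=lambda k: (abs(int(lags[k])), 0 if lags[k] >= 0 else 1))
    return np.asarray(key, dtype=np.int64)


def extract_connectivity(cset: CorrelogramSet, peak_ms: float) -> ConnectivityBundle:
    """Build the three connectivity matrices from all-pairs correlograms.

    The peak is the maximum correlogram value within |lag| <= peak_ms.  Its
    sign of lag fixes the direction (positive: reference -> target) and its
    lag times the bin width gives the delay; a zero-lag peak populates only
    the symmetric matrix.
    """
    n = len(cset.labels)
    peak_bins = int(round(peak_ms / cset.bin_ms))
    w = (len(cset.lags) - 1) // 2
    if peak_bins > w:
        raise ValueError("peak_ms exceeds the correlogram half-width")
    order = _peak_order(cset.lags, peak_bins)
    sym = np.zeros((n, n))
    direc = np.zeros((n, n))
    delay = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals = cset.values[i, j, order]
            k = int(np.argmax(vals))
            peak = float(vals[k])
            lag = int(cset.lags[order[k]])
            sym[i, j] = sym[j, i] = peak
            delay[i, j] = lag * cset.bin_ms
            delay[j, i] = -lag * cset.bin_ms
            if lag > 0:
                direc[i, j] = peak
            elif lag < 0:
                direc[j, i] = peak
    return ConnectivityBundle(
        symmetric_cm=sym,
        directional_cm=direc,
        delay_ms=delay,
        method=cset.method,
        labels=cset.labels,
    )


def pairwise_matrix(
    trains,
    method: str,
    bin_ms: float,
    max_cisi_bins: int | None = None,
    window_ms: float = 100.0,
) -> np.ndarray:
    """n x n score matrix for an information-theory method.

    ``method="te"``: entry (i, j) = transfer entropy with source i, target j.
    ``method="je"``: entry (i, j) = joint entropy with reference i, target j
    (+inf sentinel when no cISI is found).  Diagonals are zero.
    """
    trains = list(trains)
    if len(trains) < 2:
        raise ValueError("pairwise analysis requires at least 2 active electrodes")
    binned = bin_trains(trains, bin_ms)
    n = binned.n_electrodes
    if method == "te":
        occ = np.asarray(binned.occupancy().todense())
        return infotheory.te_matrix_binary(occ)
    if method == "je":
        if max_cisi_bins is None:
            max_cisi_bins = max(1, int(round(window_ms / bin_ms)))
        bins = [binned.bin_indices(i) for i in range(n)]
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                out[i, j] = infotheory.joint_entropy(
                    bins[i], bins[j], max_cisi_bins, bin_ms=bin_ms
                ).value
        return out
    raise ValueError(f"unknown method {method!r} (expected 'te' or 'je')")


def hard_threshold(cm: np.ndarray, n_sigma: float) -> ThresholdedCM:
    """Keep entries strictly above mu + n_sigma*sigma of the nonzero
    off-diagonal entries (sigma is the sample standard deviation)."""
    cm = np.asarray(cm, dtype=np.float64)
    off = ~np.eye(cm.shape[0], dtype=bool)
    nz = cm[off & (cm != 0)]
    if nz.size == 0:
        raise ValueError("cannot threshold an all-zero connectivity matrix")
    mu = float(np.mean(nz))
    sigma = float(np.std(nz, ddof=1)) if nz.size > 1 else 0.0
    thr = mu + n_sigma * sigma
    tcm = np.where(off & (cm > thr), cm, 0.0)
    return ThresholdedCM(tcm=tcm, threshold=thr)


def dither_train(train: SpikeTrain, w_ms: float, seed=None) -> SpikeTrain:
    """Spike-time dithering surrogate: displace each spike independently and
    uniformly within +-w_ms of its original position.

    Rates and spike counts are preserved exactly: displacements are clipped
    to the recording, and collisions are re-drawn for the later spike (up to
    100 attempts, falling back to the original position, then to the nearest
    free sample).
    """
    if w_ms < 0:
        raise ValueError("w_ms must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    w = int(round(w_ms * train.fs / 1000.0))
    if w == 0 or train.n_spikes == 0:
        return train
    lo = np.maximum(train.spikes - w, 0)
    hi = np.minimum(train.spikes + w, train.n_samples - 1)
    displaced = rng.integers(lo, hi + 1)
    used = set()
    out = np.empty_like(displaced)
    for k in range(displaced.size):
        s = int(displaced[k])
        attempts = 0
        while s in used and attempts < 100:
            s = int(rng.integers(lo[k], hi[k] + 1))
            attempts += 1
        if s in used:
            s = int(train.spikes[k])
            step = 0
            while s in used:  # nearest free sample; bounded by n_samples
                step += 1
                if train.spikes[k] - step >= 0 and (train.spikes[k] - step) not in used:
                    s = int(train.spikes[k] - step)
                elif train.spikes[k] + step < train.n_samples and (
                    train.spikes[k] + step
                ) not in used:
                    s = int(train.spikes[k] + step)
        used.add(s)
        out[k] = s
    return SpikeTrain(
        n_samples=train.n_samples, spikes=np.sort(out), fs=train.fs, label=train.label
    )


def _score_matrix(trains, method: str, params: CorrelationParams, max_cisi_bins=None):
    """Observed pair statistic for the surrogate test: correlogram peak within
    +-peak_ms for cc/pc, matrix entry for te/je."""
    if method in ("cc", "cc-time", "cc-freq"):
        binned = bin_trains(trains, params.bin_ms)
        cset = cross_correlograms(binned, params)
        return extract_connectivity(cset, params.peak_ms).symmetric_cm
    if method == "pc":
        binned = bin_trains(trains, params.bin_ms)
        cset = partial_correlation(binned, params)
        return extract_connectivity(cset, params.peak_ms).symmetric_cm
    if method in ("te", "je"):
        return pairwise_matrix(
            trains, method, params.bin_ms,
            max_cisi_bins=max_cisi_bins, window_ms=params.window_ms,
        )
    raise ValueError(f"unknown method {method!r}")


def surrogate_significance(
    trains,
    method: str,
    params: CorrelationParams,
    spec: ThresholdSpec,
    max_cisi_bins=None,
) -> ThresholdedCM:
    """Spike-time-dithering significance test for a whole recording.

    Each surrogate dithers every train and recomputes the pair statistic; a
    connection is kept iff the observed statistic exceeds the surrogate mean
    plus two surrogate standard deviations (for joint entropy: falls below
    the mean minus two standard deviations, since low JE indicates coupling).
    """
    if spec.n_surrogates < 1:
        raise ValueError("surrogate significance needs n_surrogates >= 1")
    trains = list(trains)
    rng = np.random.default_rng(spec.seed)
    observed = _score_matrix(trains, method, params, max_cisi_bins)
    stats = np.empty((spec.n_surrogates,) + observed.shape)
    for s in range(spec.n_surrogates):
        surro = [dither_train(t, spec.w_ms, rng) for t in trains]
        stats[s] = _score_matrix(surro, method, params, max_cisi_bins)
    finite = np.where(np.isfinite(stats), stats, np.nan)
    mean = np.nanmean(finite, axis=0)
    sd = np.nanstd(finite, axis=0, ddof=0) if spec.n_surrogates > 1 else np.zeros_like(mean)
    if method == "je":
        keep = observed < (mean - 2.0 * sd)
        keep &= np.isfinite(observed)
    else:
        keep = observed > (mean + 2.0 * sd)
    np.fill_diagonal(keep, False)
    tcm = np.where(keep & np.isfinite(observed), observed, 0.0)
    bound = mean + 2.0 * sd if method != "je" else mean - 2.0 * sd
    return ThresholdedCM(tcm=tcm, threshold=bound, method=method)


def write_matrix(matrix: np.ndarray, path) -> Path:
    """Dense whitespace-separated n x n text matrix."""
    path = Path(path)
    np.savetxt(path, np.asarray(matrix), fmt="%.10g")
    return path


def write_edge_list(tcm: ThresholdedCM, path, delay_ms: np.ndarray | None = None) -> Path:
    """Edges as 'source target weight delay_ms' rows."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# source target weight delay_ms\n")
        for i, j, wgt in tcm.edges:
            d = float(delay_ms[i, j]) if delay_ms is not None else 0.0
            fh.write(f"{i} {j} {wgt:.10g} {d:.10g}\n")
    return path
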