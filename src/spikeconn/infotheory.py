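"""First-order transfer entropy and cISI-based joint entropy.

Both estimators operate on binary occupancy sequences: a bin holds 1 if the
electrode fired at least once inside it.  Transfer entropy from a source
train y to a target train x is

    TE_{y->x} = sum p(x_t, x_{t-1}, y_{t-1})
                log2 [ p(x_t | x_{t-1}, y_{t-1}) / p(x_t | x_{t-1}) ],

estimated by counting the eight joint states of (x_t, x_{t-1}, y_{t-1}) over
t = 1..T-1, with 0*log(0) = 0.  It is directed (not symmetric) and bounded
by 1 bit for binary states.

Joint entropy is the entropy of the cross inter-spike-interval (cISI)
distribution: for each occupied bin of the reference train the delay in bins
to the next occupied bin of the target train (same-bin counts as size 0) is
recorded, restricted to ``max_cisi_bins``; JE = -sum p(cISI_k) log2 p(cISI_k).
A tightly locked pair gives a concentrated histogram, hence a LOW joint
entropy; pairs with no cISI in range carry no coupling evidence and score a
+inf sentinel (ranked as "no connection").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TEEstimate",
    "JEEstimate",
    "transfer_entropy",
    "joint_entropy",
    "NO_COUPLING",
]

NO_COUPLING = np.inf
"""Sentinel joint-entropy value for pairs with no cISI in the search range."""


@dataclass(frozen=True)
class TEEstimate:
    value: float
    pair: tuple = ("", "")  # (source y, target x)
    bin_ms: float = float("nan")


@dataclass(frozen=True)
class JEEstimate:
    value: float
    pair: tuple = ("", "")  # (reference x, target y)
    bin_ms: float = float("nan")
    max_cisi_bins: int = 0
    histogram: np.ndarray | None = None  # probability per cISI size 0..max


def _as_binary(seq) -> np.ndarray:
    return (np.asarray(seq) > 0).astype(np.int8)


def te_from_counts(counts: np.ndarray) -> float:
    """Transfer entropy in bits from the 8 joint-state counts.

    ``counts[s]`` is the number of transitions with state index
    ``s = 4*x_t + 2*x_{t-1} + y_{t-1}``.
    """
    counts = np.asarray(counts, dtype=np.float64).reshape(2, 2, 2)  # [x_t, x_tm1, y_tm1]
    total = counts.sum()
    if total <= 0:
        return 0.0
    p_xyz = counts / total
    p_bc = counts.sum(axis=0)  # (x_{t-1}, y_{t-1})
    p_ab = counts.sum(axis=2)  # (x_t, x_{t-1})
    p_b = counts.sum(axis=(0, 2))  # (x_{t-1},)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond_full = counts / p_bc[None, :, :]  # p(x_t | x_{t-1}, y_{t-1})
        cond_self = p_ab / p_b[None, :]  # p(x_t | x_{t-1})
        ratio = cond_full / cond_self[:, :, None]
        terms = p_xyz * np.log2(ratio)
    terms[p_xyz == 0] = 0.0
    return float(np.sum(terms))


def transfer_entropy(source, target, bin_ms: float = float("nan")) -> TEEstimate:
    """First-order transfer entropy TE_{source -> target} in bits.

    Parameters
    ----------
    source, target : binary (or count) bin sequences of equal length >= 2.
    """
    y = _as_binary(source)
    x = _as_binary(target)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("source and target must be 1-D sequences of equal length")
    if x.size < 2:
        raise ValueError("transfer entropy needs at least 2 bins")
    state = 4 * x[1:] + 2 * x[:-1] + y[:-1]
    counts = np.bincount(state, minlength=8)
    return TEEstimate(value=te_from_counts(counts), bin_ms=bin_ms)


def cisi_histogram(ref_bins: np.ndarray, tgt_bins: np.ndarray, max_cisi_bins: int):
    """cISI counts per size 0..max_cisi_bins.

    For each occupied reference bin, the next occupied target bin at delay
    0..max_cisi_bins contributes one cISI of that size.
    """
    if max_cisi_bins < 1:
        raise ValueError("max_cisi_bins must be >= 1")
    ref_bins = np.asarray(ref_bins, dtype=np.int64)
    tgt_bins = np.asarray(tgt_bins, dtype=np.int64)
    counts = np.zeros(max_cisi_bins + 1, dtype=np.int64)
    if ref_bins.size == 0 or tgt_bins.size == 0:
        return counts
    pos = np.searchsorted(tgt_bins, ref_bins, side="left")
    ok = pos < tgt_bins.size
    sizes = tgt_bins[pos[ok]] - ref_bins[ok]
    sizes = sizes[sizes <= max_cisi_bins]
    np.add.at(counts, sizes, 1)
    return counts


def joint_entropy(
    reference, target, max_cisi_bins: int, bin_ms: float = float("nan")
) -> JEEstimate:
    """Joint entropy of the cISI histogram between two occupancy sequences.

    ``reference`` and ``target`` may be binary bin sequences or sorted arrays
    of occupied-bin indices (any 1-D integer array that is strictly
    increasing is taken as indices).
    """
    ref_bins = _occupied_bins(reference)
    tgt_bins = _occupied_bins(target)
    counts = cisi_histogram(ref_bins, tgt_bins, max_cisi_bins)
    total = counts.sum()
    if total == 0:
        return JEEstimate(
            value=NO_COUPLING, bin_ms=bin_ms, max_cisi_bins=max_cisi_bins, histogram=None
        )
    p = counts / total
    nz = p[p > 0]
    value = float(-np.sum(nz * np.log2(nz)))
    return JEEstimate(value=value, bin_ms=bin_ms, max_cisi_bins=max_cisi_bins, histogram=p)


def _occupied_bins(seq) -> np.ndarray:
    arr = np.asarray(seq)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D sequence")
    if arr.size and not np.all((arr == 0) | (arr == 1)):
        # interpreted as occupied-bin indices
        if np.any(np.diff(arr) <= 0):
            raise ValueError("bin indices must be strictly increasing")
        return arr.astype(np.int64)
    return np.flatnonzero(arr)


def te_matrix_binary(occ: np.ndarray) -> np.ndarray:
    """All-pairs first-order transfer entropy from a dense binary array.

    ``occ`` has shape (n_electrodes, n_bins); entry (i, j) of the result is
    TE with source i and target j.  Vectorized through three matrix products
    that count the triple-coincidence states for every pair at once.
    """
    occ = (np.asarray(occ) > 0)
    n, t = occ.shape
    if t < 2:
        raise ValueError("transfer entropy needs at least 2 bins")
    # float32 is exact here: all products are 0/1 and all partial sums are
    # integers well below 2**24
    a = occ[:, 1:].astype(np.float32)  # x_t rows
    b = occ[:, :-1].astype(np.float32)  # x_{t-1}/y_{t-1} rows
    nt = t - 1
    # per-target marginal counts over (x_t, x_{t-1})
    s11 = np.einsum("jt,jt->j", a, b)
    s10 = a.sum(axis=1) - s11
    s01 = b.sum(axis=1) - s11
    s00 = nt - s11 - s10 - s01
    # per-pair counts with y_{t-1} = 1: m_ab[i, j] = #{x_t=a, x_{t-1}=b, y_{t-1}=1}
    m11 = b @ (a * b).T
    m10 = b @ (a * (1.0 - b)).T
    m01 = b @ ((1.0 - a) * b).T
    y1 = b.sum(axis=1)  # total bins with y_{t-1} = 1, per source i
    m00 = y1[:, None] - m11 - m10 - m01
    te = np.zeros((n, n))
    counts = np.empty(8)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            c111, c101, c011, c001 = m11[i, j], m10[i, j], m01[i, j], m00[i, j]
            counts[:] = (
                s00[j] - c001,  # x_t=0, x_{t-1}=0, y=0
                c001,
                s01[j] - c011,  # x_t=0, x_{t-1}=1, y=0
                c011,
                s10[j] - c101,
                c101,
                s11[j] - c111,
                c111,
            )
            te[i, j] = te_from_counts(counts)
    return te
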