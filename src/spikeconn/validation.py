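"""ROC/AUC validation of score matrices against a ground-truth synaptic
weight matrix (SWM).

A ROC curve is traced by sweeping a classification threshold over the
percentiles (0.5, 1.0, ..., 99.5) of the off-diagonal scores; at each
threshold, entries strictly above it are predicted edges, and

    TPR = TP / (TP + FN),    FPR = FP / (FP + TN)

are tallied against the SWM (an entry is a true edge iff its weight is
nonzero).  Symmetric methods are scored on the OR-symmetrized truth;
methods whose low values indicate coupling (joint entropy) enter with the
score sign inverted.  The AUC is the trapezoidal area under the (FPR, TPR)
polyline with (0, 0) and (1, 1) appended; 0.5 corresponds to a random
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ROCResult", "roc_curve", "auc"]


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    n_true: int = 0
    n_false: int = 0


def _off_diagonal_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def roc_curve(
    scores: np.ndarray,
    swm: np.ndarray,
    mode: str = "directed",
    invert: bool = False,
    percentiles: np.ndarray | None = None,
) -> ROCResult:
    """ROC of an n x n score matrix against the ground-truth weight matrix.

    Parameters
    ----------
    scores
        Pairwise connectivity scores; the diagonal is ignored.
    swm
        Ground-truth synaptic weight matrix (or a GroundTruthNetwork).
    mode
        ``"directed"``: every ordered off-diagonal pair is classified.
        ``"symmetric"``: the truth is OR-symmetrized first (an undirected
        edge exists iff either direction has nonzero weight).
    invert
        Negate scores before sweeping (for joint entropy, where lower
        values mean stronger coupling).
    """
    swm = getattr(swm, "swm", swm)
    scores = np.asarray(scores, dtype=np.float64)
    swm = np.asarray(swm)
    if scores.shape != swm.shape or scores.ndim != 2 or scores.shape[0] != scores.shape[1]:
        raise ValueError("scores and swm must be square matrices of equal shape")
    if mode not in ("directed", "symmetric"):
        raise ValueError(f"unknown mode {mode!r}")
    truth = swm != 0
    if mode == "symmetric":
        truth = truth | truth.T
    off = _off_diagonal_mask(scores.shape[0])
    s = scores[off]
    t = truth[off]
    if invert:
        s = -s
    # map sentinels to finite extremes so percentile thresholds stay finite
    finite = s[np.isfinite(s)]
    if finite.size == 0:
        raise ValueError("no finite scores to classify")
    span = max(1.0, finite.max() - finite.min())
    s = np.where(np.isposinf(s), finite.max() + span, s)
    s = np.where(np.isneginf(s), finite.min() - span, s)
    n_true = int(t.sum())
    n_false = int((~t).sum())
    if n_true == 0 or n_false == 0:
        raise ValueError("truth has a single class: TPR/FPR undefined")
    if percentiles is None:
        percentiles = np.arange(0.5, 100.0, 0.5)
    thresholds = np.percentile(s, percentiles)
    pred = s[None, :] > thresholds[:, None]
    tp = (pred & t[None, :]).sum(axis=1)
    fp = (pred & ~t[None, :]).sum(axis=1)
    tpr = tp / n_true
    fpr = fp / n_false
    result = ROCResult(
        thresholds=thresholds, tpr=tpr, fpr=fpr, auc=0.0, n_true=n_true, n_false=n_false
    )
    return ROCResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc(result),
        n_true=n_true,
        n_false=n_false,
    )


def auc(roc: ROCResult) -> float:
    """Trapezoidal area under the ROC polyline, endpoints (0,0),(1,1) appended."""
    fpr = np.concatenate([[0.0], np.asarray(roc.fpr, dtype=float), [1.0]])
    tpr = np.concatenate([[0.0], np.asarray(roc.tpr, dtype=float), [1.0]])
    order = np.lexsort((tpr, fpr))  # vertical steps traversed upward
    return float(np.trapezoid(tpr[order], fpr[order]))


def write_roc(roc: ROCResult, path) -> Path:
    """Tabular text output: threshold, FPR, TPR per row plus the AUC."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# auc {roc.auc:.6f}\n# threshold fpr tpr\n")
        for thr, f, t in zip(roc.thresholds, roc.fpr, roc.tpr):
            fh.write(f"{thr:.10g} {f:.6f} {t:.6f}\n")
    return path
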