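"""Scikit-learn-style connectivity estimators.

Each estimator consumes a list of :class:`~spikeconn.io.SpikeTrain` objects
(one per electrode, same recording) in ``fit`` and exposes the inferred
pairwise connectivity through fitted attributes:

``scores_``
    n x n score matrix (the method's natural connectivity statistic).
``labels_``
    electrode labels of the retained (active) trains, in row order.

Correlation-based estimators additionally expose ``correlograms_``,
``symmetric_cm_``, ``directional_cm_`` and ``delay_ms_``.  All estimators
implement ``get_params``/``set_params`` and compose with scikit-learn
model-selection utilities; convenience methods ``threshold`` and ``roc``
wrap the thresholding and ground-truth validation steps.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import network, validation
from .correlation import (
    CorrelationParams,
    cross_correlograms,
    partial_correlation,
)
from .io import bin_trains, filter_active

__all__ = [
    "CrossCorrelation",
    "PartialCorrelation",
    "TransferEntropy",
    "JointEntropy",
]


class _BaseConnectivity(BaseEstimator):
    """Shared fit plumbing: activity filtering and input validation."""

    _roc_mode = "directed"
    _roc_invert = False

    def _prepare(self, X):
        trains = list(X)
        if not trains:
            raise ValueError("fit requires at least one spike train")
        active = filter_active(trains, self.mfr_min)
        if len(active) < 2:
            raise ValueError("fewer than 2 active electrodes after MFR filtering")
        self.labels_ = tuple(t.label for t in active)
        self.n_features_in_ = len(trains)
        return active

    def fit(self, X, y=None):  # pragma: no cover - overridden
        raise NotImplementedError

    def threshold(self, n_sigma: float = 2.0) -> network.ThresholdedCM:
        """Hard-threshold the fitted score matrix at mu + n_sigma*sigma."""
        self._check_fitted()
        return network.hard_threshold(np.nan_to_num(self.scores_, posinf=0.0), n_sigma)

    def roc(self, swm) -> validation.ROCResult:
        """ROC of the fitted scores against a ground-truth weight matrix."""
        self._check_fitted()
        return validation.roc_curve(
            self.scores_, swm, mode=self._roc_mode, invert=self._roc_invert
        )

    def _check_fitted(self):
        if not hasattr(self, "scores_"):
            raise AttributeError("estimator is not fitted yet; call fit first")


class _BaseCorrelation(_BaseConnectivity):
    _roc_mode = "symmetric"

    def __init__(self, bin_ms=1.0, window_ms=100.0, overlap_frac=0.0, peak_ms=10.0,
                 mfr_min=0.1):
        self.bin_ms = bin_ms
        self.window_ms = window_ms
        self.overlap_frac = overlap_frac
        self.peak_ms = peak_ms
        self.mfr_min = mfr_min

    def _params(self) -> CorrelationParams:
        return CorrelationParams(
            window_ms=self.window_ms,
            bin_ms=self.bin_ms,
            overlap_frac=self.overlap_frac,
            peak_ms=self.peak_ms,
        )

    def _correlograms(self, binned, params):  # pragma: no cover - overridden
        raise NotImplementedError

    def fit(self, X, y=None):
        active = self._prepare(X)
        params = self._params()
        binned = bin_trains(active, self.bin_ms)
        cset = self._correlograms(binned, params)
        bundle = network.extract_connectivity(cset, self.peak_ms)
        self.correlograms_ = cset
        self.lags_ms_ = cset.lags * cset.bin_ms
        self.symmetric_cm_ = bundle.symmetric_cm
        self.directional_cm_ = bundle.directional_cm
        self.delay_ms_ = bundle.delay_ms
        self.scores_ = bundle.symmetric_cm
        return self


class CrossCorrelation(_BaseCorrelation):
    """Cross-correlation connectivity (time- or frequency-domain path).

    Both paths compute the same normalized correlogram; the frequency path
    (default) is the fast one for whole arrays, and their agreement to
    numerical precision is part of the package's test contract.
    """

    def __init__(self, bin_ms=1.0, window_ms=100.0, overlap_frac=0.0, peak_ms=10.0,
                 mfr_min=0.1, domain="frequency"):
        super().__init__(bin_ms, window_ms, overlap_frac, peak_ms, mfr_min)
        self.domain = domain

    def _correlograms(self, binned, params):
        from .correlation import CorrelogramSet, cross_correlation_time

        if self.domain == "frequency":
            return cross_correlograms(binned, params)
        if self.domain != "time":
            raise ValueError(f"unknown domain {self.domain!r}")
        # time-domain path, pair by pair (exploits C_xy(tau) = C_yx(-tau))
        n = binned.n_electrodes
        w = params.half_width_bins
        values = np.zeros((n, n, 2 * w + 1))
        from .correlation import _row_spikes, _time_domain_pair

        rows = [_row_spikes(binned, i) for i in range(n)]
        for i in range(n):
            for j in range(i, n):
                acc, ax, ay = _time_domain_pair(
                    rows[i][0], rows[i][1], rows[j][0], rows[j][1], params, binned.n_bins
                )
                norm = np.sqrt(ax * ay)
                vals = acc / norm if norm > 0 else acc
                values[i, j] = vals
                values[j, i] = vals[::-1]
        return CorrelogramSet(
            lags=params.lags, values=values, bin_ms=params.bin_ms,
            labels=binned.labels, method="cc",
        )


class PartialCorrelation(_BaseCorrelation):
    """Partial correlation: pairwise cross-spectra partialized on all other
    electrodes before inverse-transforming to correlograms.  Removes linear
    common-input and chain effects that inflate plain cross-correlation."""

    def _correlograms(self, binned, params):
        return partial_correlation(binned, params)


class TransferEntropy(_BaseConnectivity):
    """First-order transfer entropy; ``scores_[i, j]`` is TE with source i
    and target j (directed)."""

    def __init__(self, bin_ms=1.0, mfr_min=0.1):
        self.bin_ms = bin_ms
        self.mfr_min = mfr_min

    def fit(self, X, y=None):
        active = self._prepare(X)
        self.scores_ = network.pairwise_matrix(active, "te", self.bin_ms)
        return self


class JointEntropy(_BaseConnectivity):
    """Joint entropy of the cISI histogram; low values indicate coupling, so
    ROC evaluation inverts the score sign.  ``scores_[i, j]`` uses reference
    i and target j; pairs with no cISI in range hold +inf."""

    _roc_invert = True

    def __init__(self, bin_ms=1.0, max_cisi_bins=None, window_ms=100.0, mfr_min=0.1):
        self.bin_ms = bin_ms
        self.max_cisi_bins = max_cisi_bins
        self.window_ms = window_ms
        self.mfr_min = mfr_min

    def fit(self, X, y=None):
        active = self._prepare(X)
        self.scores_ = network.pairwise_matrix(
            active, "je", self.bin_ms,
            max_cisi_bins=self.max_cisi_bins, window_ms=self.window_ms,
        )
        return self

    def threshold(self, n_sigma: float = 2.0) -> network.ThresholdedCM:
        """Hard threshold on the coupling strength -JE (low joint entropy
        means strong coupling); pairs with no cISI evidence are dropped.
        The returned matrix holds -JE for the surviving pairs."""
        self._check_fitted()
        finite = np.where(np.isfinite(self.scores_), -self.scores_, 0.0)
        return network.hard_threshold(finite, n_sigma)
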