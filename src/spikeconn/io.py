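"""Spike-train text I/O, experiment discovery, activity filtering and binning.

A recording is stored as one plain-text file per electrode: a whitespace
separated sequence of integers whose first element is the total number of
samples in the recording and whose remaining elements are the sample indices
at which spikes were detected.  All estimators in this package consume the
sparse binned representation produced by :func:`bin_trains`.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

__all__ = [
    "SpikeTrain",
    "BinnedActivity",
    "ExperimentSet",
    "SpikeFormatError",
    "read_spike_train",
    "write_spike_train",
    "discover_experiments",
    "filter_active",
    "bin_trains",
]


class SpikeFormatError(ValueError):
    """Raised when a spike-train file or object violates the format contract."""


@dataclass(frozen=True)
class SpikeTrain:
    """A point process recorded from one electrode.

    Parameters
    ----------
    n_samples : int
        Total number of samples in the recording.
    spikes : numpy.ndarray of int
        Strictly increasing sample indices of detected spikes, all in
        ``[0, n_samples)``.
    fs : float
        Sampling rate in Hz.
    label : str
        Electrode identifier (the file stem for trains read from disk).
    """

    n_samples: int
    spikes: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        spikes = np.asarray(self.spikes, dtype=np.int64)
        object.__setattr__(self, "spikes", spikes)
        if self.n_samples < 1:
            raise SpikeFormatError(f"n_samples must be >= 1, got {self.n_samples}")
        if self.fs <= 0:
            raise SpikeFormatError(f"sampling rate must be positive, got {self.fs}")
        if spikes.size:
            if spikes[0] < 0:
                raise SpikeFormatError(f"negative spike index {spikes[0]}")
            if spikes[-1] >= self.n_samples:
                raise SpikeFormatError(
                    f"spike index {spikes[-1]} >= n_samples {self.n_samples}"
                )
            if np.any(np.diff(spikes) <= 0):
                bad = int(np.flatnonzero(np.diff(spikes) <= 0)[0]) + 1
                raise SpikeFormatError(
                    f"spike indices not strictly increasing at position {bad} "
                    f"(value {spikes[bad]})"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.spikes.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def mfr(self) -> float:
        """Mean firing rate in spikes/s."""
        return self.n_spikes * self.fs / self.n_samples

    @property
    def times_s(self) -> np.ndarray:
        """Spike times in seconds."""
        return self.spikes / self.fs

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpikeTrain):
            return NotImplemented
        return (
            self.n_samples == other.n_samples
            and self.fs == other.fs
            and self.label == other.label
            and np.array_equal(self.spikes, other.spikes)
        )


@dataclass(frozen=True)
class BinnedActivity:
    """Sparse electrodes x bins spike-count matrix.

    ``counts[e, b]`` is the number of spikes of electrode ``e`` whose sample
    index falls in the half-open bin ``[b*bin_samples, (b+1)*bin_samples)``.
    The trailing partial bin is retained so that the total spike count is
    conserved for every bin size.
    """

    counts: sp.csr_matrix
    bin_samples: int
    fs: float
    n_samples: int
    labels: tuple = field(default_factory=tuple)

    @property
    def bin_ms(self) -> float:
        return self.bin_samples / self.fs * 1000.0

    @property
    def n_electrodes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def occupancy(self) -> sp.csr_matrix:
        """Binary view (count > 0), used by the information-theoretic estimators."""
        occ = self.counts.copy()
        occ.data = (occ.data > 0).astype(np.int8)
        occ.eliminate_zeros()
        return occ

    def bin_indices(self, row: int) -> np.ndarray:
        """Sorted occupied-bin indices of one electrode."""
        start, stop = self.counts.indptr[row], self.counts.indptr[row + 1]
        return self.counts.indices[start:stop].astype(np.int64)


@dataclass(frozen=True)
class ExperimentSet:
    """Result of scanning a directory tree for per-experiment spike-train files."""

    root: Path
    experiments: tuple  # of (name, tuple of Paths)
    skipped: tuple = ()  # files that failed to parse, as (path, reason)

    def __len__(self) -> int:
        return len(self.experiments)


def read_spike_train(path, fs: float) -> SpikeTrain:
    """Read one electrode file.

    The first integer is the recording length in samples; the remaining
    integers are the spike sample indices.  Tokens may be separated by any
    whitespace (spaces, tabs, LF or CRLF newlines).
    """
    path = Path(path)
    tokens = path.read_text().split()
    if not tokens:
        raise SpikeFormatError(f"{path}: empty file")
    values = []
    for tok in tokens:
        try:
            values.append(int(tok))
        except ValueError as exc:
            raise SpikeFormatError(f"{path}: non-integer token {tok!r}") from exc
    n_samples, spikes = values[0], np.asarray(values[1:], dtype=np.int64)
    spikes = np.sort(spikes)
    try:
        return SpikeTrain(n_samples=n_samples, spikes=spikes, fs=fs, label=path.stem)
    except SpikeFormatError as exc:
        raise SpikeFormatError(f"{path}: {exc}") from exc


def write_spike_train(train: SpikeTrain, path) -> Path:
    """Write a train in the same text format; round-trips with :func:`read_spike_train`."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(str(train.n_samples))
        for s in train.spikes:
            fh.write(f"\n{int(s)}")
        fh.write("\n")
    return path


def discover_experiments(root, fs: float, pattern: str = "*.txt") -> ExperimentSet:
    """Scan ``root`` for experiments: one per subdirectory holding >=1 parseable file.

    Files that do not parse are reported in ``skipped`` and the experiment is
    formed from the remaining valid files.  Ordering is lexicographic for both
    experiments and files, so repeated scans are deterministic.
    """
    root = Path(root)
    if not root.is_dir():
        raise NotADirectoryError(f"{root} is not a readable directory")
    experiments = []
    skipped = []
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        good = []
        for f in sorted(sub.glob(pattern)):
            try:
                read_spike_train(f, fs)
            except SpikeFormatError as exc:
                skipped.append((f, str(exc)))
            else:
                good.append(f)
        if good:
            experiments.append((sub.name, tuple(good)))
    return ExperimentSet(root=root, experiments=tuple(experiments), skipped=tuple(skipped))


def load_experiment(paths, fs: float) -> list:
    """Read a list of electrode files into SpikeTrains."""
    return [read_spike_train(p, fs) for p in paths]


def _check_aligned(trains) -> None:
    if not trains:
        return
    n0, fs0 = trains[0].n_samples, trains[0].fs
    for t in trains[1:]:
        if t.n_samples != n0 or t.fs != fs0:
            raise ValueError(
                f"trains are not aligned: {t.label!r} has (n_samples, fs)="
                f"({t.n_samples}, {t.fs}), expected ({n0}, {fs0})"
            )


def filter_active(trains, mfr_min: float = 0.1) -> list:
    """Drop electrodes whose mean firing rate is below ``mfr_min`` spikes/s.

    Electrodes below the floor are treated as silent and carry negligible
    information; the default floor of 0.1 spikes/s matches common practice
    for dissociated cultures on MEAs.  Order is preserved.
    """
    _check_aligned(trains)
    return [t for t in trains if t.mfr >= mfr_min]


def bin_trains(trains, bin_ms: float) -> BinnedActivity:
    """Bin spike trains into a sparse electrodes x bins count matrix.

    ``bin_samples = round(bin_ms * fs / 1000)`` must be at least one sample.
    Bins are half-open; the last (possibly partial) bin is kept so the total
    spike count is conserved.
    """
    if not trains:
        raise ValueError("no trains to bin")
    _check_aligned(trains)
    fs, n_samples = trains[0].fs, trains[0].n_samples
    bin_samples = int(round(bin_ms * fs / 1000.0))
    if bin_samples < 1:
        raise ValueError(
            f"bin_ms={bin_ms} is smaller than one sample period (1/fs={1000.0 / fs} ms)"
        )
    n_bins = math.ceil(n_samples / bin_samples)
    rows, cols, vals = [], [], []
    for e, t in enumerate(trains):
        b, c = np.unique(t.spikes // bin_samples, return_counts=True)
        rows.append(np.full(b.size, e, dtype=np.int64))
        cols.append(b)
        vals.append(c)
    counts = sp.csr_matrix(
        (
            np.concatenate(vals) if vals else [],
            (np.concatenate(rows), np.concatenate(cols)),
        ),
        shape=(len(trains), n_bins),
        dtype=np.int64,
    )
    return BinnedActivity(
        counts=counts,
        bin_samples=bin_samples,
        fs=fs,
        n_samples=n_samples,
        labels=tuple(t.label for t in trains),
    )
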