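"""Graph construction from thresholded connectivity matrices and topology
metrics: degree distributions, clustering coefficient, characteristic path
length, plus the population post-stimulus time histogram (PSTH)."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import ThresholdedCM

__all__ = [
    "to_graph",
    "degree_distributions",
    "clustering_coefficient",
    "characteristic_path_length",
    "PSTH",
    "psth",
]


def to_graph(tcm: ThresholdedCM, directed: bool = True, delay_ms: np.ndarray | None = None):
    """Connectivity graph: one node per electrode, one edge per TCM nonzero.

    In undirected mode the (i, j) / (j, i) entries are merged keeping the
    larger weight.
    """
    n = tcm.tcm.shape[0]
    labels = tcm.labels if len(tcm.labels) == n else tuple(range(n))
    g = nx.DiGraph() if directed else nx.Graph()
    g.add_nodes_from(labels)
    for i, j, w in tcm.edges:
        u, v = labels[i], labels[j]
        attrs = {"weight": w}
        if delay_ms is not None:
            attrs["delay_ms"] = float(delay_ms[i, j])
        if not directed and g.has_edge(u, v):
            if w > g[u][v]["weight"]:
                g[u][v].update(attrs)
        else:
            g.add_edge(u, v, **attrs)
    return g


def degree_distributions(graph: nx.DiGraph) -> pd.DataFrame:
    """Per-node in- and out-degree table (directed graphs)."""
    if not graph.is_directed():
        raise ValueError("degree distributions are defined for directed graphs")
    nodes = list(graph.nodes)
    return pd.DataFrame(
        {
            "in_degree": [graph.in_degree(v) for v in nodes],
            "out_degree": [graph.out_degree(v) for v in nodes],
        },
        index=nodes,
    )


def _undirected_view(graph) -> nx.Graph:
    g = graph.to_undirected() if graph.is_directed() else graph
    g = nx.Graph(g)
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def clustering_coefficient(graph) -> float:
    """Mean Watts-Strogatz local clustering over nodes of degree >= 2.

    The graph is treated as undirected and unweighted; nodes with fewer than
    two neighbours have no defined local clustering and are excluded from
    the mean.  Returns 0.0 if no node qualifies.
    """
    g = _undirected_view(graph)
    local = nx.clustering(g)
    vals = [c for v, c in local.items() if g.degree(v) >= 2]
    return float(np.mean(vals)) if vals else 0.0


def characteristic_path_length(graph) -> float:
    """Mean shortest-path length over connected node pairs (undirected,
    unweighted view; disconnected pairs are excluded)."""
    g = _undirected_view(graph)
    lengths = []
    for src, dist in nx.all_pairs_shortest_path_length(g):
        lengths.extend(d for tgt, d in dist.items() if tgt != src)
    if not lengths:
        raise ValueError("no connected node pair: path length undefined")
    return float(np.mean(lengths))


@dataclass(frozen=True)
class PSTH:
    """Population post-stimulus time histogram.

    ``values[b]`` is the mean spike count in post-stimulus bin ``b`` per
    stimulus per electrode; ``totals`` holds the raw summed counts.
    """

    bin_ms: float
    window_ms: float
    values: np.ndarray
    totals: np.ndarray
    n_stimuli: int
    n_electrodes: int


def psth(trains, stim_samples, window_ms: float, bin_ms: float) -> PSTH:
    """Population PSTH: counts per post-stimulus bin summed over stimuli and
    electrodes, divided by (#stimuli * #electrodes)."""
    stim = np.asarray(stim_samples, dtype=np.int64)
    if stim.size == 0:
        raise ValueError("psth requires at least one stimulus")
    if window_ms <= 0 or bin_ms <= 0:
        raise ValueError("window_ms and bin_ms must be positive")
    trains = list(trains)
    fs = trains[0].fs
    if np.any(stim < 0) or np.any(stim >= trains[0].n_samples):
        raise ValueError("stimulus time outside the recording")
    bin_samples = int(round(bin_ms * fs / 1000.0))
    n_bins = int(round(window_ms / bin_ms))
    window_samples = n_bins * bin_samples
    totals = np.zeros(n_bins, dtype=np.int64)
    for t in trains:
        for s in stim:
            lo, hi = np.searchsorted(t.spikes, [s, s + window_samples])
            rel = (t.spikes[lo:hi] - s) // bin_samples
            np.add.at(totals, rel, 1)
    values = totals / (stim.size * len(trains))
    return PSTH(
        bin_ms=bin_ms,
        window_ms=window_ms,
        values=values,
        totals=totals,
        n_stimuli=int(stim.size),
        n_electrodes=len(trains),
    )
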