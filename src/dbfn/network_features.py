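"""Graph-attribute features of binary functional networks.

Every thresholded network contributes a fixed-order feature block
``[Eg, Eloc(1..n), Ci(1..n)]`` of length ``1 + 2 n_ch`` (65 for a 32-channel
montage):

* global efficiency ``Eg`` — mean inverse shortest-path length over ordered
  node pairs, with ``1/inf = 0`` for disconnected pairs, so it is well defined
  on the (possibly fragmented) thresholded graphs;
* local efficiency ``Eloc(i)`` — global efficiency of the subgraph induced by
  the neighbours of node i (Latora-Marchiori form, node i excluded);
* clustering coefficient ``Ci`` — realized fraction of edges among the
  neighbours of i.

The characteristic path length is computed for diagnostics but never enters
feature vectors: it is finite only on fully connected graphs, which
positional thresholding does not guarantee.

A trial analysed with window length ``t`` seconds produces
``12 * (60 / t)`` networks and hence ``12 * (60 / t) * (1 + 2 n_ch)`` features
(12 x 10 x 65 = 7,800 at t = 6 on 32 channels).  The production path operates
on stacked adjacency arrays with batched boolean matrix products; tests check
it against per-graph oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .connectivity import AdjacencyMatrix

__all__ = [
    "GraphMetrics",
    "TrialFeatures",
    "EdgeFrequencyMap",
    "shortest_paths",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "clustering_coefficient",
    "graph_metrics",
    "network_feature_vector",
    "feature_vectors_batch",
    "assemble_trial_features",
    "edge_frequency_map",
    "retain_frequent_edges",
]


def _as_adj(adj: AdjacencyMatrix | np.ndarray) -> np.ndarray:
    a = adj.values if isinstance(adj, AdjacencyMatrix) else np.asarray(adj)
    return a.astype(bool)


@dataclass(frozen=True)
class GraphMetrics:
    """The four graph attributes of one binary network."""

    Lp: float  # inf when the graph is disconnected
    connected: bool
    Eg: float
    Eloc: np.ndarray  # per node
    Ci: np.ndarray  # per node


@dataclass(frozen=True)
class TrialFeatures:
    """Concatenated feature vector of one trial plus its column layout."""

    vector: np.ndarray
    layout: tuple[str, ...]
    window_s: float
    n_channels: int

    def __post_init__(self) -> None:
        if len(self.layout) != self.vector.size:
            raise ValueError("layout length does not match vector length")


@dataclass(frozen=True)
class EdgeFrequencyMap:
    """Per-edge occurrence counts across a collection of networks."""

    counts: np.ndarray  # (n_ch, n_ch) int, symmetric, zero diagonal
    max_count: int


def hop_distances_batch(adj_stack: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths for a stack of graphs.

    Input ``(m, n, n)`` boolean/0-1 adjacencies (a single ``(n, n)`` matrix is
    accepted); output float distances with ``inf`` for disconnected pairs and
    0 on the diagonal.  Distances grow by breadth-first expansion expressed as
    batched boolean matrix products, so the loop length is the largest graph
    diameter, not the node count.
    """
    A = np.asarray(adj_stack)
    single = A.ndim == 2
    if single:
        A = A[np.newaxis]
    A = A.astype(np.float32)
    m, n, _ = A.shape
    dist = np.full((m, n, n), np.inf)
    idx = np.arange(n)
    dist[:, idx, idx] = 0.0
    reach = np.broadcast_to(np.eye(n, dtype=bool), (m, n, n)).copy()
    for k in range(1, n):
        new_reach = reach | (np.matmul(reach.astype(np.float32), A) > 0)
        fresh = new_reach & ~reach
        if not fresh.any():
            break
        dist[fresh] = float(k)
        reach = new_reach
    return dist[0] if single else dist


def shortest_paths(adj: AdjacencyMatrix | np.ndarray) -> np.ndarray:
    """Pairwise hop-count matrix of one simple undirected binary graph."""
    return hop_distances_batch(_as_adj(adj))


def characteristic_path_length(
    adj: AdjacencyMatrix | np.ndarray,
) -> tuple[float, bool]:
    """Mean shortest path over ordered node pairs, with a connectivity flag.

    Returns ``(inf, False)`` for disconnected graphs, where the mean is
    undefined — the reason this attribute is excluded from feature vectors.
    """
    d = shortest_paths(adj)
    n = d.shape[0]
    if n < 2:
        return 0.0, True
    off = d[~np.eye(n, dtype=bool)]
    if np.isinf(off).any():
        return float("inf"), False
    return float(off.mean()), True


def global_efficiency(adj: AdjacencyMatrix | np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered pairs (1/inf = 0)."""
    a = _as_adj(adj)
    n = a.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    d = hop_distances_batch(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[np.isinf(d)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(
    adj: AdjacencyMatrix | np.ndarray, node: int, include_node: bool = False
) -> float:
    """Efficiency of the subgraph induced by a node's neighbourhood.

    ``include_node=True`` switches to the literal reading in which the node
    itself (and its incident edges) belongs to the subgraph; the default is
    the standard neighbours-only form.  Nodes of degree < 2 score 0.
    """
    a = _as_adj(adj)
    mask = a[node].copy()
    if include_node:
        mask[node] = True
    members = np.flatnonzero(mask)
    if (a[node].sum()) < 2:
        return 0.0
    sub = a[np.ix_(members, members)]
    return global_efficiency(sub)


def clustering_coefficient(adj: AdjacencyMatrix | np.ndarray, node: int) -> float:
    """Fraction of realized edges among a node's neighbours (degree < 2 -> 0)."""
    a = _as_adj(adj)
    nbrs = np.flatnonzero(a[node])
    d = nbrs.size
    if d < 2:
        return 0.0
    e_i = a[np.ix_(nbrs, nbrs)].sum() / 2
    return float(e_i / (d * (d - 1) / 2))


def graph_metrics(adj: AdjacencyMatrix | np.ndarray) -> GraphMetrics:
    """All four attributes of one network (per-graph reference path)."""
    a = _as_adj(adj)
    n = a.shape[0]
    lp, connected = characteristic_path_length(a)
    return GraphMetrics(
        Lp=lp,
        connected=connected,
        Eg=global_efficiency(a),
        Eloc=np.array([local_efficiency(a, i) for i in range(n)]),
        Ci=np.array([clustering_coefficient(a, i) for i in range(n)]),
    )


def network_feature_vector(adj: AdjacencyMatrix | np.ndarray) -> np.ndarray:
    """Feature block ``[Eg, Eloc(1..n), Ci(1..n)]`` of one network."""
    return feature_vectors_batch(_as_adj(adj)[np.newaxis])[0]


def _global_efficiency_batch(adj_stack: np.ndarray) -> np.ndarray:
    m, n, _ = adj_stack.shape
    d = hop_distances_batch(adj_stack)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[np.isinf(d)] = 0.0
    idx = np.arange(n)
    inv[:, idx, idx] = 0.0
    return inv.sum(axis=(1, 2)) / (n * (n - 1))


def feature_vectors_batch(
    adj_stack: np.ndarray, chunk: int = 2048
) -> np.ndarray:
    """Feature blocks for a stack of networks: ``(m, 1 + 2 n_ch)``.

    Identical ordering to :func:`network_feature_vector`; large stacks are
    processed in chunks to bound memory.
    """
    A = np.asarray(adj_stack).astype(bool)
    if A.ndim == 2:
        A = A[np.newaxis]
    m, n, _ = A.shape
    out = np.empty((m, 1 + 2 * n))
    for start in range(0, m, chunk):
        a = A[start:start + chunk]
        b = a.shape[0]
        out[start:start + b, 0] = _global_efficiency_batch(a)

        # clustering: edges among neighbours of i = (A^3)_ii / 2
        af = a.astype(np.float64)
        tri = np.einsum("mij,mjk,mki->mi", af, af, af)  # 2 * E_i per node
        deg = af.sum(axis=2)
        denom = deg * (deg - 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ci = np.where(denom > 0, tri / denom, 0.0)
        out[start:start + b, 1 + n:] = ci

        # local efficiency: one masked batched APSP per node index
        eloc = np.zeros((b, n))
        for i in range(n):
            mask = a[:, i, :]  # (b, n) neighbour indicators
            deg_i = mask.sum(axis=1)
            active = deg_i >= 2
            if not active.any():
                continue
            sub = a[active] & mask[active, :, None] & mask[active, None, :]
            d = hop_distances_batch(sub)
            with np.errstate(divide="ignore"):
                inv = 1.0 / d
            inv[np.isinf(d)] = 0.0
            idx = np.arange(n)
            inv[:, idx, idx] = 0.0
            pair_mask = mask[active, :, None] & mask[active, None, :]
            sums = np.where(pair_mask, inv, 0.0).sum(axis=(1, 2))
            da = deg_i[active].astype(float)
            eloc[active, i] = sums / (da * (da - 1.0))
        out[start:start + b, 1:1 + n] = eloc
    return out


def assemble_trial_features(
    networks: np.ndarray,
    window_s: float,
    signal_names: Sequence[str] | None = None,
    channel_names: Sequence[str] | None = None,
    duration_s: float = 60.0,
) -> TrialFeatures:
    """Concatenate one trial's per-network feature blocks in layout order.

    ``networks`` is a ``(12 * duration_s / window_s, n_ch, n_ch)`` adjacency
    stack ordered signal-major then window-minor (all windows of difference
    signal 0, then of signal 1, ...).  The result is the flat feature vector
    of length ``12 * (duration_s / window_s) * (1 + 2 n_ch)`` together with a
    column-name layout ``"<signal>|w<window>|<attribute>"``.
    """
    networks = np.asarray(networks)
    if networks.ndim != 3 or networks.shape[1] != networks.shape[2]:
        raise ValueError("networks must be a (m, n_ch, n_ch) stack")
    n_windows = duration_s / window_s
    if abs(n_windows - round(n_windows)) > 1e-9:
        raise ValueError(f"{duration_s} s not divisible by {window_s} s windows")
    n_windows = int(round(n_windows))
    n_signals = 12 if signal_names is None else len(signal_names)
    expected = n_signals * n_windows
    if networks.shape[0] != expected:
        raise ValueError(
            f"expected {expected} networks ({n_signals} signals x {n_windows} "
            f"windows), got {networks.shape[0]}"
        )
    n_ch = networks.shape[1]
    if signal_names is None:
        signal_names = [f"sig{i:02d}" for i in range(n_signals)]
    if channel_names is None:
        channel_names = [f"ch{i:02d}" for i in range(n_ch)]

    blocks = feature_vectors_batch(networks)
    attrs = (["Eg"] + [f"Eloc[{c}]" for c in channel_names]
             + [f"Ci[{c}]" for c in channel_names])
    layout = tuple(
        f"{sig}|w{w:02d}|{attr}"
        for sig in signal_names
        for w in range(n_windows)
        for attr in attrs
    )
    return TrialFeatures(blocks.ravel(), layout, window_s, n_ch)


def edge_frequency_map(networks: np.ndarray) -> EdgeFrequencyMap:
    """Per-edge occurrence counts across a stack of same-size networks."""
    networks = np.asarray(networks)
    if networks.ndim == 2:
        networks = networks[np.newaxis]
    if networks.shape[0] == 0:
        raise ValueError("cannot aggregate an empty network list")
    counts = networks.astype(np.int64).sum(axis=0)
    np.fill_diagonal(counts, 0)
    return EdgeFrequencyMap(counts, int(networks.shape[0]))


def edge_list_lines(
    matrix: AdjacencyMatrix | EdgeFrequencyMap,
    channel_names: Sequence[str] | None = None,
) -> list[str]:
    """Plain-text edge list of an adjacency or edge-frequency matrix.

    One line per retained undirected edge, ``"<a>\t<b>"`` for adjacencies and
    ``"<a>\t<b>\t<count>"`` for frequency maps — handy for external graph
    tooling.
    """
    values = matrix.counts if isinstance(matrix, EdgeFrequencyMap) \
        else matrix.values
    n = values.shape[0]
    names = channel_names or [f"ch{i:02d}" for i in range(n)]
    lines = []
    for i in range(n):
        for j in range(i + 1, n):
            if values[i, j]:
                if isinstance(matrix, EdgeFrequencyMap):
                    lines.append(f"{names[i]}\t{names[j]}\t{int(values[i, j])}")
                else:
                    lines.append(f"{names[i]}\t{names[j]}")
    return lines


def retain_frequent_edges(fmap: EdgeFrequencyMap, p: float) -> AdjacencyMatrix:
    """Keep edges occurring in strictly more than ``p * max_count`` networks.

    This is the aggregation behind the dense "summary" network maps: at t = 6
    a trial yields 120 networks, so p = 0.8 keeps edges present in > 96.
    """
    cutoff = p * fmap.max_count
    adj = (fmap.counts > cutoff).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return AdjacencyMatrix(adj, p, float(cutoff))
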