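"""Mutual-information functional connectivity and positional-threshold graphs.

Dependence between two channel series x, y is measured by the histogram
estimate of mutual information, MI = H_x + H_y - H_xy in nats, with marginal
and joint entropies from equal-width histograms (8 bins per axis by default;
128-sample windows make finer binning unstable).  One symmetric MI matrix is
computed per time window of each band-difference signal; its diagonal carries
the per-channel marginal entropy (the self-MI).

Binarization uses a positional (proportional-rank) threshold computed per
matrix rather than a global cutoff, because absolute MI levels differ strongly
between individuals: all n^2 entries (diagonal included) are sorted ascending
and the element at 1-based rank floor(q * n^2) is the threshold — q = 0.3 on a
32 x 32 matrix gives rank 307 of 1024.  Entries strictly above the threshold
become edges; the diagonal is then zeroed so graphs are simple.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "AdjacencyMatrix",
    "marginal_entropy",
    "mutual_information",
    "connectivity_matrix",
    "positional_threshold",
    "mi_matrix_stack",
    "threshold_stack",
    "DEFAULT_N_BINS",
]

DEFAULT_N_BINS = 8


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric per-window MI matrix; diagonal = per-channel entropy."""

    values: np.ndarray  # (n_ch, n_ch), nats
    window_index: int = 0
    signal_id: str = ""

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Binary simple graph from positional thresholding of an MI matrix."""

    values: np.ndarray  # (n_ch, n_ch) in {0, 1}, zero diagonal
    threshold_position: float
    threshold_value: float

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def _digitize_rows(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bin index per sample, per row, over each row's [min, max].

    Constant rows land entirely in bin 0.
    """
    lo = x.min(axis=-1, keepdims=True)
    hi = x.max(axis=-1, keepdims=True)
    span = hi - lo
    span[span == 0.0] = 1.0
    idx = np.floor((x - lo) / span * n_bins).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def marginal_entropy(x: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> float:
    """Histogram entropy H = -sum p ln p (nats) over an equal-width binning.

    Bins span [min(x), max(x)]; a constant vector has zero entropy.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot estimate entropy of an empty sample")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    counts = np.bincount(_digitize_rows(x[np.newaxis, :], n_bins)[0],
                         minlength=n_bins)
    # sorted summation matches the joint-entropy path bit-for-bit, so
    # MI(x, constant) collapses to exactly 0
    p = np.sort(counts[counts > 0]) / x.size
    return float(-(p * np.log(p)).sum())


def mutual_information(
    x: np.ndarray, y: np.ndarray, n_bins: int = DEFAULT_N_BINS
) -> float:
    """Histogram MI(x, y) = H_x + H_y - H_xy in nats, clamped to >= 0.

    The joint entropy comes from the n_bins x n_bins joint histogram on the
    product of the two marginal equal-width binnings.  Symmetric in (x, y);
    MI(x, x) = H_x; MI with a constant is 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    dx = _digitize_rows(x[np.newaxis, :], n_bins)[0]
    dy = _digitize_rows(y[np.newaxis, :], n_bins)[0]
    joint = np.bincount(dx * n_bins + dy, minlength=n_bins * n_bins)
    n = x.size
    # sorted summation keeps MI(x, y) == MI(y, x) bit-exact
    pj = np.sort(joint[joint > 0]) / n
    h_xy = -(pj * np.log(pj)).sum()
    return max(0.0, marginal_entropy(x, n_bins) + marginal_entropy(y, n_bins)
               - float(h_xy))


def mi_matrix_stack(
    windows: np.ndarray, n_bins: int = DEFAULT_N_BINS
) -> np.ndarray:
    """All-pairs MI matrices for a stack of windows, vectorized.

    Parameters
    ----------
    windows
        Array of shape ``(n_windows, n_channels, n_samples)`` (a single
        ``(n_channels, n_samples)`` window is also accepted).
    n_bins
        Histogram bins per axis.

    Returns
    -------
    ndarray of shape (n_windows, n_channels, n_channels): symmetric MI in
    nats with marginal entropies on the diagonal.

    Notes
    -----
    Joint histograms for all channel pairs of one window are obtained in one
    matrix product of the stacked one-hot bin indicators: with
    ``B[(c, b), s] = 1`` iff sample s of channel c falls in bin b,
    ``B @ B.T`` holds every pairwise n_bins x n_bins joint histogram as a
    block.  This is algebraically identical to the per-pair histogram loop.
    """
    windows = np.asarray(windows, dtype=float)
    single = windows.ndim == 2
    if single:
        windows = windows[np.newaxis]
    n_win, n_ch, n_samp = windows.shape
    if n_ch < 2:
        raise ValueError("need at least 2 channels")
    if n_samp < 2:
        raise ValueError("need at least 2 samples per window")

    out = np.empty((n_win, n_ch, n_ch))
    for w in range(n_win):
        d = _digitize_rows(windows[w], n_bins)  # (n_ch, n_samp)
        onehot = np.zeros((n_ch * n_bins, n_samp), dtype=np.float32)
        onehot[d + np.arange(n_ch)[:, None] * n_bins,
               np.arange(n_samp)[None, :]] = 1.0
        joint = (onehot @ onehot.T).reshape(n_ch, n_bins, n_ch, n_bins)
        joint = joint.transpose(0, 2, 1, 3)  # (n_ch, n_ch, n_bins, n_bins)
        p = joint.astype(np.float64) / n_samp  # counts are exact in float32
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        h_joint = -plogp.sum(axis=(2, 3))  # H_xy for every pair; diag = H_x
        h_marg = np.diagonal(h_joint)
        mi = h_marg[:, None] + h_marg[None, :] - h_joint
        mi = 0.5 * (mi + mi.T)  # bin-summation order must not break symmetry
        np.maximum(mi, 0.0, out=mi)
        np.fill_diagonal(mi, h_marg)
        out[w] = mi
    return out[0] if single else out


def connectivity_matrix(
    window: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    window_index: int = 0,
    signal_id: str = "",
) -> ConnectivityMatrix:
    """MI connectivity matrix of one channels x samples window."""
    return ConnectivityMatrix(
        mi_matrix_stack(window, n_bins), window_index, signal_id
    )


def _threshold_value(flat_sorted: np.ndarray, q: float) -> float:
    """Element at 1-based ascending rank floor(q * n), clamped to >= 1."""
    n = flat_sorted.size
    rank = max(1, int(np.floor(q * n)))
    return float(flat_sorted[rank - 1])


def positional_threshold(
    cm: ConnectivityMatrix | np.ndarray, q: float = 0.3
) -> AdjacencyMatrix:
    """Binarize an MI matrix at the value ranked q-th by position.

    All n^2 entries (diagonal included) are sorted ascending; the threshold is
    the element at 1-based index floor(q * n^2).  Entries strictly greater
    than the threshold become 1 (ties are discarded, never retained); the
    diagonal is forced to 0.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"threshold position q must be in (0, 1), got {q}")
    values = cm.values if isinstance(cm, ConnectivityMatrix) else np.asarray(cm)
    thr = _threshold_value(np.sort(values, axis=None), q)
    adj = (values > thr).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return AdjacencyMatrix(adj, q, thr)


def threshold_stack(mi_stack: np.ndarray, q: float = 0.3) -> np.ndarray:
    """Positional-threshold binarization of a stack of MI matrices.

    Vectorized equivalent of applying :func:`positional_threshold` to each
    ``(n_ch, n_ch)`` slice; returns int8 adjacencies with zero diagonals.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"threshold position q must be in (0, 1), got {q}")
    mi_stack = np.asarray(mi_stack)
    single = mi_stack.ndim == 2
    if single:
        mi_stack = mi_stack[np.newaxis]
    n_win, n_ch, _ = mi_stack.shape
    flat = np.sort(mi_stack.reshape(n_win, n_ch * n_ch), axis=1)
    rank = max(1, int(np.floor(q * n_ch * n_ch)))
    thr = flat[:, rank - 1]
    adj = (mi_stack > thr[:, None, None]).astype(np.int8)
    idx = np.arange(n_ch)
    adj[:, idx, idx] = 0
    return adj[0] if single else adj
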