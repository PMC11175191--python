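"""Functional-connectivity channel graphs for spectral graph filtering.

Edges are absolute Pearson correlations between channel time series, pooled
over the *training* trials only, then sparsified by a threshold tau. From the
weighted adjacency W the combinatorial Laplacian L = D - W is formed, its full
symmetric eigendecomposition L = U diag(lambda) U^T defines the graph Fourier
basis, and an affine rescaling L_scaled = 2 L / lambda_max - I maps the
spectrum into [-1, 1] so that Chebyshev polynomials of L_scaled are well
conditioned.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass

import numpy as np

from .data import EpochSet

_EIG_TOL = 1e-8


@dataclass
class ChannelGraph:
    """Adjacency, degree, Laplacian and spectral basis over EEG channels."""

    W: np.ndarray            # symmetric nonnegative adjacency, zero diagonal
    D: np.ndarray            # diagonal degree matrix, D_ii = sum_j W_ij
    L: np.ndarray            # combinatorial Laplacian D - W
    U: np.ndarray            # orthonormal eigenvectors, columns
    lam: np.ndarray          # eigenvalues, ascending
    L_scaled: np.ndarray     # 2 L / lambda_max - I
    channel_names: list[str]

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    @property
    def lambda_max(self) -> float:
        return float(self.lam[-1])


def correlation_adjacency(es: EpochSet) -> np.ndarray:
    """Absolute Pearson correlation between channels, pooled over trials.

    Trials are concatenated along time before correlating, the field's usual
    convention for a single static connectivity estimate. The diagonal is
    forced to zero so self-loops never enter the Laplacian.
    """
    if es.n_channels < 2:
        raise ValueError("need at least 2 channels to build a graph")
    # (channels, trials*samples)
    flat = es.epochs.transpose(1, 0, 2).reshape(es.n_channels, -1)
    std = flat.std(axis=1)
    dead = np.flatnonzero(std == 0)
    if dead.size:
        names = ", ".join(es.channel_names[i] for i in dead)
        raise ValueError(f"zero-variance channel(s): {names}")
    C = np.abs(np.corrcoef(flat))
    C = (C + C.T) / 2.0  # exact symmetry (corrcoef is symmetric only to ulp)
    np.fill_diagonal(C, 0.0)
    return C


def correlation_adjacency_per_epoch(es: EpochSet) -> np.ndarray:
    """Alternative pooling: average the per-trial |r| matrices."""
    if es.n_channels < 2:
        raise ValueError("need at least 2 channels to build a graph")
    acc = np.zeros((es.n_channels, es.n_channels))
    for t in range(es.n_trials):
        x = es.epochs[t]
        std = x.std(axis=1)
        dead = np.flatnonzero(std == 0)
        if dead.size:
            names = ", ".join(es.channel_names[i] for i in dead)
            raise ValueError(f"zero-variance channel(s) in trial {t}: {names}")
        acc += np.abs(np.corrcoef(x))
    C = acc / es.n_trials
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 0.0)
    return C


def threshold_sparsify(C: np.ndarray, tau: float) -> np.ndarray:
    """Keep entries >= tau, zero the rest (symmetric in, symmetric out)."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau={tau} outside [0, 1]")
    if not np.allclose(C, C.T):
        raise ValueError("connectivity matrix must be symmetric")
    W = np.where(C >= tau, C, 0.0)
    np.fill_diagonal(W, 0.0)
    return W


def degree_matrix(W: np.ndarray) -> np.ndarray:
    """Diagonal matrix of vertex degrees (row sums of W)."""
    W = np.asarray(W)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if np.any(W < 0):
        raise ValueError("adjacency weights must be nonnegative")
    return np.diag(W.sum(axis=1))


def laplacian(W: np.ndarray) -> np.ndarray:
    """Combinatorial graph Laplacian L = D - W."""
    if not np.allclose(W, W.T):
        raise ValueError("adjacency must be symmetric")
    return degree_matrix(W) - W


def spectral_decompose(L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full symmetric eigendecomposition; eigenvalues ascending.

    Returns ``(U, lam)`` with orthonormal eigenvector columns. For a connected
    graph lam[0] == 0 (within tolerance); extra zero eigenvalues indicate
    disconnected components and are reported as a warning.
    """
    lam, U = np.linalg.eigh(L)
    n_zero = int(np.sum(np.abs(lam) < 1e-10))
    if n_zero > 1:
        warnings.warn(
            f"graph has {n_zero} connected components (multiple zero "
            "eigenvalues); consider lowering the sparsification threshold",
            stacklevel=2)
    return U, lam


def scale_laplacian(L: np.ndarray, lambda_max: float) -> np.ndarray:
    """Affine rescale so the spectrum lies in [-1, 1]: 2 L / lambda_max - I."""
    if lambda_max <= 0:
        raise ValueError(
            "lambda_max must be positive; an all-zero Laplacian means the "
            "thresholded graph has no edges — lower the threshold tau")
    n = L.shape[0]
    return 2.0 * L / lambda_max - np.eye(n)


def gft(q: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Graph Fourier transform: project a vertex signal onto the basis."""
    q = np.asarray(q)
    if q.shape[0] != U.shape[0]:
        raise ValueError("signal length must equal graph order")
    return U.T @ q


def igft(qhat: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Inverse graph Fourier transform."""
    qhat = np.asarray(qhat)
    if qhat.shape[0] != U.shape[0]:
        raise ValueError("spectrum length must equal graph order")
    return U @ qhat


def build_graph(train: EpochSet, tau: float = 0.3,
                pooling: str = "concatenate") -> ChannelGraph:
    """Build the full ChannelGraph from training trials.

    ``pooling`` selects how trials are combined before correlating:
    "concatenate" (default) or "per_epoch" averaging.
    """
    if pooling == "concatenate":
        C = correlation_adjacency(train)
    elif pooling == "per_epoch":
        C = correlation_adjacency_per_epoch(train)
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    W = threshold_sparsify(C, tau)
    return graph_from_adjacency(W, list(train.channel_names))


def graph_from_adjacency(W: np.ndarray,
                         channel_names: list[str] | None = None
                         ) -> ChannelGraph:
    """Assemble degree/Laplacian/spectral pieces from a given adjacency."""
    W = np.asarray(W, dtype=np.float64)
    D = degree_matrix(W)
    L = laplacian(W)
    U, lam = spectral_decompose(L)
    if lam[-1] <= _EIG_TOL:
        raise ValueError(
            "graph has no edges (lambda_max == 0); lower the threshold tau")
    L_scaled = scale_laplacian(L, lam[-1])
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(W.shape[0])]
    return ChannelGraph(W=W, D=D, L=L, U=U, lam=lam, L_scaled=L_scaled,
                        channel_names=channel_names)


def save_adjacency(graph: ChannelGraph, path: str) -> None:
    """Write the adjacency as dense CSV with a channel-name header."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(graph.channel_names)
        for row in graph.W:
            writer.writerow([f"{v:.10g}" for v in row])


def load_adjacency(path: str) -> ChannelGraph:
    """Rebuild a ChannelGraph from :func:`save_adjacency` output."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    names = rows[0]
    W = np.array([[float(v) for v in row] for row in rows[1:]])
    return graph_from_adjacency(W, names)
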