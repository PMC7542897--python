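"""Supervised adjacency graph and its Laplacian.

The graph penalty Tr((H beta)^T Z (H beta)) asks that samples connected in a
similarity graph receive similar network outputs.  Here the graph is built
from the *training labels*: two samples are adjacent iff they carry the same
label, which encodes "similar samples should have similar predictions" in
the simplest supervised form.  Z = D - W is the combinatorial graph
Laplacian, whose quadratic form satisfies

    Tr(T^T Z T) = 1/2 sum_ij W_ij ||t_i - t_j||^2  >=  0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GraphLaplacian",
    "label_similarity",
    "heat_kernel_similarity",
    "laplacian",
]


@dataclass(frozen=True)
class GraphLaplacian:
    """Similarity matrix W, degree vector, and Laplacian Z = diag(degree) - W."""

    W: np.ndarray
    Z: np.ndarray
    degree: np.ndarray


def label_similarity(
    labels: np.ndarray,
    *,
    normalize: bool = False,
) -> np.ndarray:
    """Binary same-label adjacency with zero diagonal.

    W_ij = 1 when labels[i] == labels[j] and i != j, else 0.  With
    ``normalize=True`` each edge weight is divided by the size of its class,
    so every class contributes a penalty of comparable total weight
    regardless of how many members it has (useful under class imbalance;
    off by default).
    """
    labels = np.asarray(labels)
    if labels.ndim != 1 or labels.size == 0:
        raise ValueError("labels must be a non-empty 1-D array")
    same = (labels[:, None] == labels[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)
    if normalize:
        _, inverse, counts = np.unique(labels, return_inverse=True, return_counts=True)
        same /= counts[inverse][:, None].astype(float)
        same = (same + same.T) / 2.0
    return same


def heat_kernel_similarity(X: np.ndarray, bandwidth: float = 1.0) -> np.ndarray:
    """Feature-based heat-kernel weights W_ij = exp(-||x_i - x_j||^2 / bandwidth^2).

    An unsupervised alternative to the label graph (diagonal zeroed); not
    used by default.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    sq = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    W = np.exp(-sq / bandwidth**2)
    np.fill_diagonal(W, 0.0)
    return W


def laplacian(W: np.ndarray) -> GraphLaplacian:
    """Combinatorial Laplacian Z = diag(rowsum(W)) - W of a similarity matrix.

    Requires W symmetric with nonnegative entries; every row of Z sums to
    zero and Z is positive semidefinite, so the graph penalty can never
    reward disagreement.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("W must be symmetric")
    if np.any(W < 0):
        raise ValueError("W must be nonnegative")
    degree = W.sum(axis=1)
    Z = np.diag(degree) - W
    return GraphLaplacian(W=W, Z=Z, degree=degree)
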