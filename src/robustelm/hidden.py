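"""Random single-hidden-layer feature map.

An extreme learning machine (ELM) never trains its first layer: the input
weights ``A`` (one row per hidden node) and biases ``b`` are drawn once at
random and frozen, and only the linear read-out on top of the resulting
nonlinear features is fitted.  This module owns that frozen map: its
construction, and the evaluation of the hidden output matrix

    H[i, j] = g(a_j . x_i + b_j),

where ``g`` is the sigmoid.  Every row of ``H`` is the hidden representation
h(x_i) of one sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HiddenLayerMap", "init_hidden_map", "hidden_output", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable elementwise logistic function 1 / (1 + exp(-z)).

    Branches on the sign of the argument so that ``exp`` is only ever
    evaluated on non-positive values, avoiding overflow for large ``|z|``.
    """
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass(frozen=True)
class HiddenLayerMap:
    """Frozen random first layer of a single-hidden-layer network.

    Attributes
    ----------
    input_weights : ndarray of shape (n_hidden, n_features)
        Random input weight matrix ``A``; row ``j`` holds the weights of
        hidden node ``j``.
    biases : ndarray of shape (n_hidden,)
        Random biases, one per hidden node.
    activation : str
        Name of the activation; only ``"sigmoid"`` is supported.
    seed : int
        Seed used to draw the weights; reconstruction with the same
        ``(n_features, n_hidden, seed)`` is bit-for-bit identical.
    """

    input_weights: np.ndarray
    biases: np.ndarray
    activation: str = "sigmoid"
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.input_weights, dtype=float)
        b = np.asarray(self.biases, dtype=float)
        if w.ndim != 2:
            raise ValueError("input_weights must be a 2-D array")
        if b.shape != (w.shape[0],):
            raise ValueError(
                f"biases must have length {w.shape[0]}, got {b.shape}"
            )
        if self.activation != "sigmoid":
            raise ValueError(f"unsupported activation {self.activation!r}")
        w.setflags(write=False)
        b.setflags(write=False)
        object.__setattr__(self, "input_weights", w)
        object.__setattr__(self, "biases", b)

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.input_weights.shape[1]


def init_hidden_map(n_features: int, n_hidden: int, seed: int = 0) -> HiddenLayerMap:
    """Draw a fresh random hidden layer.

    Weights and biases are i.i.d. uniform on [-1, 1] — the standard ELM
    choice; any non-degenerate continuous distribution would satisfy the
    theory, uniform keeps every hidden node pre-activation at a comparable
    scale.  Deterministic given ``seed``.
    """
    if n_features < 1 or n_hidden < 1:
        raise ValueError(
            f"n_features and n_hidden must be positive, got "
            f"({n_features}, {n_hidden})"
        )
    rng = np.random.default_rng(seed)
    weights = rng.uniform(-1.0, 1.0, size=(n_hidden, n_features))
    biases = rng.uniform(-1.0, 1.0, size=n_hidden)
    return HiddenLayerMap(weights, biases, activation="sigmoid", seed=seed)


def hidden_output(hidden: HiddenLayerMap, X: np.ndarray) -> np.ndarray:
    """Hidden layer output matrix H of shape (n_samples, n_hidden).

    Row ``i`` is h(x_i); entries lie strictly inside (0, 1) for finite
    inputs, and rows are computed independently of each other.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != hidden.n_features:
        raise ValueError(
            f"X has {X.shape[1]} features, hidden map expects "
            f"{hidden.n_features}"
        )
    return sigmoid(X @ hidden.input_weights.T + hidden.biases)
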