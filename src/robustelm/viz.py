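"""Optional plotting helpers (require matplotlib)."""

from __future__ import annotations

import numpy as np

from .model import TrainedELM, decision_scores, predict


def plot_decision_boundary(model: TrainedELM, X, y, ax=None, resolution=200,
                           margin=1.0):
    """Scatter a 2-D dataset and shade the model's predicted regions.

    Only for two-feature problems (e.g. the synthetic Gaussian benchmark).
    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    X = np.asarray(X, dtype=float)
    if X.shape[1] != 2:
        raise ValueError("decision-boundary plots require exactly 2 features")
    if ax is None:
        _, ax = plt.subplots()
    x0 = np.linspace(X[:, 0].min() - margin, X[:, 0].max() + margin, resolution)
    x1 = np.linspace(X[:, 1].min() - margin, X[:, 1].max() + margin, resolution)
    G0, G1 = np.meshgrid(x0, x1)
    grid = np.column_stack([G0.ravel(), G1.ravel()])
    scores = decision_scores(model, grid)
    region = np.argmax(scores, axis=1).reshape(G0.shape)
    ax.contourf(G0, G1, region, alpha=0.2, levels=np.arange(scores.shape[1] + 1) - 0.5)
    codes = {c: k for k, c in enumerate(model.classes)}
    y_codes = np.asarray([codes.get(v, -1) for v in np.asarray(y).tolist()])
    ax.scatter(X[:, 0], X[:, 1], c=y_codes, s=8, edgecolors="none")
    ax.set_xlabel("feature 1")
    ax.set_ylabel("feature 2")
    return ax
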