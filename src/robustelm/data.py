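"""Datasets and synthetic generators.

The generators reproduce a classic two-class robustness benchmark: two
isotropic Gaussian clouds in the plane, class 1 centred at [-2, -2] and
class 2 at [2, 2], both with identity covariance, 300 samples per class.
Label noise is injected by flipping the labels of randomly chosen class-2
points so they masquerade as class 1 — the features are untouched, only the
supervision is corrupted.  A square-loss learner chases those mislabelled
points; a bounded robust loss should shrug them off.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Dataset",
    "SyntheticSpec",
    "one_hot",
    "gaussian_classes",
    "inject_label_noise",
]


@dataclass(frozen=True)
class Dataset:
    """Feature matrix with integer-coded labels and a class codebook.

    ``y`` holds integer codes into ``classes`` (the codebook, fixed order);
    ``targets()`` yields the one-hot matrix used as regression targets.
    """

    X: np.ndarray
    y: np.ndarray
    classes: tuple
    flipped_indices: tuple = ()

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        y = np.asarray(self.y, dtype=int)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y must have the same number of rows")
        if y.size and (y.min() < 0 or y.max() >= len(self.classes)):
            raise ValueError("label codes out of codebook range")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "classes", tuple(self.classes))

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def targets(self, coding: str = "zero_one") -> np.ndarray:
        return one_hot(self.y, self.n_classes, coding=coding)

    def labels(self) -> np.ndarray:
        """Decode integer codes back to the original class names."""
        return np.asarray(self.classes, dtype=object)[self.y]


def one_hot(y: np.ndarray, n_classes: int, coding: str = "zero_one") -> np.ndarray:
    """One-hot target matrix T (n_samples x n_classes).

    ``coding="zero_one"`` uses 0/1 targets (matching the (0, 1) range of the
    sigmoid hidden layer); ``coding="plus_minus"`` uses -1/+1.
    """
    y = np.asarray(y, dtype=int)
    if coding == "zero_one":
        off, on = 0.0, 1.0
    elif coding == "plus_minus":
        off, on = -1.0, 1.0
    else:
        raise ValueError(f"unknown coding {coding!r}")
    T = np.full((y.size, n_classes), off)
    T[np.arange(y.size), y] = on
    return T


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a Gaussian-mixture classification benchmark.

    Defaults are the two-class planar setup: 300 points per class from
    N([-2,-2], I) and N([2,2], I), no label noise.
    """

    n_per_class: tuple = (300, 300)
    means: tuple = ((-2.0, -2.0), (2.0, 2.0))
    covariances: tuple | None = None  # None -> identity for every class
    n_noise: int = 0
    noise_from: int = 1
    noise_to: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.means) != len(self.n_per_class):
            raise ValueError("means and n_per_class must have equal length")
        if self.covariances is not None and len(self.covariances) != len(self.means):
            raise ValueError("covariances and means must have equal length")
        if self.n_noise > self.n_per_class[self.noise_from]:
            raise ValueError("n_noise exceeds the size of the source class")

    def resolved_covariances(self) -> list[np.ndarray]:
        dim = len(self.means[0])
        if self.covariances is None:
            return [np.eye(dim) for _ in self.means]
        return [np.asarray(c, dtype=float) for c in self.covariances]


def gaussian_classes(spec: SyntheticSpec) -> Dataset:
    """Draw one dataset from the Gaussian class-conditional spec.

    Class ``k`` contributes ``spec.n_per_class[k]`` points from
    N(mean_k, cov_k); samples are concatenated class by class.
    Deterministic given ``spec.seed``.  Raises for a covariance matrix that
    is not symmetric positive semidefinite.
    """
    rng = np.random.default_rng(spec.seed)
    covs = spec.resolved_covariances()
    for cov in covs:
        if not np.allclose(cov, cov.T, atol=1e-12):
            raise ValueError("covariance matrices must be symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < -1e-10:
            raise ValueError("covariance matrices must be positive semidefinite")
    blocks, labels = [], []
    for k, (n_k, mean, cov) in enumerate(zip(spec.n_per_class, spec.means, covs)):
        blocks.append(rng.multivariate_normal(np.asarray(mean, float), cov, size=n_k,
                                              method="svd"))
        labels.append(np.full(n_k, k, dtype=int))
    X = np.vstack(blocks)
    y = np.concatenate(labels)
    classes = tuple(f"class{k + 1}" for k in range(len(spec.means)))
    ds = Dataset(X=X, y=y, classes=classes)
    if spec.n_noise:
        ds = inject_label_noise(ds, spec.n_noise, spec.noise_from, spec.noise_to,
                                seed=spec.seed)
    return ds


def inject_label_noise(
    dataset: Dataset,
    n_noise: int,
    from_class: int,
    to_class: int,
    seed: int = 0,
) -> Dataset:
    """Flip the labels of ``n_noise`` random members of ``from_class``.

    Features are left bitwise untouched; only labels change, and the flipped
    row indices are recorded on the returned dataset for diagnostics.
    """
    if n_noise == 0:
        return dataset
    members = np.flatnonzero(dataset.y == from_class)
    if n_noise > members.size:
        raise ValueError(
            f"cannot flip {n_noise} labels: class {from_class} has only "
            f"{members.size} members"
        )
    rng = np.random.default_rng(seed)
    flipped = rng.choice(members, size=n_noise, replace=False)
    y = dataset.y.copy()
    y[flipped] = to_class
    return Dataset(
        X=dataset.X,
        y=y,
        classes=dataset.classes,
        flipped_indices=tuple(int(i) for i in np.sort(flipped)),
    )
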