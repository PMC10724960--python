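"""Wrapper fitness: leave-one-out cross-validated accuracy (0-100 scale).

Accuracy is 100 * CC / N where CC counts correctly classified held-out
samples. The search loop uses a deterministic k-NN surrogate (Euclidean
distance on the masked genes, majority vote); the CNN classifier is reserved
for final evaluation. Tie rules are fixed so repeated calls are bitwise
identical: equal vote counts go to the lowest class code, equal neighbor
distances to the lowest sample index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .datasets_io import ExpressionDataset
from .errors import ValidationError
from .mrmr import GenePool


@dataclass(frozen=True)
class FitnessResult:
    """Accuracy on the 0-100 scale with its integer provenance (CC of N)."""

    accuracy: float
    CC: int
    N: int
    per_sample_pred: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "per_sample_pred", np.asarray(self.per_sample_pred, dtype=int)
        )
        if self.CC > self.N:
            raise ValidationError("CC cannot exceed N")
        if self.accuracy != 100.0 * self.CC / self.N:
            raise ValidationError("accuracy must equal 100*CC/N exactly")


def knn_predict(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    k: int = 1,
) -> np.ndarray:
    """Euclidean k-NN with deterministic ties (lowest index, lowest class)."""
    train_x = np.atleast_2d(np.asarray(train_x, dtype=float))
    test_x = np.atleast_2d(np.asarray(test_x, dtype=float))
    train_y = np.asarray(train_y, dtype=int)
    if not (1 <= k <= train_x.shape[0]):
        raise ValidationError(f"k={k} out of range [1, {train_x.shape[0]}]")
    dist = cdist(test_x, train_x)
    # stable sort: equal distances resolve to the lowest training index
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    votes = train_y[order]
    n_classes = int(train_y.max()) + 1
    preds = np.array(
        [np.argmax(np.bincount(row, minlength=n_classes)) for row in votes]
    )
    return preds


def loocv_fitness(
    dataset: ExpressionDataset, mask: np.ndarray, k: int = 1
) -> FitnessResult:
    """LOOCV accuracy of the k-NN surrogate on the masked genes.

    Vectorized: one all-pairs distance matrix with the diagonal (the held-out
    sample itself) excluded from every neighborhood.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise ValidationError("mask must select at least one gene")
    if dataset.n_samples < 2:
        raise ValidationError("LOOCV needs at least 2 samples")
    x = dataset.matrix[:, mask]
    y = dataset.labels
    n = dataset.n_samples
    dist = cdist(x, x)
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    n_classes = dataset.n_classes
    preds = np.array(
        [np.argmax(np.bincount(y[row], minlength=n_classes)) for row in order]
    )
    cc = int(np.sum(preds == y))
    return FitnessResult(accuracy=100.0 * cc / n, CC=cc, N=n, per_sample_pred=preds)


def make_knn_fitness(dataset: ExpressionDataset, pool: GenePool, k: int = 1):
    """Build the optimizer's fitness function over pool-local masks.

    The returned callable maps a binary mask of length ``pool.size`` to the
    LOOCV accuracy of the corresponding original-gene subset.
    """
    pool_genes = np.asarray(pool.selected_idx, dtype=int)
    sub = dataset.matrix[:, pool_genes]
    y = dataset.labels
    n_classes = dataset.n_classes
    n = dataset.n_samples

    def fitness(mask: np.ndarray) -> float:
        m = np.asarray(mask).astype(bool)
        if m.shape != (pool_genes.size,):
            raise ValidationError("mask length must equal pool size")
        if m.sum() == 0:
            raise ValidationError("mask must select at least one gene")
        x = sub[:, m]
        dist = cdist(x, x)
        np.fill_diagonal(dist, np.inf)
        order = np.argsort(dist, axis=1, kind="stable")[:, :k]
        preds = np.array(
            [np.argmax(np.bincount(y[row], minlength=n_classes)) for row in order]
        )
        return 100.0 * int(np.sum(preds == y)) / n

    return fitness


def pool_mask_to_gene_mask(mask: np.ndarray, pool: GenePool, n_genes: int) -> np.ndarray:
    """Lift a pool-local binary mask to the original gene index space."""
    m = np.asarray(mask).astype(bool)
    if m.shape != (pool.size,):
        raise ValidationError("mask length must equal pool size")
    out = np.zeros(n_genes, dtype=np.int8)
    out[np.asarray(pool.selected_idx, dtype=int)[m]] = 1
    return out
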