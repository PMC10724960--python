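"""Minimum-redundancy-maximum-relevance prefiltering.

Greedy forward selection on plug-in mutual information over discretized
expression values: step 1 takes the gene with maximal MI against the class
label; step t takes the argmax of

    MID:  MI(g, label) - mean_{s in selected} MI(g, s)
    MIQ:  MI(g, label) / max(mean_s MI(g, s), 1e-12)

Ties at any argmax break toward the lowest gene index. Labels are already
discrete and are used as-is; genes are discretized independently of labels
(default: 3 quantile bins).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets_io import ExpressionDataset
from .errors import ConfigError, ValidationError

SCHEMES = ("MID", "MIQ")
_MIQ_FLOOR = 1e-12


@dataclass(frozen=True)
class DiscretizedMatrix:
    """Integer codes in [0, n_bins) per sample and gene, plus the bin edges."""

    codes: np.ndarray
    n_bins: int
    bin_edges: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        object.__setattr__(self, "codes", codes)
        if codes.max(initial=0) >= self.n_bins or codes.min(initial=0) < 0:
            raise ValidationError("codes out of range [0, n_bins)")


@dataclass(frozen=True)
class GenePool:
    """mRMR-reduced gene pool, in selection order.

    ``selected_idx[0]`` is always the maximally relevant gene, so downstream
    repair rules can fall back to it deterministically.
    """

    selected_idx: tuple[int, ...]
    relevance: tuple[float, ...]          # MI(gene, label) for every gene, nats
    score_at_selection: tuple[float, ...]  # MID/MIQ score each pick achieved
    scheme: str

    def __post_init__(self) -> None:
        if len(set(self.selected_idx)) != len(self.selected_idx):
            raise ValidationError("duplicate gene in pool")
        if self.scheme not in SCHEMES:
            raise ConfigError(f"unknown mRMR scheme {self.scheme!r}")

    @property
    def size(self) -> int:
        return len(self.selected_idx)

    def to_dict(self) -> dict:
        return {
            "selected_idx": list(self.selected_idx),
            "relevance": list(self.relevance),
            "score_at_selection": list(self.score_at_selection),
            "scheme": self.scheme,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "GenePool":
        return cls(
            selected_idx=tuple(payload["selected_idx"]),
            relevance=tuple(payload["relevance"]),
            score_at_selection=tuple(payload["score_at_selection"]),
            scheme=payload["scheme"],
        )


def discretize_expression(
    dataset: ExpressionDataset, n_bins: int = 3, strategy: str = "quantile"
) -> DiscretizedMatrix:
    """Discretize each gene independently into ``n_bins`` codes.

    ``quantile`` aims at equal bin occupancy, ``width`` at equal-width bins
    over the gene's range. Constant genes map to code 0.
    """
    if n_bins < 2:
        raise ConfigError("n_bins must be >= 2")
    if strategy not in ("quantile", "width"):
        raise ConfigError(f"unknown strategy {strategy!r}")
    if strategy == "quantile" and dataset.n_samples < n_bins:
        raise ConfigError("quantile strategy needs n_samples >= n_bins")
    x = dataset.matrix
    codes = np.zeros(x.shape, dtype=np.int64)
    all_edges: list[np.ndarray] = []
    qs = np.arange(1, n_bins) / n_bins
    for j in range(x.shape[1]):
        col = x[:, j]
        if strategy == "quantile":
            edges = np.quantile(col, qs)
        else:
            edges = col.min() + (col.max() - col.min()) * qs
        edges = np.unique(edges)
        # closed-right bins (x <= edge); an edge separates iff min <= edge < max
        edges = edges[(edges >= col.min()) & (edges < col.max())]
        codes[:, j] = np.digitize(col, edges, right=True)
        all_edges.append(edges)
    return DiscretizedMatrix(codes=codes, n_bins=n_bins, bin_edges=tuple(all_edges))


def mutual_information(x_codes: np.ndarray, y_codes: np.ndarray) -> float:
    """Plug-in MI (nats) from the joint contingency table of two code vectors."""
    x = np.asarray(x_codes, dtype=np.int64)
    y = np.asarray(y_codes, dtype=np.int64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValidationError("code vectors must be equal-length 1-D, non-empty")
    nx = int(x.max()) + 1
    ny = int(y.max()) + 1
    joint = np.bincount(x * ny + y, minlength=nx * ny).reshape(nx, ny).astype(float)
    n = x.size
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    mi = float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))
    return max(mi, 0.0)  # clip -0.0 / rounding

def relevance_vector(disc: DiscretizedMatrix, labels: np.ndarray) -> np.ndarray:
    """MI(gene, label) for every gene."""
    labels = np.asarray(labels, dtype=np.int64)
    return np.array(
        [mutual_information(disc.codes[:, j], labels) for j in range(disc.codes.shape[1])]
    )


def mrmr_select(
    disc: DiscretizedMatrix,
    labels: np.ndarray,
    k: int,
    scheme: str = "MID",
) -> GenePool:
    """Greedy mRMR forward selection of ``k`` genes."""
    if scheme not in SCHEMES:
        raise ConfigError(f"unknown mRMR scheme {scheme!r}")
    n_genes = disc.codes.shape[1]
    if not (1 <= k <= n_genes):
        raise ConfigError(f"k={k} out of range [1, {n_genes}]")
    relevance = relevance_vector(disc, labels)

    selected: list[int] = []
    scores: list[float] = []
    remaining = np.ones(n_genes, dtype=bool)
    # running sum of MI(candidate, already-selected) per candidate
    redundancy_sum = np.zeros(n_genes)

    first = int(np.argmax(relevance))  # argmax takes the lowest index on ties
    selected.append(first)
    scores.append(float(relevance[first]))
    remaining[first] = False

    while len(selected) < k:
        last = selected[-1]
        for j in np.nonzero(remaining)[0]:
            redundancy_sum[j] += mutual_information(
                disc.codes[:, j], disc.codes[:, last]
            )
        mean_red = redundancy_sum / len(selected)
        if scheme == "MID":
            score = relevance - mean_red
        else:
            score = relevance / np.maximum(mean_red, _MIQ_FLOOR)
        score[~remaining] = -np.inf
        pick = int(np.argmax(score))
        selected.append(pick)
        scores.append(float(score[pick]))
        remaining[pick] = False

    return GenePool(
        selected_idx=tuple(selected),
        relevance=tuple(float(v) for v in relevance),
        score_at_selection=tuple(scores),
        scheme=scheme,
    )
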