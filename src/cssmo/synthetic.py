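"""Synthetic gene-expression generator with planted ground truth.

Emulates the structure wrapper gene selection assumes: far more genes than
samples, a small set of class-informative genes, correlated redundant copies
of each informative gene, and a large majority of label-independent noise
genes. Class c shifts each informative gene's mean by ``c * effect_size *
noise_sd`` (a monotone ladder, so any number of classes works).

A redundant copy is parent + N(0, tau^2) with tau^2 = noise_sd^2 (1-rho^2)/rho^2,
which makes corr(parent, copy) = rho on the parent's residual (within-class)
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets_io import ExpressionDataset
from .errors import ConfigError, ValidationError


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; defaults give the bundled recovery benchmark."""

    n_samples: int = 60
    n_genes: int = 500
    n_classes: int = 2
    n_informative: int = 5
    n_redundant_per_informative: int = 4
    effect_size: float = 2.0
    redundancy_corr: float = 0.8
    class_proportions: tuple[float, ...] | None = None
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1:
            raise ConfigError("n_samples and n_genes must be positive")
        if self.n_classes < 2:
            raise ConfigError("need at least 2 classes")
        if self.n_informative < 1:
            raise ConfigError("need at least 1 informative gene")
        if self.n_redundant_per_informative < 0:
            raise ConfigError("n_redundant_per_informative must be >= 0")
        planted = self.n_informative * (1 + self.n_redundant_per_informative)
        if planted > self.n_genes:
            raise ConfigError(
                f"{planted} planted genes exceed n_genes={self.n_genes}"
            )
        if not (0 < self.redundancy_corr <= 1):
            raise ConfigError("redundancy_corr must be in (0, 1]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.class_proportions is not None:
            p = tuple(float(v) for v in self.class_proportions)
            if len(p) != self.n_classes:
                raise ConfigError("class_proportions length != n_classes")
            if abs(sum(p) - 1.0) > 1e-12 or min(p) <= 0:
                raise ConfigError("class_proportions must be positive and sum to 1")
            object.__setattr__(self, "class_proportions", p)
        if self.n_samples < self.n_classes:
            raise ConfigError("need at least one sample per class")

    @property
    def proportions(self) -> np.ndarray:
        if self.class_proportions is None:
            return np.full(self.n_classes, 1.0 / self.n_classes)
        return np.asarray(self.class_proportions)


@dataclass(frozen=True)
class GroundTruth:
    """Partition of gene indices into informative / redundant / noise.

    ``parent_of`` maps each redundant gene index to its informative parent.
    """

    informative_idx: tuple[int, ...]
    redundant_idx: tuple[int, ...]
    noise_idx: tuple[int, ...]
    parent_of: dict[int, int] = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.informative_idx) + len(self.redundant_idx) + len(self.noise_idx)


def _class_counts(n_samples: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder rounding of n*p; guarantees >=1 per class."""
    raw = proportions * n_samples
    counts = np.floor(raw).astype(int)
    counts = np.maximum(counts, 1)
    while counts.sum() > n_samples:
        counts[np.argmax(counts - raw)] -= 1
    remainder = raw - counts
    order = np.argsort(-remainder)
    for i in range(n_samples - counts.sum()):
        counts[order[i % len(counts)]] += 1
    return counts


def generate_synthetic_dataset(
    spec: SyntheticSpec,
) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate an expression dataset plus its planted-gene ground truth.

    Fully reproducible from ``spec.seed``; gene roles are assigned to a seeded
    random permutation of the gene indices so planted genes are scattered.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _class_counts(spec.n_samples, spec.proportions)
    labels = rng.permutation(np.repeat(np.arange(spec.n_classes), counts))

    placement = rng.permutation(spec.n_genes)
    n_inf = spec.n_informative
    n_red = spec.n_informative * spec.n_redundant_per_informative
    informative = placement[:n_inf]
    redundant = placement[n_inf : n_inf + n_red]
    noise = placement[n_inf + n_red :]

    sd = spec.noise_sd
    matrix = np.empty((spec.n_samples, spec.n_genes))
    matrix[:, noise] = rng.normal(0.0, sd, size=(spec.n_samples, len(noise)))
    class_shift = labels[:, None] * spec.effect_size * sd
    matrix[:, informative] = class_shift + rng.normal(
        0.0, sd, size=(spec.n_samples, n_inf)
    )

    rho = spec.redundancy_corr
    tau = 0.0 if rho == 1.0 else sd * np.sqrt((1.0 - rho**2) / rho**2)
    parent_of: dict[int, int] = {}
    for i, g in enumerate(redundant):
        parent = informative[i % n_inf]
        parent_of[int(g)] = int(parent)
        matrix[:, g] = matrix[:, parent] + rng.normal(0.0, tau, size=spec.n_samples)

    dataset = ExpressionDataset(
        matrix=matrix,
        labels=labels,
        gene_ids=tuple(f"g{j:04d}" for j in range(spec.n_genes)),
        sample_ids=tuple(f"s{i:04d}" for i in range(spec.n_samples)),
        class_names=tuple(f"class{c}" for c in range(spec.n_classes)),
    )
    truth = GroundTruth(
        informative_idx=tuple(sorted(int(g) for g in informative)),
        redundant_idx=tuple(sorted(int(g) for g in redundant)),
        noise_idx=tuple(sorted(int(g) for g in noise)),
        parent_of=parent_of,
    )
    return dataset, truth


@dataclass(frozen=True)
class RecoveryScore:
    informative_hit_fraction: float
    selected_size: int
    noise_fraction: float


def planted_recovery_score(mask: np.ndarray, truth: GroundTruth) -> RecoveryScore:
    """Score a selected gene mask against the planted truth.

    An informative gene counts as hit if it or any of its redundant copies is
    selected (copies carry the same signal). ``noise_fraction`` is the share
    of selected genes that are pure noise.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != (truth.n_genes,):
        raise ValidationError(
            f"mask length {mask.shape} != n_genes {truth.n_genes}"
        )
    selected = set(np.nonzero(mask)[0].tolist())
    hits = 0
    for g in truth.informative_idx:
        copies = {r for r, p in truth.parent_of.items() if p == g}
        if g in selected or selected & copies:
            hits += 1
    n_sel = len(selected)
    noise_sel = len(selected & set(truth.noise_idx))
    return RecoveryScore(
        informative_hit_fraction=hits / len(truth.informative_idx),
        selected_size=n_sel,
        noise_fraction=(noise_sel / n_sel) if n_sel else 0.0,
    )
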