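"""Reading, validating and normalizing expression matrices.

The canonical in-memory layout is samples x genes with integer class codes.
Files may ship genes-as-rows (the common microarray export); the loader
transposes them into the canonical orientation. Expression values must be
finite after loading -- the default policy is to reject files with missing
cells rather than impute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, ValidationError

NORMALIZATIONS = ("minmax_per_gene", "zscore_per_gene", "none")
ORIENTATIONS = ("samples_by_genes", "genes_by_samples")


@dataclass(frozen=True)
class ExpressionDataset:
    """An expression matrix (n_samples x n_genes) with per-sample class labels.

    ``labels`` hold integer codes into ``class_names``; every class occurs at
    least once. Gene and sample identifiers are unique.
    """

    matrix: np.ndarray
    labels: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "class_names", tuple(self.class_names))
        if matrix.ndim != 2:
            raise ValidationError("expression matrix must be 2-D")
        n_samples, n_genes = matrix.shape
        if not np.all(np.isfinite(matrix)):
            raise ValidationError("expression matrix contains non-finite values")
        if labels.shape != (n_samples,):
            raise ValidationError(
                f"labels length {labels.shape} does not match n_samples={n_samples}"
            )
        n_classes = len(self.class_names)
        if n_classes < 1:
            raise ValidationError("at least one class required")
        present = np.unique(labels)
        if present.min(initial=0) < 0 or present.max(initial=0) >= n_classes:
            raise ValidationError("class codes out of range [0, C)")
        if len(present) != n_classes:
            raise ValidationError("every class must occur at least once")
        if len(self.gene_ids) != n_genes:
            raise ValidationError("gene_ids length mismatch")
        if len(self.sample_ids) != n_samples:
            raise ValidationError("sample_ids length mismatch")
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene ids")
        if len(set(self.sample_ids)) != n_samples:
            raise ValidationError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass(frozen=True)
class PreprocessConfig:
    """Loader behaviour: normalization method, file orientation, label column.

    ``label_column=None`` means: a column named "class" (case-insensitive) if
    present, else the last column.
    """

    normalization: str = "minmax_per_gene"
    orientation: str = "samples_by_genes"
    label_column: str | None = None

    def __post_init__(self) -> None:
        if self.normalization not in NORMALIZATIONS:
            raise ConfigError(f"unknown normalization {self.normalization!r}")
        if self.orientation not in ORIENTATIONS:
            raise ConfigError(f"unknown orientation {self.orientation!r}")


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def load_expression_matrix(
    path: str | Path, config: PreprocessConfig = PreprocessConfig()
) -> ExpressionDataset:
    """Load a delimited expression matrix with one label column.

    The first column holds row identifiers. With
    ``orientation="genes_by_samples"`` the table is transposed first (rows are
    genes, columns are samples, and the label line is a row named like the
    label column).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    frame = pd.read_csv(path, sep=_sniff_delimiter(path), index_col=0, dtype=str)
    if frame.shape[1] == 0:
        raise FormatError(f"{path}: no data columns found")
    if config.orientation == "genes_by_samples":
        frame = frame.T
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)

    label_col = config.label_column
    if label_col is None:
        matches = [c for c in frame.columns if c.lower() == "class"]
        label_col = matches[0] if matches else frame.columns[-1]
    elif label_col not in frame.columns:
        raise FormatError(f"{path}: label column {label_col!r} not found")
    labels_raw = frame[label_col]
    expr = frame.drop(columns=[label_col])

    class_names = tuple(sorted(set(labels_raw)))
    code_of = {name: i for i, name in enumerate(class_names)}
    labels = np.array([code_of[v] for v in labels_raw], dtype=int)

    values = np.empty(expr.shape, dtype=float)
    for j, col in enumerate(expr.columns):
        converted = pd.to_numeric(expr[col], errors="coerce")
        bad = np.nonzero(converted.isna().to_numpy())[0]
        if bad.size:
            row = expr.index[bad[0]]
            raise FormatError(
                f"{path}: non-numeric or missing value at row {row!r}, "
                f"column {col!r}"
            )
        values[:, j] = converted.to_numpy()

    if len(set(expr.columns)) != expr.shape[1]:
        raise ValidationError(f"{path}: duplicate gene ids")
    if len(set(expr.index)) != expr.shape[0]:
        raise ValidationError(f"{path}: duplicate sample ids")

    dataset = ExpressionDataset(
        matrix=values,
        labels=labels,
        gene_ids=tuple(expr.columns),
        sample_ids=tuple(expr.index),
        class_names=class_names,
    )
    if config.normalization != "none":
        dataset = normalize_expression(dataset, config.normalization)
    return dataset


def normalize_expression(dataset: ExpressionDataset, method: str) -> ExpressionDataset:
    """Per-gene rescaling: minmax to [0,1] or z-score; constant genes map to 0."""
    if method == "none":
        return dataset
    if method not in NORMALIZATIONS:
        raise ConfigError(f"unknown normalization {method!r}")
    if dataset.n_samples < 2:
        raise ValidationError("normalization requires at least 2 samples")
    x = dataset.matrix
    if method == "minmax_per_gene":
        lo = x.min(axis=0)
        span = x.max(axis=0) - lo
        safe = np.where(span == 0, 1.0, span)
        out = (x - lo) / safe
        out[:, span == 0] = 0.0
    else:  # zscore_per_gene
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        safe = np.where(sd == 0, 1.0, sd)
        out = (x - mu) / safe
        out[:, sd == 0] = 0.0
    return replace(dataset, matrix=out)


def write_expression_matrix(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write the canonical samples x genes CSV with a trailing ``class`` column."""
    frame = pd.DataFrame(
        dataset.matrix, index=list(dataset.sample_ids), columns=list(dataset.gene_ids)
    )
    frame["class"] = [dataset.class_names[c] for c in dataset.labels]
    # 17 significant digits round-trips float64 exactly
    frame.to_csv(path, float_format="%.17g")


def write_selection_report(result, path: str | Path) -> None:
    """Serialize a SelectionResult to JSON (re-loadable via load_selection_report)."""
    if int(np.sum(result.best_mask)) == 0:
        raise ValidationError("refusing to write a report for an empty gene mask")
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
        fh.write("\n")


def load_selection_report(path: str | Path):
    from .swarm_core import SelectionResult

    with open(path) as fh:
        payload = json.load(fh)
    return SelectionResult.from_dict(payload)
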