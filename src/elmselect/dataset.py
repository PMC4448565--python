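"""Expression dataset container shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


@dataclass
class ExpressionDataset:
    """Genes x samples numeric matrix with gene identifiers and sample labels.

    Parameters
    ----------
    matrix
        2-D float array, shape ``(n_genes, n_samples)``. Must be finite.
    gene_ids
        One unique identifier per matrix row.
    labels
        One class label per matrix column. At least two distinct classes.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    labels: list[str]
    classes: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValidationError(
                f"expression matrix must be 2-D, got shape {self.matrix.shape}"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("expression matrix contains missing or non-finite values")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.labels = [str(l) for l in self.labels]
        if len(self.gene_ids) != self.matrix.shape[0]:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {self.matrix.shape[0]} matrix rows"
            )
        if len(self.labels) != self.matrix.shape[1]:
            raise ValidationError(
                f"{len(self.labels)} labels for {self.matrix.shape[1]} matrix columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            dups = sorted({g for g in self.gene_ids if g in seen or seen.add(g)})
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        # preserve first-appearance order of classes: stable across runs
        self.classes = tuple(dict.fromkeys(self.labels))
        if len(self.classes) < 2:
            raise ValidationError("dataset must contain at least 2 classes")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {c: 0 for c in self.classes}
        for l in self.labels:
            counts[l] += 1
        return counts

    def subset_genes(self, row_indices: np.ndarray) -> "ExpressionDataset":
        """Dataset restricted to the given gene rows (order preserved)."""
        row_indices = np.asarray(row_indices, dtype=int)
        return ExpressionDataset(
            matrix=self.matrix[row_indices],
            gene_ids=[self.gene_ids[i] for i in row_indices],
            labels=list(self.labels),
        )

    def samples_by_features(self) -> np.ndarray:
        """The matrix transposed into the classifier's samples x features layout."""
        return self.matrix.T
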