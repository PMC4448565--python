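"""Synthetic multi-class expression data with planted discriminative genes.

Emulates the regime of the motivating benchmarks: many features, few
samples per class, optional class imbalance. Each informative gene gets a
random low/high mean pattern across classes (guaranteed non-constant), with
the two levels separated by ``effect_size`` noise standard deviations;
noise genes are identically distributed across classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import ExpressionDataset, ValidationError


@dataclass(frozen=True)
class SyntheticSpec:
    n_classes: int = 4
    samples_per_class: tuple[int, ...] = (15, 15, 15, 15)
    n_informative: int = 10
    n_noise: int = 490
    effect_size: float = 5.0
    noise_sd: float = 1.0
    lognormal: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValidationError("need at least 2 classes")
        if len(self.samples_per_class) != self.n_classes:
            raise ValidationError(
                f"samples_per_class has {len(self.samples_per_class)} entries "
                f"for {self.n_classes} classes"
            )
        if any(n < 2 for n in self.samples_per_class):
            raise ValidationError("every class needs at least 2 samples")
        if self.n_informative < 1:
            raise ValidationError("n_informative must be >= 1")
        if self.n_noise < 0:
            raise ValidationError("n_noise must be >= 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.n_informative + self.n_noise

    @property
    def n_samples(self) -> int:
        return sum(self.samples_per_class)


@dataclass
class PlantedTruth:
    informative_gene_ids: list[str]
    class_mean_matrix: np.ndarray  # n_informative x n_classes
    classes: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "informative_gene_ids": list(self.informative_gene_ids),
            "classes": list(self.classes),
            "class_mean_matrix": self.class_mean_matrix.tolist(),
        }


def generate_dataset(spec: SyntheticSpec) -> tuple[ExpressionDataset, PlantedTruth]:
    """Generate a labelled expression matrix plus the planted ground truth.

    Deterministic given ``spec.seed``; gene order is shuffled so informative
    genes are not positionally clustered.
    """
    rng = np.random.default_rng(spec.seed)
    classes = tuple(f"class{c}" for c in range(spec.n_classes))
    labels = [c for c, n in zip(classes, spec.samples_per_class) for _ in range(n)]
    class_col = np.repeat(np.arange(spec.n_classes), spec.samples_per_class)

    # low/high pattern per informative gene; redraw all-equal patterns so each
    # informative gene separates some pair of classes (unless effect_size = 0)
    patterns = np.empty((spec.n_informative, spec.n_classes), dtype=np.int8)
    for g in range(spec.n_informative):
        while True:
            p = rng.integers(0, 2, size=spec.n_classes)
            if 0 < p.sum() < spec.n_classes:
                patterns[g] = p
                break
    class_means = patterns * (spec.effect_size * spec.noise_sd)

    matrix = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_samples))
    matrix[: spec.n_informative] += class_means[:, class_col]
    if spec.lognormal:
        matrix = np.exp(matrix)

    perm = rng.permutation(spec.n_genes)
    matrix = matrix[perm]
    width = max(4, len(str(spec.n_genes)))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(spec.n_genes)]
    informative_ids = [gene_ids[int(np.flatnonzero(perm == g)[0])] for g in range(spec.n_informative)]

    dataset = ExpressionDataset(matrix=matrix, gene_ids=gene_ids, labels=labels)
    truth = PlantedTruth(
        informative_gene_ids=informative_ids,
        class_mean_matrix=class_means.astype(float),
        classes=classes,
    )
    return dataset, truth


def recovery_score(selected_gene_ids, truth: PlantedTruth) -> tuple[float, float]:
    """(precision, recall) of a selection against the planted informative set."""
    selected = set(selected_gene_ids)
    if not selected:
        raise ValidationError("selection is empty")
    informative = set(truth.informative_gene_ids)
    hit = len(selected & informative)
    return hit / len(selected), hit / len(informative)
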