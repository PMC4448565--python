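"""Subset evaluation: repeated stratified random splits, ELM accuracy, fitness.

A candidate gene subset is scored by restricting the expression matrix to
the selected genes, repeating a stratified 75/25 train/test split ``n_splits``
times, training an ELM on each training part, and averaging the test-part
overall accuracies. The fitness adds a parsimony bonus ``omega_f / n_selected``
once the mean accuracy strictly exceeds the threshold ``d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import ExpressionDataset, ValidationError
from .elm import predict_elm, train_elm


@dataclass(frozen=True)
class FitnessParams:
    """Fitness hyperparameters.

    ``omega_f`` is the feature-selection cost weight and ``d`` the expected
    accuracy threshold; the defaults follow the reference settings
    (omega_f=1, d=0.98, 20 splits at 75% training).
    """

    omega_f: float = 1.0
    d: float = 0.98
    n_splits: int = 20
    train_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.omega_f < 0:
            raise ValidationError("omega_f must be nonnegative")
        if not 0 < self.d <= 1:
            raise ValidationError("d must lie in (0, 1]")
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must lie in (0, 1)")
        if self.n_splits < 1:
            raise ValidationError("n_splits must be >= 1")


@dataclass(frozen=True)
class ELMSettings:
    """Classifier settings used inside fitness evaluation."""

    n_hidden: int | None = None  # None -> max(100, min(4 * n_train, 1000))
    activation: str = "rbf"


@dataclass
class FitnessResult:
    mean_accuracy: float
    n_selected: int
    fitness: float
    per_split_accuracies: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "n_selected": self.n_selected,
            "fitness": self.fitness,
            "per_split_accuracies": list(self.per_split_accuracies),
        }


def random_split(
    dataset: ExpressionDataset, train_fraction: float, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random partition of sample indices into (train, test).

    Each class contributes ``ceil(train_fraction * n_c)`` samples to training,
    clamped to leave at least one sample per class on each side. Deterministic
    given ``seed``.
    """
    if not 0 < train_fraction < 1:
        raise ValidationError("train_fraction must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.asarray(dataset.labels, dtype=object)
    train_parts: list[np.ndarray] = []
    test_parts: list[np.ndarray] = []
    for cls in dataset.classes:
        idx = np.flatnonzero(labels == cls)
        n_c = idx.size
        if n_c < 2:
            raise ValidationError(
                f"class {cls!r} has only {n_c} sample(s); at least 2 are required to split"
            )
        n_train = int(np.ceil(train_fraction * n_c))
        n_train = min(max(n_train, 1), n_c - 1)
        perm = rng.permutation(idx)
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    train = np.sort(np.concatenate(train_parts))
    test = np.sort(np.concatenate(test_parts))
    return train, test


def overall_accuracy(predicted, truth) -> float:
    """Fraction of correctly classified samples."""
    predicted = list(predicted)
    truth = list(truth)
    if not predicted or not truth:
        raise ValidationError("accuracy of an empty prediction set is undefined")
    if len(predicted) != len(truth):
        raise ValidationError(
            f"{len(predicted)} predictions vs {len(truth)} true labels"
        )
    return sum(p == t for p, t in zip(predicted, truth)) / len(truth)


def parsimony_fitness(mean_accuracy: float, n_selected: int, params: FitnessParams) -> float:
    """Accuracy plus a parsimony bonus above the threshold.

    Returns ``mean_accuracy + omega_f / n_selected`` when
    ``mean_accuracy > d`` (strict), else ``mean_accuracy``.
    """
    if n_selected < 1:
        raise ValidationError("n_selected must be >= 1 (empty subsets are unscorable)")
    if not 0 <= mean_accuracy <= 1:
        raise ValidationError("mean_accuracy must lie in [0, 1]")
    if mean_accuracy > params.d:
        return mean_accuracy + params.omega_f / n_selected
    return mean_accuracy


def evaluate_subset(
    dataset: ExpressionDataset,
    chromosome: np.ndarray,
    params: FitnessParams,
    elm: ELMSettings = ELMSettings(),
    seed=0,
) -> FitnessResult:
    """Score one gene subset by repeated split-train-test with an ELM.

    ``chromosome`` is a binary vector over the dataset's gene rows
    (1 = gene included). ``seed`` may be an int or a tuple such as
    ``(master_seed, generation)``; split and classifier randomness are both
    derived from it, so repeated calls are bit-identical.
    """
    bits = np.asarray(chromosome)
    if bits.shape != (dataset.n_genes,):
        raise ValidationError(
            f"chromosome length {bits.shape} does not match gene count {dataset.n_genes}"
        )
    selected = np.flatnonzero(bits)
    if selected.size == 0:
        raise ValidationError("chromosome selects no genes")

    X_all = dataset.matrix[selected].T  # samples x features
    labels = list(dataset.labels)

    ss = np.random.SeedSequence(seed)
    accuracies: list[float] = []
    for child in ss.spawn(params.n_splits):
        split_rng, elm_rng = (np.random.default_rng(s) for s in child.spawn(2))
        train_idx, test_idx = random_split(dataset, params.train_fraction, split_rng)
        model = train_elm(
            X_all[train_idx],
            [labels[i] for i in train_idx],
            n_hidden=elm.n_hidden,
            activation=elm.activation,
            seed=elm_rng,
        )
        pred = predict_elm(model, X_all[test_idx])
        accuracies.append(overall_accuracy(pred, [labels[i] for i in test_idx]))

    mean_acc = float(np.mean(accuracies))
    return FitnessResult(
        mean_accuracy=mean_acc,
        n_selected=int(selected.size),
        fitness=parsimony_fitness(mean_acc, int(selected.size), params),
        per_split_accuracies=accuracies,
    )
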