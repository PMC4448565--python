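import numpy as np
import pytest

from elmselect import ExpressionDataset, SyntheticSpec, generate_dataset


@pytest.fixture
def tiny_dataset():
    """4 classes x 4 samples, 20 genes, strong class structure in genes 0-7."""
    rng = np.random.default_rng(42)
    labels = [c for c in "ABCD" for _ in range(4)]
    matrix = rng.normal(0, 1, size=(20, 16))
    for g in range(8):
        pattern = rng.integers(0, 2, size=4)
        shift = np.repeat(pattern * 6.0, 4)
        matrix[g] += shift
    return ExpressionDataset(matrix=matrix, gene_ids=[f"g{i}" for i in range(20)], labels=labels)


@pytest.fixture
def easy_synthetic():
    """Small planted dataset: 4 classes x 10 samples, 5 informative, 45 noise."""
    spec = SyntheticSpec(
        n_classes=4, samples_per_class=(10, 10, 10, 10),
        n_informative=5, n_noise=45, effect_size=5.0, seed=11,
    )
    return generate_dataset(spec)


def informative_bits(dataset, truth):
    bits = np.zeros(dataset.n_genes, dtype=np.uint8)
    idx = [dataset.gene_ids.index(g) for g in truth.informative_gene_ids]
    bits[idx] = 1
    return bits
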