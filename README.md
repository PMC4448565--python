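# elmselect

Wrapper gene selection for multi-class expression data. A binary-coded
genetic algorithm (GA) searches over gene-inclusion bit strings; every
candidate subset is scored by an extreme learning machine (ELM) — a
single-hidden-layer network with random hidden parameters and analytically
solved (pseudoinverse) output weights — under repeated stratified 75/25
train/test splits. The fitness is the mean validation accuracy plus a
parsimony bonus `omega_f / n_selected` once accuracy strictly exceeds a
threshold `d`, so the search converges to small, discriminative gene sets.

## Components

| module                 | what it does |
| ---------------------- | ------------ |
| `elmselect.elm`        | ELM classifier: random sigmoid or Gaussian-RBF hidden layer, least-squares output weights, argmax decision rule, random-restart tuning |
| `elmselect.fitness`    | stratified random splits, overall accuracy, the parsimony-penalized fitness, subset evaluation |
| `elmselect.ga`         | GA: uniform + two-point hybrid crossover (best 2 of 4 offspring), normalized geometric ranking selection, per-bit mutation, elitism |
| `elmselect.simulate`   | synthetic multi-class expression matrices with planted discriminative genes among noise genes |
| `elmselect.io`         | TSV/CSV/GCT/RES expression matrices, CLS/plain label files, gene-list + JSON run reports |
| `elmselect.cli`        | `elmselect simulate / select / classify` |

## CLI

Generate a synthetic dataset, select genes, and re-score the selection:

```sh
elmselect simulate --n-classes 4 --samples-per-class 15 \
    --n-informative 10 --n-noise 490 --effect-size 5 --seed 1 --out data/

elmselect select data/expression.tsv data/labels.cls \
    --seed 1 --out run/ --population-size 30 --max-generations 15

elmselect classify data/expression.tsv data/labels.cls run/selected_genes.tsv
```

`select` accepts a YAML config (`ga:`, `fitness:`, `elm:` sections) with
CLI flags taking precedence; the JSON report echoes the full configuration
and master seed, so a run is replayable byte-for-byte. Exit codes: 0
success, 2 validation error, 1 runtime error.

Defaults follow the reference protocol: population 200, crossover 0.80,
mutation 0.20, selection q = 0.01, 50 generations, initial subsets of
20–200 genes, fitness `omega_f = 1`, `d = 0.98`, 20 splits at 75 %
training.

## Library

```python
from elmselect import (SyntheticSpec, generate_dataset, GAConfig,
                       FitnessParams, evolve, best_solution, recovery_score)

dataset, truth = generate_dataset(SyntheticSpec(seed=1))
state = evolve(dataset, GAConfig(population_size=30, max_generations=15,
                                 master_seed=1), FitnessParams())
genes, result = best_solution(state, dataset.gene_ids)
precision, recall = recovery_score(genes, truth)
```

## Notes on defaults

- The hidden-layer default is deliberately overparameterized
  (`max(100, min(4 * n_train, 1000))` neurons): at `n_hidden == n_train`
  the least-squares fit interpolates the training data and generalization
  collapses, while the overparameterized minimum-norm solution degrades
  gracefully when noise genes are present.
- The default activation is Gaussian RBF (centers drawn from training
  samples, width = median pairwise training distance), which is markedly
  more robust to irrelevant features than random sigmoid projections;
  sigmoid is available via `ELMSettings(activation="sigmoid")`.
- Splits are stratified per class so that small classes (down to 2
  samples) always appear on both sides of a split.
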