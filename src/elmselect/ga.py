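"""Binary-coded genetic algorithm over gene-inclusion bit strings.

The generational loop: rank the population, draw parent pairs with
normalized geometric ranking probabilities, recombine each pair with a
hybrid crossover (two uniform-crossover children plus two two-point
children, keep the best two of the four), mutate offspring, and carry the
best-so-far individual into the next generation unchanged.

``run_ga`` is the generic engine over an arbitrary bit-string fitness
function; ``evolve`` wires it to expression data via
:func:`elmselect.fitness.evaluate_subset`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np

from .dataset import ExpressionDataset, ValidationError
from .fitness import ELMSettings, FitnessParams, FitnessResult, evaluate_subset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 200
    crossover_prob: float = 0.80
    mutation_prob: float = 0.20
    selection_q: float = 0.01
    max_generations: int = 50
    init_gene_range: tuple[int, int] = (20, 200)
    target_fitness: float | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.population_size % 2:
            raise ValidationError("population_size must be an even integer >= 2")
        for name in ("crossover_prob", "mutation_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if not 0 < self.selection_q < 1:
            raise ValidationError("selection_q must lie in (0, 1)")
        if self.max_generations < 0:
            raise ValidationError("max_generations must be >= 0")
        lo, hi = self.init_gene_range
        if not 1 <= lo <= hi:
            raise ValidationError("init_gene_range must satisfy 1 <= lo <= hi")


@dataclass
class Individual:
    bits: np.ndarray  # uint8 vector, >= 1 set bit
    result: FitnessResult
    order: int = 0  # insertion order, used as the final ranking tie-break


@dataclass
class GAState:
    generation: int
    population: list[Individual]
    best_ever: Individual
    history: list[dict] = field(default_factory=list)

    def to_report(self, gene_ids: Sequence[str] | None = None, config: GAConfig | None = None) -> dict:
        report = {
            "generations_run": self.generation,
            "history": list(self.history),
            "best": {
                "n_selected": self.best_ever.result.n_selected,
                "fitness": self.best_ever.result.fitness,
                "mean_accuracy": self.best_ever.result.mean_accuracy,
                "per_split_accuracies": list(self.best_ever.result.per_split_accuracies),
                "selected_indices": np.flatnonzero(self.best_ever.bits).tolist(),
            },
        }
        if gene_ids is not None:
            report["best"]["selected_genes"] = [
                gene_ids[i] for i in np.flatnonzero(self.best_ever.bits)
            ]
        if config is not None:
            report["config"] = asdict(config)
        return report


def _as_rng(seed) -> np.random.Generator:
    # accepts a Generator, any generator-like object (for tests), or seed material
    if isinstance(seed, np.random.Generator) or hasattr(seed, "choice"):
        return seed
    return np.random.default_rng(seed)


def _as_bits(x) -> np.ndarray:
    bits = np.asarray(x, dtype=np.uint8)
    if bits.ndim != 1:
        raise ValidationError("chromosome must be a 1-D bit vector")
    return bits


def repair(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Guarantee at least one set bit (the fitness divides by the count)."""
    if not bits.any():
        bits = bits.copy()
        bits[rng.integers(0, bits.size)] = 1
    return bits


def init_population(n_genes: int, config: GAConfig, seed) -> list[np.ndarray]:
    """Random chromosomes with set-bit counts uniform over ``init_gene_range``."""
    rng = _as_rng(seed)
    lo, hi = config.init_gene_range
    if hi > n_genes:
        raise ValidationError(
            f"init_gene_range upper bound {hi} exceeds gene count {n_genes}"
        )
    population = []
    for _ in range(config.population_size):
        k = int(rng.integers(lo, hi + 1))
        bits = np.zeros(n_genes, dtype=np.uint8)
        bits[rng.choice(n_genes, size=k, replace=False)] = 1
        population.append(bits)
    return population


def selection_probabilities(ranked_population_size: int, q: float) -> np.ndarray:
    """Normalized geometric ranking probabilities, best rank first.

    P(rank r) = q' (1-q)^(r-1) with q' = q / (1 - (1-q)^N); the vector sums
    to 1 and strictly decreases with rank.
    """
    if not 0 < q < 1:
        raise ValidationError("q must lie in (0, 1)")
    n = ranked_population_size
    if n < 1:
        raise ValidationError("population size must be >= 1")
    ranks = np.arange(1, n + 1)
    raw = q * (1 - q) ** (ranks - 1)
    return raw / (1 - (1 - q) ** n)


def uniform_crossover(
    parent_a: np.ndarray, parent_b: np.ndarray, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus random mask; the two children take complementary alleles."""
    rng = _as_rng(seed)
    a, b = _as_bits(parent_a), _as_bits(parent_b)
    if a.shape != b.shape:
        raise ValidationError(f"parent lengths differ: {a.size} vs {b.size}")
    mask = rng.integers(0, 2, size=a.size).astype(bool)
    child1 = np.where(mask, a, b).astype(np.uint8)
    child2 = np.where(mask, b, a).astype(np.uint8)
    return child1, child2


def two_point_crossover(
    parent_a: np.ndarray, parent_b: np.ndarray, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Swap the half-open segment [i, j), cut points drawn uniformly."""
    rng = _as_rng(seed)
    a, b = _as_bits(parent_a), _as_bits(parent_b)
    if a.shape != b.shape:
        raise ValidationError(f"parent lengths differ: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValidationError("two-point crossover needs length >= 2")
    i, j = np.sort(rng.choice(a.size + 1, size=2, replace=False))
    child1, child2 = a.copy(), b.copy()
    child1[i:j], child2[i:j] = b[i:j], a[i:j]
    return child1, child2


def mutate(chromosome: np.ndarray, per_bit_rate: float, seed) -> np.ndarray:
    """Flip each bit independently with probability ``per_bit_rate``; repair."""
    if not 0 <= per_bit_rate <= 1:
        raise ValidationError("per_bit_rate must lie in [0, 1]")
    rng = _as_rng(seed)
    bits = _as_bits(chromosome)
    flips = rng.random(bits.size) < per_bit_rate
    return repair(np.where(flips, 1 - bits, bits).astype(np.uint8), rng)


def hybrid_crossover(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    fitness_fn: Callable[[np.ndarray], FitnessResult],
    seed,
) -> list[tuple[np.ndarray, FitnessResult]]:
    """Four offspring (2 uniform + 2 two-point); return the best two, scored.

    All-zero offspring are repaired before evaluation. Results are returned
    alongside the chromosomes so callers need not re-evaluate.
    """
    rng = _as_rng(seed)
    u1, u2 = uniform_crossover(parent_a, parent_b, rng)
    t1, t2 = two_point_crossover(parent_a, parent_b, rng)
    offspring = [repair(c, rng) for c in (u1, u2, t1, t2)]
    scored = [(c, fitness_fn(c)) for c in offspring]
    scored.sort(key=lambda cr: (-cr[1].fitness, cr[1].n_selected))
    return scored[:2]


def _rank_key(ind: Individual) -> tuple:
    # best first: highest fitness, then fewer selected genes, then insertion order
    return (-ind.result.fitness, ind.result.n_selected, ind.order)


def run_ga(
    n_genes: int,
    fitness_fn: Callable[[np.ndarray, int], FitnessResult],
    config: GAConfig,
    target_attr: str = "mean_accuracy",
) -> GAState:
    """Generic GA engine over bit strings.

    ``fitness_fn(bits, generation)`` scores a chromosome; all chromosomes in
    one generation receive the same ``generation`` argument so evaluation
    noise (e.g. random data splits) is shared within a generation.
    Early stop triggers when ``getattr(best.result, target_attr)`` reaches
    ``config.target_fitness``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.master_seed, 0xE1)))
    order = 0

    def make(bits: np.ndarray, result: FitnessResult) -> Individual:
        nonlocal order
        ind = Individual(bits=bits, result=result, order=order)
        order += 1
        return ind

    population = [
        make(bits, fitness_fn(bits, 0))
        for bits in init_population(n_genes, config, rng)
    ]
    best_ever = min(population, key=_rank_key)
    state = GAState(generation=0, population=population, best_ever=best_ever)
    _record(state)

    probs = selection_probabilities(config.population_size, config.selection_q)
    L = n_genes
    for gen in range(1, config.max_generations + 1):
        if _target_met(state.best_ever, config, target_attr):
            break
        ranked = sorted(state.population, key=_rank_key)
        eval_fn = lambda bits: fitness_fn(bits, gen)  # noqa: E731
        children: list[Individual] = []
        for _ in range(config.population_size // 2):
            ia, ib = rng.choice(config.population_size, size=2, p=probs)
            pa, pb = ranked[ia], ranked[ib]
            if rng.random() < config.crossover_prob:
                pair = hybrid_crossover(pa.bits, pb.bits, eval_fn, rng)
            else:
                pair = [(pa.bits.copy(), pa.result), (pb.bits.copy(), pb.result)]
            for bits, result in pair:
                if rng.random() < config.mutation_prob:
                    bits = mutate(bits, 1.0 / L, rng)
                    result = eval_fn(bits)
                children.append(make(bits, result))
        # elitism: the best-so-far individual replaces the worst child, unmodified
        worst = max(range(len(children)), key=lambda i: _rank_key(children[i]))
        children[worst] = make(state.best_ever.bits.copy(), state.best_ever.result)
        state.population = children
        state.generation = gen
        gen_best = min(children, key=_rank_key)
        if gen_best.result.fitness > state.best_ever.result.fitness:
            state.best_ever = gen_best
        _record(state)
    return state


def _target_met(best: Individual, config: GAConfig, target_attr: str) -> bool:
    if config.target_fitness is None:
        return False
    return getattr(best.result, target_attr) >= config.target_fitness


def _record(state: GAState) -> None:
    fits = [ind.result.fitness for ind in state.population]
    entry = {
        "generation": state.generation,
        "best_fitness": float(max(fits)),
        "mean_fitness": float(np.mean(fits)),
        "best_ever_fitness": float(state.best_ever.result.fitness),
        "best_ever_n_selected": int(state.best_ever.result.n_selected),
    }
    state.history.append(entry)
    logger.info(
        "generation %(generation)d: best %(best_fitness).4f mean %(mean_fitness).4f "
        "best-ever %(best_ever_fitness).4f (%(best_ever_n_selected)d genes)",
        entry,
    )


def evolve(
    dataset: ExpressionDataset,
    config: GAConfig,
    params: FitnessParams = FitnessParams(),
    elm: ELMSettings = ELMSettings(),
) -> GAState:
    """Run the full gene-selection GA on an expression dataset.

    Split seeds derive from ``(master_seed, generation)`` so every chromosome
    within a generation is scored on identical data splits; the whole run is
    reproducible from ``config.master_seed``.
    """
    def fitness_fn(bits: np.ndarray, generation: int) -> FitnessResult:
        return evaluate_subset(
            dataset, bits, params, elm, seed=(config.master_seed, generation)
        )

    return run_ga(dataset.n_genes, fitness_fn, config)


def best_solution(state: GAState, gene_ids: Sequence[str]) -> tuple[list[str], FitnessResult]:
    """Gene identifiers at the best-ever chromosome's set bits, with its score."""
    if state.best_ever is None:  # pragma: no cover - constructed states always set it
        raise ValidationError("GA state has no evaluated best individual")
    idx = np.flatnonzero(state.best_ever.bits)
    return [gene_ids[i] for i in idx], state.best_ever.result
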