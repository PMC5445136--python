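"""Steady-state genetic algorithm for wrapper feature selection.

Chromosomes are binary masks over the feature columns (36 bits for the
full BVP/ECG/SCL set); a set bit keeps the feature. Fitness is the mean
stratified k-fold cross-validation accuracy of the configured classifier
(LDA by default) trained on the decoded subset, so the search directly
optimizes downstream recognition rate.

The loop is steady-state: each breeding event draws two parents by
roulette-wheel selection, forms one offspring by two-point crossover,
mutates it by independent bit flips, and replaces the current worst
individual only when the offspring is fitter. Best fitness is therefore
monotone over the run. One "generation" is ``population_size`` breeding
events, which bounds fitness evaluations at roughly
``population_size * (max_generations + 1)``; evaluations are memoized by
bit pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from . import classifiers


@dataclass
class Chromosome:
    bits: np.ndarray
    fitness: float | None = None

    @classmethod
    def from_string(cls, s: str) -> "Chromosome":
        return cls(bits=_parse_bits(s))

    def to_string(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    def copy(self) -> "Chromosome":
        return Chromosome(bits=self.bits.copy(), fitness=self.fitness)


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 100
    max_generations: int = 30
    crossover_rate: float = 0.8
    mutation_rate: float = 0.01
    cv_folds: int = 5
    fitness_classifier: str = "lda"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class GAResult:
    best_chromosome: Chromosome
    best_fitness: float
    best_generation: int
    history: list[float] = field(default_factory=list)

    def selected_indices(self) -> set[int]:
        return decode_chromosome(self.best_chromosome.bits)


def _parse_bits(bits: "str | np.ndarray | list[int]") -> np.ndarray:
    if isinstance(bits, str):
        if set(bits) - {"0", "1"}:
            bad = sorted(set(bits) - {"0", "1"})
            raise ValueError(f"chromosome contains non-binary characters: {bad}")
        return np.fromiter((c == "1" for c in bits), dtype=bool, count=len(bits))
    arr = np.asarray(bits)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("chromosome bits must be 0 or 1")
    return arr.astype(bool)


def decode_chromosome(bits: "str | np.ndarray | list[int]") -> set[int]:
    """1-based indices of the selected features (bit i set -> feature i)."""
    mask = _parse_bits(bits)
    return set((np.flatnonzero(mask) + 1).tolist())


def encode_indices(indices: set[int], length: int) -> Chromosome:
    bits = np.zeros(length, dtype=bool)
    for i in indices:
        if not (1 <= i <= length):
            raise ValueError(f"feature index {i} outside 1..{length}")
        bits[i - 1] = True
    return Chromosome(bits=bits)


class FitnessEvaluator:
    """Memoized CV-accuracy fitness over a fixed normalized dataset.

    ``n_cv_evaluations`` counts actual cross-validation runs (cache
    misses); the all-zero chromosome scores 0 by convention and is never
    cross-validated.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, cfg: GAConfig):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.cfg = cfg
        _, counts = np.unique(self.y, return_counts=True)
        if counts.min() < cfg.cv_folds:
            raise ValueError(
                f"smallest class has {counts.min()} samples, fewer than "
                f"cv_folds={cfg.cv_folds}"
            )
        self._template = classifiers.make_estimator(
            classifiers.ClassifierConfig(kind=cfg.fitness_classifier)
        )
        self._cv = StratifiedKFold(
            n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed % 2**31
        )
        self._cache: dict[bytes, float] = {}
        self.n_cv_evaluations = 0

    def __call__(self, bits: np.ndarray) -> float:
        key = np.packbits(bits).tobytes()
        if key in self._cache:
            return self._cache[key]
        if not bits.any():
            fit = 0.0
        else:
            Xs = self.X[:, bits]
            accs = []
            for tr, te in self._cv.split(Xs, self.y):
                est = clone(self._template)
                est.fit(Xs[tr], self.y[tr])
                accs.append(float(np.mean(est.predict(Xs[te]) == self.y[te])))
            fit = float(np.mean(accs))
            self.n_cv_evaluations += 1
        self._cache[key] = fit
        return fit


def roulette_select(fitnesses: np.ndarray, rng: np.random.Generator) -> int:
    """Index drawn with probability proportional to fitness; uniform when
    all fitnesses are zero."""
    f = np.asarray(fitnesses, dtype=float)
    total = f.sum()
    if total <= 0:
        return int(rng.integers(len(f)))
    return int(rng.choice(len(f), p=f / total))


def two_point_crossover(
    p1: Chromosome,
    p2: Chromosome,
    rng: np.random.Generator,
    crossover_rate: float = 0.8,
) -> Chromosome:
    """Standard two-point crossover: with probability ``crossover_rate``
    the offspring is parent 1 with the segment between two random cuts
    replaced by parent 2's segment; otherwise a copy of parent 1."""
    if len(p1.bits) != len(p2.bits):
        raise ValueError("parent chromosomes must have equal length")
    child = p1.bits.copy()
    if rng.random() < crossover_rate:
        cuts = np.sort(rng.integers(0, len(child) + 1, size=2))
        child[cuts[0] : cuts[1]] = p2.bits[cuts[0] : cuts[1]]
    return Chromosome(bits=child)


def mutate(
    c: Chromosome, mutation_rate: float, rng: np.random.Generator
) -> Chromosome:
    """Independent bit flips at ``mutation_rate`` per position."""
    flips = rng.random(len(c.bits)) < mutation_rate
    return Chromosome(bits=c.bits ^ flips)


def run_ga(
    X: np.ndarray,
    y: np.ndarray,
    cfg: GAConfig,
    n_features: int | None = None,
) -> GAResult:
    """Run the steady-state GA over feature masks of the given dataset.

    Deterministic given ``cfg.seed``. ``history`` holds the population's
    best fitness after each generation (index 0 = after initialization)
    and is non-decreasing; ``best_generation`` is the generation at which
    the final best fitness first appeared (0 = already at initialization).
    """
    X = np.asarray(X, dtype=float)
    d = n_features if n_features is not None else X.shape[1]
    evaluate = FitnessEvaluator(X, y, cfg)
    rng = np.random.default_rng(cfg.seed)

    population = []
    for _ in range(cfg.population_size):
        c = Chromosome(bits=rng.random(d) < 0.5)
        c.fitness = evaluate(c.bits)
        population.append(c)

    fitnesses = np.array([c.fitness for c in population])
    history = [float(fitnesses.max())]
    best_generation = 0
    for gen in range(1, cfg.max_generations + 1):
        for _ in range(cfg.population_size):
            i1 = roulette_select(fitnesses, rng)
            i2 = roulette_select(fitnesses, rng)
            child = two_point_crossover(
                population[i1], population[i2], rng, cfg.crossover_rate
            )
            child = mutate(child, cfg.mutation_rate, rng)
            child.fitness = evaluate(child.bits)
            worst = int(np.argmin(fitnesses))
            if child.fitness > fitnesses[worst]:
                population[worst] = child
                fitnesses[worst] = child.fitness
        gen_best = float(fitnesses.max())
        if gen_best > history[-1] + 1e-15:
            best_generation = gen
        history.append(gen_best)

    best = population[int(np.argmax(fitnesses))]
    return GAResult(
        best_chromosome=best.copy(),
        best_fitness=float(best.fitness),
        best_generation=best_generation,
        history=history,
    )
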