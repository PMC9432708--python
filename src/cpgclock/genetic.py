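"""Genetic-algorithm search over fixed-size CpG subsets.

A population of "creatures" — candidate subsets of ``subset_size`` CpGs —
is evolved under survival-of-the-fittest: fitness is the held-out R² of an
elastic-net age model trained on the creature's features; each generation
the weakest half is culled, survivors breed children whose features are
drawn from the parents' pooled genes, and children mutate with some
probability by swapping a block of features for random unused CpGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from sklearn.linear_model import ElasticNet
from sklearn.metrics import r2_score

from .data_io import FeatureSet, MethylationMatrix

__all__ = ["GaConfig", "Creature", "init_population", "evaluate_fitness", "evolve", "GeneticSelector"]


@dataclass(frozen=True)
class GaConfig:
    """Evolution parameters.

    Defaults follow the large-cohort regime (3000 creatures of 50 features,
    cull 50% per generation, mutate 30% of a child's features with
    probability 0.5).  ``validation_fraction`` of samples is split off once
    per run (seeded) and reused for every fitness evaluation.  ``elitism``
    keeps the single best creature unmodified each generation, which makes
    best-fitness non-decreasing.  ``fitness_threshold`` optionally stops
    early once the best fitness reaches it.  ``polygamy`` biases parent
    sampling toward fitter survivors; ``fitness_scaled_litter`` lets fitter
    pairs contribute more children.  Both are off by default.
    """

    population_size: int = 3000
    subset_size: int = 50
    cull_fraction: float = 0.5
    mutation_feature_fraction: float = 0.3
    mutation_probability: float = 0.5
    generations: int = 20
    validation_fraction: float = 0.2
    seed: int = 0
    elitism: bool = True
    fitness_threshold: Optional[float] = None
    polygamy: bool = False
    fitness_scaled_litter: bool = False

    def __post_init__(self) -> None:
        for name in ("cull_fraction", "mutation_feature_fraction",
                     "mutation_probability", "validation_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.subset_size < 1 or self.generations < 1:
            raise ValueError("subset_size and generations must be >= 1")


@dataclass
class Creature:
    """A candidate feature subset with its (lazily computed) fitness."""

    features: tuple[str, ...]
    fitness: Optional[float] = None

    def key(self) -> frozenset:
        return frozenset(self.features)


def _fitness_model() -> ElasticNet:
    return ElasticNet(alpha=0.01, l1_ratio=0.5, max_iter=2000, tol=1e-3)


def _split(m: MethylationMatrix, cfg: GaConfig) -> tuple[np.ndarray, np.ndarray]:
    n = m.n_samples
    n_val = max(1, round(cfg.validation_fraction * n))
    if n - n_val < 2 or n_val < 3:
        raise ValueError(
            f"degenerate train/validation split for n={n} at "
            f"validation_fraction={cfg.validation_fraction}"
        )
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    return perm[n_val:], perm[:n_val]


def init_population(m: MethylationMatrix, cfg: GaConfig) -> list[Creature]:
    """Uniform random subsets of ``subset_size`` distinct CpGs, seeded."""
    if cfg.subset_size > m.n_cpgs:
        raise ValueError(
            f"subset_size={cfg.subset_size} exceeds available CpGs ({m.n_cpgs})"
        )
    rng = np.random.default_rng(cfg.seed)
    cpgs = np.asarray(m.cpg_ids, dtype=object)
    return [
        Creature(tuple(rng.choice(cpgs, size=cfg.subset_size, replace=False)))
        for _ in range(cfg.population_size)
    ]


def evaluate_fitness(
    population: list[Creature],
    m: MethylationMatrix,
    cfg: GaConfig,
    _cache: dict | None = None,
    _split_idx: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[Creature]:
    """Assign each creature the validation R² of its elastic-net age model.

    The train/validation split is derived once from the run seed and shared
    by every creature, so fitnesses are directly comparable; identical
    feature sets share a cached fitness.
    """
    train, val = _split(m, cfg) if _split_idx is None else _split_idx
    cache = {} if _cache is None else _cache
    y = m.y
    y_train, y_val = y[train], y[val]
    for creature in population:
        if creature.fitness is not None:
            continue
        key = creature.key()
        if key in cache:
            creature.fitness = cache[key]
            continue
        X = m.betas.loc[:, list(creature.features)].to_numpy(dtype=float)
        model = _fitness_model()
        model.fit(X[train], y_train)
        fit = float(r2_score(y_val, model.predict(X[val])))
        creature.fitness = cache[key] = fit
    return population


def _breed(
    survivors: list[Creature],
    cfg: GaConfig,
    all_cpgs: np.ndarray,
    rng: np.random.Generator,
) -> Creature:
    if cfg.polygamy:
        # rank-weighted parent choice: fitter survivors breed more often
        ranks = np.arange(len(survivors), 0, -1, dtype=float)
        probs = ranks / ranks.sum()
        i, j = rng.choice(len(survivors), size=2, replace=False, p=probs)
    else:
        i, j = rng.choice(len(survivors), size=2, replace=False)
    pool = np.asarray(
        sorted(set(survivors[i].features) | set(survivors[j].features)), dtype=object
    )
    if len(pool) >= cfg.subset_size:
        feats = set(rng.choice(pool, size=cfg.subset_size, replace=False))
    else:
        feats = set(pool)
        outside = np.asarray(sorted(set(all_cpgs) - feats), dtype=object)
        feats |= set(
            rng.choice(outside, size=cfg.subset_size - len(feats), replace=False)
        )
    # mutation: swap a block of features for random unused CpGs
    if rng.random() < cfg.mutation_probability:
        n_mut = int(cfg.mutation_feature_fraction * cfg.subset_size)
        if n_mut:
            current = np.asarray(sorted(feats), dtype=object)
            drop = rng.choice(current, size=n_mut, replace=False)
            feats -= set(drop)
            unused = np.asarray(sorted(set(all_cpgs) - feats), dtype=object)
            feats |= set(rng.choice(unused, size=n_mut, replace=False))
    return Creature(tuple(sorted(feats)))


def evolve(m: MethylationMatrix, cfg: GaConfig, on_generation=None) -> FeatureSet:
    """Run the full evolutionary loop and return the best creature's subset.

    Each generation: evaluate fitness, cull the ``cull_fraction`` weakest,
    refill to ``population_size`` by breeding survivors, mutate children at
    random.  Returns the best creature's features; its fitness is recorded
    in the provenance string.

    ``on_generation(generation, evaluated, survivors, refilled)`` is an
    optional observer called once per generation with the sorted evaluated
    population, the post-cull survivors and the refilled population.
    """
    rng = np.random.default_rng(cfg.seed)
    split_idx = _split(m, cfg)
    cache: dict = {}
    all_cpgs = np.asarray(m.cpg_ids, dtype=object)
    population = init_population(m, cfg)
    best: Creature | None = None

    for generation in range(cfg.generations):
        evaluate_fitness(population, m, cfg, _cache=cache, _split_idx=split_idx)
        population.sort(key=lambda c: (-c.fitness, c.features))
        if best is None or population[0].fitness > best.fitness:
            best = Creature(population[0].features, population[0].fitness)
        if cfg.fitness_threshold is not None and best.fitness >= cfg.fitness_threshold:
            break
        n_cull = int(cfg.cull_fraction * len(population))
        survivors = population[: len(population) - n_cull]
        if cfg.fitness_scaled_litter and not cfg.polygamy:
            # handled inside _breed via rank weighting; simplest coupling
            cfg_breed = replace(cfg, polygamy=True)
        else:
            cfg_breed = cfg
        if cfg.elitism:
            # survivors (best creature included) pass through unmodified
            n_children = cfg.population_size - len(survivors)
            refilled = survivors + [
                _breed(survivors, cfg_breed, all_cpgs, rng) for _ in range(n_children)
            ]
        else:
            # generational replacement: the whole next population is bred
            refilled = [
                _breed(survivors, cfg_breed, all_cpgs, rng)
                for _ in range(cfg.population_size)
            ]
        if on_generation is not None:
            on_generation(generation, list(population), list(survivors), list(refilled))
        population = refilled

    evaluate_fitness(population, m, cfg, _cache=cache, _split_idx=split_idx)
    population.sort(key=lambda c: (-c.fitness, c.features))
    if population[0].fitness > best.fitness:
        best = population[0]
    return FeatureSet(
        tuple(sorted(best.features)),
        provenance=f"genetic_algorithm(best_fitness={best.fitness:.4f}, "
        f"generations={cfg.generations}, population={cfg.population_size})",
    )


@dataclass
class GeneticSelector:
    cfg: GaConfig = GaConfig()
    name: str = "genetic"

    def select(self, m: MethylationMatrix) -> FeatureSet:
        return evolve(m, self.cfg)
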