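"""Generational evolutionary optimization of CTRNN parameters.

Genotypes are real vectors in [0, 1]^D (D = N^2 + 4N for an N-neuron
network) decoded linearly into parameter ranges.  Each generation the top
1% of the population is copied unchanged (elitism) and the remainder is
produced by fitness-proportionate selection of two parents, uniform
crossover, and additive Gaussian mutation (std 0.01) clipped back to
[0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np

from .ctrnn import NetworkParams
from . import tasks

Genotype = np.ndarray


@dataclass(frozen=True)
class ParameterRanges:
    """Linear decoding ranges per parameter group.

    Defaults are conventional for evolved CTRNNs: weights and biases in
    [-16, 16], time constants in [0.5, 10] (comfortably stable at dt=0.02).
    """

    weights: Tuple[float, float] = (-16.0, 16.0)
    input_weights: Tuple[float, float] = (-16.0, 16.0)
    output_weights: Tuple[float, float] = (-16.0, 16.0)
    taus: Tuple[float, float] = (0.5, 10.0)
    biases: Tuple[float, float] = (-16.0, 16.0)


def genotype_length(n_neurons: int) -> int:
    return n_neurons * n_neurons + 4 * n_neurons


def decode(genotype: Genotype, n_neurons: int = 3, ranges: ParameterRanges = ParameterRanges()) -> NetworkParams:
    """Map a genotype in [0, 1]^D to network parameters.

    Gene order: recurrent weights (row-major, N^2), input weights (N),
    output weights (N), time constants (N), biases (N); each gene ``g``
    maps to ``low + g * (high - low)`` of its group's range.
    """
    g = np.asarray(genotype, dtype=float).ravel()
    if g.shape != (genotype_length(n_neurons),):
        raise ValueError("genotype length does not match network size")
    if np.any(g < 0) or np.any(g > 1):
        raise ValueError("genes must lie in [0, 1]")

    def scale(vals, lo_hi):
        lo, hi = lo_hi
        return lo + vals * (hi - lo)

    n = n_neurons
    return NetworkParams(
        weights=scale(g[: n * n], ranges.weights).reshape(n, n),
        input_weights=scale(g[n * n : n * n + n], ranges.input_weights),
        output_weights=scale(g[n * n + n : n * n + 2 * n], ranges.output_weights),
        taus=scale(g[n * n + 2 * n : n * n + 3 * n], ranges.taus),
        biases=scale(g[n * n + 3 * n :], ranges.biases),
    )


@dataclass
class EvolConfig:
    population_size: int = 100
    generations: int = 50
    elite_fraction: float = 0.01
    mutation_std: float = 0.01
    rng_seed: int = 0
    stop_at_fitness: Optional[float] = None

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not (0 < self.elite_fraction < 1):
            raise ValueError("elite_fraction must be in (0, 1)")
        if self.mutation_std < 0:
            raise ValueError("mutation_std must be >= 0")


@dataclass
class EvolResult:
    best_genotype: Genotype
    best_fitness: float
    best_fitness_history: np.ndarray
    mean_fitness_history: np.ndarray

    @property
    def n_generations(self) -> int:
        return len(self.best_fitness_history)


def selection_probabilities(fitness: np.ndarray) -> np.ndarray:
    """Fitness-proportionate probabilities after shifting by the minimum.

    If all shifted fitnesses are zero (a flat population) selection falls
    back to uniform.
    """
    shifted = fitness - fitness.min()
    total = shifted.sum()
    if total <= 0:
        return np.full(len(fitness), 1.0 / len(fitness))
    return shifted / total


def evolve(fitness_fn: Callable[[Genotype], float], genotype_len: int, config: EvolConfig) -> EvolResult:
    """Run the generational algorithm; deterministic given the seed.

    ``stop_at_fitness`` stops as soon as the best-of-population fitness
    reaches the given target (the history then ends at that generation).
    """
    rng = np.random.default_rng(config.rng_seed)
    pop = rng.random((config.population_size, genotype_len))
    n_elite = max(1, round(config.elite_fraction * config.population_size))

    best_hist, mean_hist = [], []
    best_g: Optional[Genotype] = None
    best_f = -np.inf
    for _gen in range(config.generations):
        fitness = np.array([fitness_fn(g) for g in pop])
        if np.any(np.isnan(fitness)):
            bad = int(np.argmax(np.isnan(fitness)))
            raise FloatingPointError(f"NaN fitness for genotype {pop[bad]!r}")
        order = np.argsort(fitness)[::-1]
        if fitness[order[0]] > best_f:
            best_f = float(fitness[order[0]])
            best_g = pop[order[0]].copy()
        best_hist.append(best_f)
        mean_hist.append(float(fitness.mean()))
        if config.stop_at_fitness is not None and best_f >= config.stop_at_fitness:
            break
        probs = selection_probabilities(fitness)
        elites = pop[order[:n_elite]].copy()
        n_children = config.population_size - n_elite
        parents_a = pop[rng.choice(config.population_size, size=n_children, p=probs)]
        parents_b = pop[rng.choice(config.population_size, size=n_children, p=probs)]
        take_a = rng.random((n_children, genotype_len)) < 0.5
        children = np.where(take_a, parents_a, parents_b)
        children = children + rng.normal(0.0, config.mutation_std, size=children.shape)
        np.clip(children, 0.0, 1.0, out=children)
        pop = np.vstack([elites, children])
    return EvolResult(
        best_genotype=best_g,
        best_fitness=best_f,
        best_fitness_history=np.array(best_hist),
        mean_fitness_history=np.array(mean_hist),
    )


CPG_SUCCESS_FITNESS = 30.0


def run_optimization(
    task: str,
    config: Optional[EvolConfig] = None,
    n_neurons: int = 3,
    ranges: ParameterRanges = ParameterRanges(),
    trials: Optional[list] = None,
    early_stop: bool = True,
):
    """Optimize a network for one task.

    ``task`` is ``"cpg"`` (default 50 generations, success iff best fitness
    reaches 30) or ``"relational"`` (default 500 generations, fitness = task
    performance on the 2-probe battery).  Returns ``(result, params,
    success)`` where ``success`` is the CPG criterion for the CPG task and
    ``True`` otherwise.
    """
    if task == "cpg":
        if config is None:
            config = EvolConfig(generations=50)
        if config.stop_at_fitness is None and early_stop:
            config.stop_at_fitness = CPG_SUCCESS_FITNESS

        def fitness_fn(g):
            return tasks.cpg_fitness(decode(g, n_neurons, ranges))

    elif task == "relational":
        if config is None:
            config = EvolConfig(generations=500)
        battery = trials if trials is not None else tasks.make_relational_trials("2probe")
        inputs, targets, probe_mask = tasks.relational_input_matrix(battery)

        def fitness_fn(g):
            return tasks.relational_fitness(decode(g, n_neurons, ranges), inputs, targets, probe_mask)

    else:
        raise ValueError(f"unknown task {task!r}")

    result = evolve(fitness_fn, genotype_length(n_neurons), config)
    params = decode(result.best_genotype, n_neurons, ranges)
    success = result.best_fitness >= CPG_SUCCESS_FITNESS if task == "cpg" else True
    return result, params, success
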