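"""Optimizer main loops: the hybrid, plus CSA-only and SMO-only baselines.

Per generation the hybrid applies: local leader phase -> selection
probabilities + global leader phase -> leader learning -> local leader
decision (cuckoo search on stagnant groups) -> global leader decision
(group split/merge). The swarm starts as a single group; groups emerge only
through global stagnation. Runs terminate after ``n_generations`` or as soon
as the global leader reaches accuracy 100 (fitness cannot improve further).

Multi-run statistics (mean/SD of the per-run best accuracy) use sequential
seed offsets from the base seed, so any run can be reproduced in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .cuckoo import LevyParams, abandon_nests, generate_cuckoo, pa_schedule
from .datasets_io import ExpressionDataset
from .errors import ConfigError
from .fitness import pool_mask_to_gene_mask
from .mrmr import GenePool
from .smo_phases import (
    classic_local_leader_decision,
    global_leader_decision,
    global_leader_phase,
    local_leader_decision,
    local_leader_phase,
    update_leaders,
)
from .swarm_core import (
    CSSMOConfig,
    FitnessCache,
    SelectionResult,
    better_result,
    binarize,
    init_swarm,
)

logger = logging.getLogger(__name__)

ALGORITHMS = ("cssmo", "csa", "smo")
# phases that may propose a new position for each member in one generation
_PHASES_PER_GENERATION = 4  # LLP, GLP, LLD (cuckoo: eggs+abandon), GLD


class _BestTracker:
    """Keeps the best-ever (fitness, mask, position) under the reporting
    tie-break: higher fitness, then smaller subset, then lexicographic mask."""

    def __init__(self, threshold: float):
        self.threshold = threshold
        self.fitness = -np.inf
        self.mask: np.ndarray | None = None

    def offer(self, position: np.ndarray, fitness: float) -> None:
        mask = binarize(position, self.threshold)
        if self.mask is None or better_result(fitness, mask, self.fitness, self.mask):
            self.fitness = fitness
            self.mask = mask


def _result_from(
    tracker: _BestTracker,
    trace: list[float],
    cache: FitnessCache,
    dataset: ExpressionDataset,
    pool: GenePool,
    config: CSSMOConfig,
    algorithm: str,
) -> SelectionResult:
    assert tracker.mask is not None
    return SelectionResult(
        best_mask=pool_mask_to_gene_mask(tracker.mask, pool, dataset.n_genes),
        best_fitness=float(tracker.fitness),
        fitness_trace=tuple(trace),
        evaluations=cache.evaluations,
        config_echo=config,
        pool=pool,
        seed=config.seed,
        algorithm=algorithm,
    )


def run_cssmo(
    dataset: ExpressionDataset,
    pool: GenePool,
    fitness_fn,
    config: CSSMOConfig,
) -> SelectionResult:
    """One hybrid run; see the module docstring for the phase sequence."""
    if pool.size < 1:
        raise ConfigError("gene pool is empty")
    rng = np.random.default_rng(config.seed)
    cache = FitnessCache(fitness_fn)
    evaluate = lambda p: cache.evaluate_position(p, config.binarize_threshold)

    swarm = init_swarm(pool.size, config, cache, rng)
    tracker = _BestTracker(config.binarize_threshold)
    for i in range(swarm.size):
        tracker.offer(swarm.positions[i], float(swarm.fitness[i]))

    trace: list[float] = []
    for gen in range(config.n_generations):
        pa = pa_schedule(gen, config.n_generations, config.pa_min, config.pa_max)
        local_leader_phase(swarm, config.pr, evaluate, rng)
        global_leader_phase(swarm, evaluate, rng, all_dims=config.glp_all_dims)
        update_leaders(swarm)
        local_leader_decision(swarm, config, evaluate, rng, pa)
        global_leader_decision(swarm, config)
        for i in range(swarm.size):
            tracker.offer(swarm.positions[i], float(swarm.fitness[i]))
        tracker.offer(swarm.global_leader_pos, swarm.global_leader_fit)
        trace.append(float(swarm.global_leader_fit))
        logger.info(
            "gen=%d best=%.4f evaluations=%d groups=%d",
            gen, swarm.global_leader_fit, cache.evaluations, swarm.n_groups,
        )
        if swarm.global_leader_fit >= 100.0:
            break

    budget = (1 + _PHASES_PER_GENERATION * (1 + config.n_eggs)) * swarm.size * (
        config.n_generations + 1
    )
    assert cache.evaluations <= budget, "evaluation budget exceeded"
    return _result_from(tracker, trace, cache, dataset, pool, config, "cssmo")


def run_csa(
    dataset: ExpressionDataset,
    pool: GenePool,
    fitness_fn,
    config: CSSMOConfig,
) -> SelectionResult:
    """Standalone cuckoo search baseline: Levy walks toward the global best
    plus per-generation abandonment with the scheduled pa."""
    if pool.size < 1:
        raise ConfigError("gene pool is empty")
    rng = np.random.default_rng(config.seed)
    cache = FitnessCache(fitness_fn)
    evaluate = lambda p: cache.evaluate_position(p, config.binarize_threshold)
    params = LevyParams(beta=config.levy_beta, alpha_step=config.alpha_step)

    positions = rng.random((config.n_nests, pool.size))
    fitness = np.array([evaluate(p) for p in positions])
    best = int(np.argmax(fitness))
    best_pos, best_fit = positions[best].copy(), float(fitness[best])
    tracker = _BestTracker(config.binarize_threshold)
    for i in range(positions.shape[0]):
        tracker.offer(positions[i], float(fitness[i]))

    trace: list[float] = []
    for gen in range(config.n_generations):
        pa = pa_schedule(gen, config.n_generations, config.pa_min, config.pa_max)
        for i in range(positions.shape[0]):
            egg = generate_cuckoo(positions[i], best_pos, params, rng)
            target = int(rng.integers(positions.shape[0]))
            egg_fit = evaluate(egg)
            if egg_fit > fitness[target]:
                positions[target] = egg
                fitness[target] = egg_fit
                tracker.offer(egg, float(egg_fit))
        elite = int(np.argmax(fitness))
        positions, abandoned = abandon_nests(positions, pa, rng, best_idx=elite)
        for i in np.nonzero(abandoned)[0]:
            fitness[i] = evaluate(positions[i])
            tracker.offer(positions[i], float(fitness[i]))
        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > best_fit:
            best_pos, best_fit = positions[gen_best].copy(), float(fitness[gen_best])
        trace.append(best_fit)
        if best_fit >= 100.0:
            break

    return _result_from(tracker, trace, cache, dataset, pool, config, "csa")


def run_smo(
    dataset: ExpressionDataset,
    pool: GenePool,
    fitness_fn,
    config: CSSMOConfig,
) -> SelectionResult:
    """Classic six-phase spider monkey baseline (random-reinit local decision)."""
    if pool.size < 1:
        raise ConfigError("gene pool is empty")
    rng = np.random.default_rng(config.seed)
    cache = FitnessCache(fitness_fn)
    evaluate = lambda p: cache.evaluate_position(p, config.binarize_threshold)

    swarm = init_swarm(pool.size, config, cache, rng)
    tracker = _BestTracker(config.binarize_threshold)
    for i in range(swarm.size):
        tracker.offer(swarm.positions[i], float(swarm.fitness[i]))

    trace: list[float] = []
    for gen in range(config.n_generations):
        local_leader_phase(swarm, config.pr, evaluate, rng)
        global_leader_phase(swarm, evaluate, rng, all_dims=config.glp_all_dims)
        update_leaders(swarm)
        classic_local_leader_decision(swarm, config, evaluate, rng)
        global_leader_decision(swarm, config)
        for i in range(swarm.size):
            tracker.offer(swarm.positions[i], float(swarm.fitness[i]))
        tracker.offer(swarm.global_leader_pos, swarm.global_leader_fit)
        trace.append(float(swarm.global_leader_fit))
        if swarm.global_leader_fit >= 100.0:
            break

    return _result_from(tracker, trace, cache, dataset, pool, config, "smo")


def run_baseline(
    algorithm: str,
    dataset: ExpressionDataset,
    pool: GenePool,
    fitness_fn,
    config: CSSMOConfig,
) -> SelectionResult:
    if algorithm == "csa":
        return run_csa(dataset, pool, fitness_fn, config)
    if algorithm == "smo":
        return run_smo(dataset, pool, fitness_fn, config)
    if algorithm == "cssmo":
        return run_cssmo(dataset, pool, fitness_fn, config)
    raise ConfigError(f"unknown algorithm {algorithm!r}")


@dataclass(frozen=True)
class RunSummary:
    """Per-run best accuracies with their mean/sample-SD and the best run."""

    per_run_best_fitness: tuple[float, ...]
    mean: float
    sd: float
    best_overall: SelectionResult

    def __post_init__(self) -> None:
        arr = np.asarray(self.per_run_best_fitness)
        assert abs(self.mean - float(arr.mean())) < 1e-12
        expected_sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        assert abs(self.sd - expected_sd) < 1e-12


def run_many(
    dataset: ExpressionDataset,
    pool: GenePool,
    fitness_fn,
    config: CSSMOConfig,
    n_runs: int | None = None,
    algorithm: str = "cssmo",
) -> RunSummary:
    """Repeat runs with seeds ``config.seed + 0 .. + n_runs-1``; summarize."""
    n_runs = config.n_runs if n_runs is None else n_runs
    if n_runs < 1:
        raise ConfigError("n_runs must be >= 1")
    results = []
    for offset in range(n_runs):
        run_config = replace(config, seed=config.seed + offset)
        results.append(run_baseline(algorithm, dataset, pool, fitness_fn, run_config))
    per_run = tuple(r.best_fitness for r in results)
    best = results[0]
    for r in results[1:]:
        if better_result(r.best_fitness, r.best_mask, best.best_fitness, best.best_mask):
            best = r
    arr = np.asarray(per_run)
    return RunSummary(
        per_run_best_fitness=per_run,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        best_overall=best,
    )
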