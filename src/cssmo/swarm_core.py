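"""Shared population state for the swarm optimizers.

Members live in the continuous unit cube [0,1]^d (d = pool size) and decode
to gene subsets by strict thresholding at 0.5. Fitness is the LOOCV accuracy
of the decoded subset on the 0-100 scale and is maximized; identical masks
share one classifier evaluation through a cache keyed by the mask bytes.

The swarm carries the spider-monkey bookkeeping: a contiguous partition into
groups, per-group local leaders with stagnation counters, and the global
leader with its counter. Elitism is structural -- the global leader is only
ever replaced by a strictly fitter position.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .errors import ConfigError, ValidationError
from .mrmr import GenePool


@dataclass(frozen=True)
class CSSMOConfig:
    """Control parameters of the hybrid optimizer.

    Defaults are the published operating point: population 50, 10 cuckoo
    rounds ("eggs") per local search, 200 generations, discovery probability
    ramped 0.3 -> 0.5, Levy step scale 1, at most 5 groups, global leader
    limit 50, local leader limit 1500, 100 runs. ``pr`` (per-dimension
    perturbation rate of the local leader phase) defaults to 0.3.
    """

    n_nests: int = 50
    n_eggs: int = 10
    n_generations: int = 200
    pa_min: float = 0.3
    pa_max: float = 0.5
    alpha_step: float = 1.0
    swarm_size: int = 50
    max_groups: int = 5
    global_leader_limit: int = 50
    local_leader_limit: int = 1500
    n_runs: int = 100
    pr: float = 0.3
    levy_beta: float = 1.5
    binarize_threshold: float = 0.5
    glp_all_dims: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.pa_min <= self.pa_max <= 1):
            raise ConfigError("need 0 <= pa_min <= pa_max <= 1")
        if not (0 < self.pr < 1):
            raise ConfigError("pr must be in (0,1)")
        if not (0 < self.binarize_threshold < 1):
            raise ConfigError("binarize_threshold must be in (0,1)")
        if not (1 < self.levy_beta <= 2):
            raise ConfigError("levy_beta must be in (1,2]")
        for name in (
            "n_nests", "n_eggs", "n_generations", "swarm_size", "max_groups",
            "global_leader_limit", "local_leader_limit", "n_runs",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "CSSMOConfig":
        return cls(**payload)


def binarize(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Decode a continuous position to a gene mask: coordinate > threshold.

    An all-zero decode is repaired by selecting pool-local index 0, which by
    GenePool construction is the top-ranked (maximally relevant) gene.
    """
    if not (0 < threshold < 1):
        raise ConfigError("threshold must be in (0,1)")
    mask = (np.asarray(position) > threshold).astype(np.int8)
    if mask.sum() == 0:
        mask = mask.copy()
        mask[0] = 1
    return mask


def compute_selection_probability(fitness: np.ndarray) -> np.ndarray:
    """Global-leader-phase selection probability: 0.9 * fit/max_fit + 0.1.

    The fittest member gets exactly 1.0; if every fitness is zero the floor
    0.1 is returned uniformly.
    """
    fitness = np.asarray(fitness, dtype=float)
    if np.any(fitness < 0):
        raise ValidationError("fitness must be non-negative")
    top = fitness.max()
    if top == 0:
        return np.full(fitness.shape, 0.1)
    return 0.9 * (fitness / top) + 0.1


class FitnessCache:
    """Memoizes mask -> fitness; counts classifier evaluations (cache misses)."""

    def __init__(self, fitness_fn):
        self._fn = fitness_fn
        self._table: dict[bytes, float] = {}
        self.evaluations = 0

    def __call__(self, mask: np.ndarray) -> float:
        key = np.asarray(mask, dtype=np.int8).tobytes()
        if key not in self._table:
            self._table[key] = float(self._fn(mask))
            self.evaluations += 1
        return self._table[key]

    def evaluate_position(self, position: np.ndarray, threshold: float = 0.5) -> float:
        return self(binarize(position, threshold))


@dataclass
class Swarm:
    """Mutable optimizer population (positions are rows of an (N, d) array)."""

    positions: np.ndarray
    fitness: np.ndarray
    group_of: np.ndarray
    n_groups: int
    local_leader_pos: list[np.ndarray]
    local_leader_fit: list[float]
    global_leader_pos: np.ndarray
    global_leader_fit: float
    local_limit_count: list[int]
    global_limit_count: int = 0

    @property
    def size(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    def members_of(self, g: int) -> np.ndarray:
        return np.nonzero(self.group_of == g)[0]

    def check_invariants(self, max_groups: int | None = None) -> None:
        if not (np.all(self.positions >= 0) and np.all(self.positions <= 1)):
            raise ValidationError("positions escaped [0,1]^d")
        if self.n_groups < 1 or (max_groups and self.n_groups > max_groups):
            raise ValidationError("group count out of range")
        for g in range(self.n_groups):
            if self.members_of(g).size == 0:
                raise ValidationError(f"group {g} empty")
        if sorted(np.unique(self.group_of)) != list(range(self.n_groups)):
            raise ValidationError("group labels do not partition the swarm")
        # note: a member may transiently exceed the stored global leader until
        # the next leader-learning pass; elitism is the monotone leader trace


def contiguous_partition(n_members: int, n_groups: int) -> np.ndarray:
    """Assign members 0..N-1 to n_groups near-equal contiguous blocks."""
    group_of = np.empty(n_members, dtype=int)
    for g, block in enumerate(np.array_split(np.arange(n_members), n_groups)):
        group_of[block] = g
    return group_of


def init_swarm(
    dim: int, config: CSSMOConfig, cache: FitnessCache, rng: np.random.Generator
) -> Swarm:
    """Uniform-random population, one group, leaders learned greedily."""
    n = config.swarm_size
    positions = rng.random((n, dim))
    fitness = np.array(
        [cache.evaluate_position(p, config.binarize_threshold) for p in positions]
    )
    best = int(np.argmax(fitness))
    return Swarm(
        positions=positions,
        fitness=fitness,
        group_of=np.zeros(n, dtype=int),
        n_groups=1,
        local_leader_pos=[positions[best].copy()],
        local_leader_fit=[float(fitness[best])],
        global_leader_pos=positions[best].copy(),
        global_leader_fit=float(fitness[best]),
        local_limit_count=[0],
    )


def evaluate_swarm(swarm: Swarm, cache: FitnessCache, threshold: float = 0.5) -> Swarm:
    """(Re)populate every member's fitness through the cache."""
    swarm.fitness = np.array(
        [cache.evaluate_position(p, threshold) for p in swarm.positions]
    )
    return swarm


def mask_key(mask: np.ndarray) -> bytes:
    return np.asarray(mask, dtype=np.int8).tobytes()


def better_result(fit_a: float, mask_a: np.ndarray, fit_b: float, mask_b: np.ndarray) -> bool:
    """True if (fit_a, mask_a) should be reported over (fit_b, mask_b).

    Higher fitness wins; ties prefer the smaller subset, then the
    lexicographically smaller mask (deterministic reporting).
    """
    if fit_a != fit_b:
        return fit_a > fit_b
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    if na != nb:
        return na < nb
    return mask_key(mask_a) < mask_key(mask_b)


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one optimizer run, decoded to the original gene space."""

    best_mask: np.ndarray  # length n_genes of the original dataset
    best_fitness: float
    fitness_trace: tuple[float, ...]
    evaluations: int
    config_echo: CSSMOConfig
    pool: GenePool
    seed: int
    algorithm: str = "cssmo"

    def __post_init__(self) -> None:
        mask = np.asarray(self.best_mask, dtype=np.int8)
        object.__setattr__(self, "best_mask", mask)
        object.__setattr__(self, "fitness_trace", tuple(self.fitness_trace))
        if mask.sum() == 0:
            raise ValidationError("best_mask must be non-empty")
        if np.any(np.diff(self.fitness_trace) < 0):
            raise ValidationError("fitness trace must be non-decreasing")
        support = set(np.nonzero(mask)[0].tolist())
        if not support <= set(self.pool.selected_idx):
            raise ValidationError("mask support outside the mRMR pool")

    @property
    def selected_genes(self) -> tuple[int, ...]:
        return tuple(int(i) for i in np.nonzero(self.best_mask)[0])

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "algorithm": self.algorithm,
            "best_mask": self.best_mask.astype(int).tolist(),
            "best_fitness": self.best_fitness,
            "fitness_trace": list(self.fitness_trace),
            "evaluations": self.evaluations,
            "config": self.config_echo.to_dict(),
            "pool": self.pool.to_dict(),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SelectionResult":
        return cls(
            best_mask=np.asarray(payload["best_mask"], dtype=np.int8),
            best_fitness=payload["best_fitness"],
            fitness_trace=tuple(payload["fitness_trace"]),
            evaluations=payload["evaluations"],
            config_echo=CSSMOConfig.from_dict(payload["config"]),
            pool=GenePool.from_dict(payload["pool"]),
            seed=payload["seed"],
            algorithm=payload.get("algorithm", "cssmo"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)
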