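"""Cuckoo search with Mantegna Levy flights.

Used standalone as the CSA baseline and, inside the hybrid, as the
local-leader optimizer invoked when a group stagnates. New candidate nests
("eggs") are random walks whose step lengths follow a heavy-tailed Levy
distribution, so occasional long jumps can escape local optima; a fraction
``pa`` of non-best nests is abandoned and re-randomized each round.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gamma, pi, sin

import numpy as np

from .errors import ConfigError, ValidationError


@dataclass(frozen=True)
class LevyParams:
    beta: float = 1.5
    alpha_step: float = 1.0

    def __post_init__(self) -> None:
        if not (1 < self.beta <= 2):
            raise ConfigError("beta must be in (1, 2]")
        if self.alpha_step < 0:
            raise ConfigError("alpha_step must be >= 0")


def mantegna_sigma(beta: float) -> float:
    """Closed-form sigma_u of the Mantegna generator (approx. 0.6966 at beta=1.5)."""
    num = gamma(1 + beta) * sin(pi * beta / 2)
    den = gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
    return (num / den) ** (1 / beta)


def levy_step(d: int, params: LevyParams, rng: np.random.Generator) -> np.ndarray:
    """Draw a d-dimensional Levy step: alpha * u / |v|^(1/beta)."""
    if d < 1:
        raise ValidationError("d must be >= 1")
    sigma = mantegna_sigma(params.beta)
    u = rng.normal(0.0, sigma, size=d)
    v = rng.normal(0.0, 1.0, size=d)
    return params.alpha_step * u / np.abs(v) ** (1.0 / params.beta)


def generate_cuckoo(
    current: np.ndarray,
    guide: np.ndarray,
    params: LevyParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Levy walk scaled by the displacement from the guide, clipped to [0,1]^d.

    A nest sitting on its guide is a fixed point (zero displacement).
    """
    current = np.asarray(current, dtype=float)
    guide = np.asarray(guide, dtype=float)
    if current.shape != guide.shape:
        raise ValidationError("position dimension mismatch")
    step = levy_step(current.size, params, rng)
    return np.clip(current + step * (current - guide), 0.0, 1.0)


def abandon_nests(
    positions: np.ndarray,
    pa: float,
    rng: np.random.Generator,
    best_idx: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Re-randomize each nest independently with probability ``pa``.

    The best nest (``best_idx``) is never abandoned. Returns the new
    positions and the boolean vector of abandoned nests.
    """
    if not (0 <= pa <= 1):
        raise ConfigError("pa must be in [0,1]")
    positions = np.asarray(positions, dtype=float)
    abandoned = rng.random(positions.shape[0]) < pa
    if best_idx is not None:
        abandoned[best_idx] = False
    out = positions.copy()
    if abandoned.any():
        out[abandoned] = rng.random((int(abandoned.sum()), positions.shape[1]))
    return out, abandoned


def pa_schedule(gen: int, total_gens: int, pa_min: float, pa_max: float) -> float:
    """Linear ramp of the discovery probability from pa_min to pa_max."""
    if total_gens < 1 or not (0 <= gen <= total_gens):
        raise ValidationError("need 0 <= gen <= total_gens, total_gens >= 1")
    return pa_min + (pa_max - pa_min) * gen / total_gens


def cuckoo_local_search(
    positions: np.ndarray,
    leader: np.ndarray,
    evaluate,
    n_eggs: int,
    pa: float,
    params: LevyParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Refine a group of positions by ``n_eggs`` cuckoo rounds.

    Each round proposes one egg per member (Levy walk guided by the current
    leader), greedily replaces a uniformly chosen nest when the egg is
    fitter, then abandons a ``pa`` fraction of non-best nests. Returns
    (positions, fitness, leader_position, leader_fitness); the leader's
    fitness never decreases.

    ``evaluate`` maps a position to its (cached) fitness.
    """
    if n_eggs < 1:
        raise ConfigError("n_eggs must be >= 1")
    positions = np.asarray(positions, dtype=float).copy()
    if positions.shape[0] == 0:
        raise ValidationError("group must be non-empty")
    fitness = np.array([evaluate(p) for p in positions])
    leader = np.asarray(leader, dtype=float).copy()
    leader_fit = float(evaluate(leader))

    for _ in range(n_eggs):
        for i in range(positions.shape[0]):
            egg = generate_cuckoo(positions[i], leader, params, rng)
            target = int(rng.integers(positions.shape[0]))
            egg_fit = evaluate(egg)
            if egg_fit > fitness[target]:
                positions[target] = egg
                fitness[target] = egg_fit
        best = int(np.argmax(fitness))
        positions, abandoned = abandon_nests(positions, pa, rng, best_idx=best)
        if abandoned.any():
            for i in np.nonzero(abandoned)[0]:
                fitness[i] = evaluate(positions[i])
        round_best = int(np.argmax(fitness))
        if fitness[round_best] > leader_fit:
            leader = positions[round_best].copy()
            leader_fit = float(fitness[round_best])

    return positions, fitness, leader, leader_fit
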