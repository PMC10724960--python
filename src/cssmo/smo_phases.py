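"""The spider-monkey phases.

Position updates use the classic forms (fresh U(0,1)/U(-1,1) coefficients
per perturbed dimension):

  LLP:  x_j <- x_j + U(0,1) (LL_j - x_j) + U(-1,1) (x_rj - x_j)   w.p. pr per dim
  GLP:  one random dimension, member selected w.p. prob_i,
        x_j <- x_j + U(0,1) (GL_j - x_j) + U(-1,1) (x_rj - x_j)

Every proposal is greedily accepted only if strictly fitter. Leader learning
treats ties as non-improvement, so stagnation counters keep driving
exploration. The local-leader decision hands the stagnant group to cuckoo
search (the hybrid's defining move); the global-leader decision splits the
swarm into one more contiguous group, or merges everything back to a single
group once the maximum is reached.
"""

from __future__ import annotations

import numpy as np

from .cuckoo import LevyParams, cuckoo_local_search
from .swarm_core import (
    CSSMOConfig,
    FitnessCache,
    Swarm,
    compute_selection_probability,
    contiguous_partition,
)


def _greedy_move(swarm: Swarm, i: int, proposal: np.ndarray, evaluate) -> None:
    new_fit = evaluate(proposal)
    if new_fit > swarm.fitness[i]:
        swarm.positions[i] = proposal
        swarm.fitness[i] = new_fit


def local_leader_phase(
    swarm: Swarm, pr: float, evaluate, rng: np.random.Generator
) -> Swarm:
    """Per-dimension stochastic move toward the local leader, greedy accept."""
    for g in range(swarm.n_groups):
        members = swarm.members_of(g)
        leader = swarm.local_leader_pos[g]
        for i in members:
            perturb = rng.random(swarm.dim) < pr
            if not perturb.any():
                continue
            u = rng.random(swarm.dim)
            w = rng.uniform(-1.0, 1.0, size=swarm.dim)
            x = swarm.positions[i]
            proposal = x.copy()
            delta = u * (leader - x)
            if members.size > 1:
                others = members[members != i]
                r = others[int(rng.integers(others.size))]
                delta = delta + w * (swarm.positions[r] - x)
            proposal[perturb] = np.clip(x[perturb] + delta[perturb], 0.0, 1.0)
            _greedy_move(swarm, i, proposal, evaluate)
    return swarm


def global_leader_phase(
    swarm: Swarm, evaluate, rng: np.random.Generator, all_dims: bool = False
) -> Swarm:
    """Fitness-proportional updates toward the global leader, greedy accept."""
    prob = compute_selection_probability(swarm.fitness)
    for i in range(swarm.size):
        if rng.random() >= prob[i]:
            continue
        members = swarm.members_of(swarm.group_of[i])
        x = swarm.positions[i]
        proposal = x.copy()
        dims = np.arange(swarm.dim) if all_dims else np.array(
            [int(rng.integers(swarm.dim))]
        )
        for j in dims:
            u = rng.random()
            w = rng.uniform(-1.0, 1.0)
            val = x[j] + u * (swarm.global_leader_pos[j] - x[j])
            if members.size > 1:
                others = members[members != i]
                r = others[int(rng.integers(others.size))]
                val += w * (swarm.positions[r][j] - x[j])
            proposal[j] = np.clip(val, 0.0, 1.0)
        _greedy_move(swarm, i, proposal, evaluate)
    return swarm


def update_leaders(swarm: Swarm) -> Swarm:
    """Greedy leader learning; ties count as stagnation (counter += 1)."""
    for g in range(swarm.n_groups):
        members = swarm.members_of(g)
        best = members[int(np.argmax(swarm.fitness[members]))]
        if swarm.fitness[best] > swarm.local_leader_fit[g]:
            swarm.local_leader_pos[g] = swarm.positions[best].copy()
            swarm.local_leader_fit[g] = float(swarm.fitness[best])
            swarm.local_limit_count[g] = 0
        else:
            swarm.local_limit_count[g] += 1
    best = int(np.argmax(swarm.fitness))
    if swarm.fitness[best] > swarm.global_leader_fit:
        swarm.global_leader_pos = swarm.positions[best].copy()
        swarm.global_leader_fit = float(swarm.fitness[best])
        swarm.global_limit_count = 0
    else:
        swarm.global_limit_count += 1
    return swarm


def local_leader_decision(
    swarm: Swarm,
    config: CSSMOConfig,
    evaluate,
    rng: np.random.Generator,
    pa: float,
) -> Swarm:
    """Hybrid local-leader decision: stagnant groups forage via cuckoo search."""
    params = LevyParams(beta=config.levy_beta, alpha_step=config.alpha_step)
    for g in range(swarm.n_groups):
        if swarm.local_limit_count[g] <= config.local_leader_limit:
            continue
        members = swarm.members_of(g)
        positions, fitness, leader, leader_fit = cuckoo_local_search(
            swarm.positions[members],
            swarm.local_leader_pos[g],
            evaluate,
            n_eggs=config.n_eggs,
            pa=pa,
            params=params,
            rng=rng,
        )
        swarm.positions[members] = positions
        swarm.fitness[members] = fitness
        swarm.local_leader_pos[g] = leader
        swarm.local_leader_fit[g] = leader_fit
        swarm.local_limit_count[g] = 0
        if leader_fit > swarm.global_leader_fit:
            swarm.global_leader_pos = leader.copy()
            swarm.global_leader_fit = leader_fit
    return swarm


def classic_local_leader_decision(
    swarm: Swarm,
    config: CSSMOConfig,
    evaluate,
    rng: np.random.Generator,
) -> Swarm:
    """Classic SMO decision (baseline): stagnant group members re-diversify.

    Each dimension is either re-initialized uniformly (w.p. pr) or pushed
    toward the global leader and away from the local leader; greedy accept.
    """
    for g in range(swarm.n_groups):
        if swarm.local_limit_count[g] <= config.local_leader_limit:
            continue
        members = swarm.members_of(g)
        leader = swarm.local_leader_pos[g]
        for i in members:
            x = swarm.positions[i]
            reinit = rng.random(swarm.dim) < config.pr
            u1 = rng.random(swarm.dim)
            u2 = rng.random(swarm.dim)
            directed = x + u1 * (swarm.global_leader_pos - x) + u2 * (x - leader)
            proposal = np.where(reinit, rng.random(swarm.dim), directed)
            _greedy_move(swarm, i, np.clip(proposal, 0.0, 1.0), evaluate)
        swarm.local_limit_count[g] = 0
        best = int(np.argmax(swarm.fitness))
        if swarm.fitness[best] > swarm.global_leader_fit:
            swarm.global_leader_pos = swarm.positions[best].copy()
            swarm.global_leader_fit = float(swarm.fitness[best])
    return swarm


def _relearn_local_leaders(swarm: Swarm) -> None:
    swarm.local_leader_pos = []
    swarm.local_leader_fit = []
    swarm.local_limit_count = []
    for g in range(swarm.n_groups):
        members = swarm.members_of(g)
        best = members[int(np.argmax(swarm.fitness[members]))]
        swarm.local_leader_pos.append(swarm.positions[best].copy())
        swarm.local_leader_fit.append(float(swarm.fitness[best]))
        swarm.local_limit_count.append(0)


def global_leader_decision(swarm: Swarm, config: CSSMOConfig) -> Swarm:
    """Split into one more contiguous group on global stagnation; merge at MG."""
    if swarm.global_limit_count <= config.global_leader_limit:
        return swarm
    if swarm.n_groups < config.max_groups:
        swarm.n_groups += 1
    else:
        swarm.n_groups = 1
    swarm.group_of = contiguous_partition(swarm.size, swarm.n_groups)
    swarm.global_limit_count = 0
    _relearn_local_leaders(swarm)
    return swarm
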