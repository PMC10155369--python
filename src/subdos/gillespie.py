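"""Stochastic (Gillespie) simulation of the duplicate-fate chain.

Monte Carlo realisations of the same generator matrix, used as an
independent check on the analytic matrix-exponential propagation: each
replicate draws exponential waiting times from its current total exit
rate and jumps to a neighbour with probability proportional to the
off-diagonal rates.

Reproducibility: a single user seed keys a counter-based (Philox)
bit generator per replicate, so replicate ``i`` sees the same stream
regardless of execution order or of how many replicates are run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .markov import GeneratorMatrix

__all__ = ["SimulationSettings", "GillespieResult", "gillespie_simulate"]


@dataclass(frozen=True)
class SimulationSettings:
    """Replicate count, horizon (generations) and RNG seed."""

    n_replicates: int
    t_max: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be >= 1")
        if self.t_max < 0:
            raise InvalidParameterError("t_max must be non-negative")


@dataclass(frozen=True)
class GillespieResult:
    """Empirical state occupancy at t_max over all replicates."""

    t: float
    counts: np.ndarray
    frequencies: np.ndarray
    n_absorbed_s: int
    n_absorbed_y: int


def gillespie_simulate(
    q: GeneratorMatrix,
    settings: SimulationSettings,
    initial_state: int = 0,
) -> GillespieResult:
    """Simulate the chain and return empirical frequencies at ``t_max``.

    A replicate that starts in (or reaches) a state with zero exit rate
    stays there; starting in an absorbing state is therefore valid and
    returns that state with probability 1.
    """
    n_states = q.q.shape[0]
    if not 0 <= initial_state < n_states:
        raise InvalidParameterError(f"initial_state {initial_state} out of range")

    matrix = q.q
    exit_rates = -np.diag(matrix)
    # per-state jump distributions, precomputed once
    jump_targets: list[np.ndarray | None] = []
    jump_probs: list[np.ndarray | None] = []
    for s in range(n_states):
        if exit_rates[s] <= 0:
            jump_targets.append(None)
            jump_probs.append(None)
            continue
        row = matrix[s].copy()
        row[s] = 0.0
        targets = np.nonzero(row)[0]
        jump_targets.append(targets)
        jump_probs.append(row[targets] / exit_rates[s])

    counts = np.zeros(n_states, dtype=np.int64)
    for rep in range(settings.n_replicates):
        key = np.array([settings.seed, rep], dtype=np.uint64)
        rng = np.random.Generator(np.random.Philox(key=key))
        state = initial_state
        t = 0.0
        while exit_rates[state] > 0:
            t += rng.exponential(1.0 / exit_rates[state])
            if t > settings.t_max:
                break
            state = int(rng.choice(jump_targets[state], p=jump_probs[state]))
        counts[state] += 1

    freqs = counts / settings.n_replicates
    return GillespieResult(
        t=settings.t_max,
        counts=counts,
        frequencies=freqs,
        n_absorbed_s=int(counts[q.s_index]),
        n_absorbed_y=int(counts[q.y_index]),
    )
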