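"""Continuous-time Markov chain over duplicate-gene redundancy states.

The state space for a gene with ``z`` regulatory domains is

    {0, 1, ..., z-1} U {S, Y}

where transient state ``i`` means one copy has lost ``i`` regulatory
domains, ``S`` (subfunctionalized: the domains are partitioned so both
copies are required) and ``Y`` (one copy pseudogenized) are absorbing.
Off-diagonal rates combine the mutational opportunity (region length
times per-nucleotide rate, times the number of mutable targets) with
the population-scaled fixation probability ``g * N_e`` of the
resulting configuration.  The neutral model sets ``g * N_e = 1``
everywhere; the dosage-aware model computes ``g`` from the
hydrophobic-patch load of each state.

The state distribution after ``t`` generations is ``p(0) @ expm(Q t)``;
terminal absorption probabilities come from the fundamental-matrix
linear solve on the transient block.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy.linalg import expm

from .errors import InvalidParameterError
from .fitness import (
    ExpressionScenario,
    GeneArchitecture,
    SelectionParams,
    fitness,
    fixation_probability,
    state_hp_sum,
)

__all__ = [
    "Variant",
    "ModelSpec",
    "GeneratorMatrix",
    "StateDistribution",
    "mutation_rates",
    "build_generator",
    "propagate",
    "trajectory",
    "absorption_probabilities",
    "s_crossing_time",
]


class Variant(str, enum.Enum):
    """Which transition-rate model to build."""

    SUB_ONLY = "SUB_ONLY"  # neutral: every g*N_e == 1
    SUB_DOS = "SUB_DOS"  # dosage-aware fixation probabilities


@dataclass(frozen=True)
class ModelSpec:
    """Complete parameterization of one model run.

    For ``Variant.SUB_ONLY`` the selection, scenario and binding
    parameters are ignored by construction (the chain is neutral), but
    they are kept in the spec so a neutral/selected pair can share one
    parameterization.
    """

    variant: Variant
    architecture: GeneArchitecture
    selection: SelectionParams
    scenario: ExpressionScenario
    keq: float

    def __post_init__(self) -> None:
        if self.keq <= 0:
            raise InvalidParameterError(f"keq must be positive, got {self.keq}")


@dataclass(frozen=True)
class GeneratorMatrix:
    """(z+2)x(z+2) transition-rate matrix, states [0..z-1, S, Y]."""

    q: np.ndarray
    z: int

    @property
    def state_labels(self) -> List[str]:
        return [f"state_{i}" for i in range(self.z)] + ["S", "Y"]

    @property
    def s_index(self) -> int:
        return self.z

    @property
    def y_index(self) -> int:
        return self.z + 1


@dataclass(frozen=True)
class StateDistribution:
    """Probability vector over [0..z-1, S, Y] at time t (generations)."""

    t: float
    p: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
            raise InvalidParameterError(
                f"distribution is not simplex-valued: sum={p.sum()}, min={p.min()}"
            )

    @classmethod
    def point_mass(cls, index: int, n_states: int, t: float = 0.0) -> "StateDistribution":
        p = np.zeros(n_states)
        p[index] = 1.0
        return cls(t=t, p=p)


def mutation_rates(architecture: GeneArchitecture) -> Tuple[float, float]:
    """Per-generation loss rates (u_c, u_r) for whole regions.

    u_c = u_h * l_c is the rate at which a coding region acquires a
    null mutation; u_r = u_b * l_r the same for one regulatory domain.
    """
    return (
        architecture.u_h * architecture.l_c,
        architecture.u_b * architecture.l_r,
    )


def _scaled_fixation_factors(spec: ModelSpec) -> dict:
    """g * N_e for every transition, keyed by (from_state, target label)."""
    z = spec.architecture.z
    w = spec.selection.w
    n_e = spec.selection.n_e

    def f_of(state) -> float:
        return fitness(state_hp_sum(state, spec.scenario, spec.keq, z), w)

    factors = {}
    for i in range(z):
        f_i = f_of(i)
        factors[(i, "Y")] = fixation_probability(f_i, f_of("Y"), n_e) * n_e
        factors[(i, "S")] = fixation_probability(f_i, f_of(("S", i)), n_e) * n_e
        if i < z - 1:
            factors[(i, "next")] = fixation_probability(f_i, f_of(i + 1), n_e) * n_e
    return factors


def build_generator(spec: ModelSpec) -> GeneratorMatrix:
    """Assemble the generator matrix Q for the requested model variant.

    Reachability: from state 0 only state 1 and Y; from 1 <= i <= z-2
    states i+1, S and Y; from z-1 only S and Y.  The configuration
    entered into S from state i carries the load of i+1 lost domains
    (from z-1, the all-domains load, i.e. the same as Y): the lumped
    absorbing state's fitness is that of the single mutation being
    fixed.  Rows S and Y are zero; diagonals close each row to 0.
    """
    z = spec.architecture.z
    u_c, u_r = mutation_rates(spec.architecture)
    n = z + 2
    s_idx, y_idx = z, z + 1

    if spec.variant is Variant.SUB_DOS:
        factors = _scaled_fixation_factors(spec)
    else:
        keys = [(i, t) for i in range(z) for t in ("Y", "S", "next")]
        factors = dict.fromkeys(keys, 1.0)

    q = np.zeros((n, n))
    q[0, 1] = 2.0 * z * factors[(0, "next")] * u_r
    q[0, y_idx] = 2.0 * factors[(0, "Y")] * u_c
    for i in range(1, z - 1):
        q[i, i + 1] = (z - i) * factors[(i, "next")] * u_r
        q[i, s_idx] = (z - i) * factors[(i, "S")] * u_r
        q[i, y_idx] = factors[(i, "Y")] * u_c
    q[z - 1, s_idx] = factors[(z - 1, "S")] * u_r
    q[z - 1, y_idx] = factors[(z - 1, "Y")] * u_c + factors[(z - 1, "Y")] * u_r

    np.fill_diagonal(q, -q.sum(axis=1))
    return GeneratorMatrix(q=q, z=z)


def propagate(
    q: GeneratorMatrix, t: float, initial: StateDistribution
) -> StateDistribution:
    """Advance a state distribution by t generations: p(t) = p(0) @ expm(Qt)."""
    if t < 0:
        raise InvalidParameterError(f"t must be non-negative, got {t}")
    if t == 0:
        return initial
    p = initial.p @ expm(q.q * t)
    p = np.clip(p, 0.0, None)
    return StateDistribution(t=initial.t + t, p=p / p.sum())


def trajectory(spec: ModelSpec, times: Sequence[float]) -> List[StateDistribution]:
    """State distributions at each requested time, starting fully redundant.

    Times must be sorted and non-negative.  Occupancy of the absorbing
    states S and Y is non-decreasing along the result; state 0 is
    non-increasing (nothing transitions into it).
    """
    times = list(times)
    if any(t < 0 for t in times):
        raise InvalidParameterError("times must be non-negative")
    if any(b < a for a, b in zip(times, times[1:])):
        raise InvalidParameterError("times must be sorted ascending")

    gen = build_generator(spec)
    start = StateDistribution.point_mass(0, gen.z + 2)
    return [propagate(gen, t, start) for t in times]


def absorption_probabilities(
    q: GeneratorMatrix, initial: StateDistribution
) -> Tuple[float, float]:
    """Terminal absorption probabilities (p_S, p_Y).

    Fundamental-matrix solve on the transient block: with Q partitioned
    into transient block T and absorption rates R, the absorption
    matrix is B = (-T)^{-1} R, exact for any positive rates and immune
    to the stiffness of exponentiating to astronomical times.
    """
    z = q.z
    t_block = q.q[:z, :z]
    r_block = q.q[:z, z:]
    b = np.linalg.solve(-t_block, r_block)
    p_abs = initial.p[:z] @ b + initial.p[z:]
    return float(p_abs[0]), float(p_abs[1])


def s_crossing_time(
    spec_a: ModelSpec,
    spec_b: ModelSpec,
    t_max: float = 5000.0,
    n_grid: int = 500,
) -> float | None:
    """First time in (0, t_max] where the S-occupancies of the two models cross.

    Scans a uniform grid for a sign change of S_b(t) - S_a(t) and
    bisects the bracketing interval.  Detects a crossing in either
    direction; returns None if no sign change occurs on the grid.
    """
    gen_a = build_generator(spec_a)
    gen_b = build_generator(spec_b)
    start_a = StateDistribution.point_mass(0, gen_a.z + 2)
    start_b = StateDistribution.point_mass(0, gen_b.z + 2)

    def diff(t: float) -> float:
        s_a = propagate(gen_a, t, start_a).p[gen_a.s_index]
        s_b = propagate(gen_b, t, start_b).p[gen_b.s_index]
        return s_b - s_a

    ts = np.linspace(0.0, t_max, n_grid + 1)[1:]
    prev_t, prev_d = 0.0, 0.0
    for t in ts:
        d = diff(t)
        if prev_d != 0.0 and d != 0.0 and (prev_d < 0.0) != (d < 0.0):
            sign = 1.0 if prev_d < 0.0 else -1.0
            lo, hi = prev_t, t
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if sign * diff(mid) < 0:
                    lo = mid
                else:
                    hi = mid
            return 0.5 * (lo + hi)
        prev_t, prev_d = t, d
    return None
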