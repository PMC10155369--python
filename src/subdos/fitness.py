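"""State fitness from stoichiometric load, and fixation probabilities.

Each Markov state describes a duplicate gene pair by how many of the
``z`` regulatory domains have lost expression on one copy.  Per domain,
the gene product A is either in stoichiometric balance with its
obligate partner B or at a 1:2 deficit (one copy's expression lost).
The mis-interaction load of a state is the hydrophobic-patch
concentration summed over its domains; fitness is the inverse penalty

    f = 1 / (1 + w * sum_hp)

and a new loss-of-function variant with state fitness ``f_j`` fixes in
a haploid population of effective size ``N_e`` with probability

    g = (1 - f_i/f_j) / (1 - (f_i/f_j)**N_e),

which tends to the neutral 1/N_e as f_j -> f_i.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Tuple, Union

from .equilibrium import DimerSystem, solve_dimer_equilibrium
from .errors import InvalidParameterError, InvalidStateError

__all__ = [
    "Scenario",
    "GeneArchitecture",
    "SelectionParams",
    "ExpressionScenario",
    "StateLabel",
    "imbalanced_domain_count",
    "state_hp_sum",
    "fitness",
    "fixation_probability",
]

#: Below this |ln(f_i/f_j)| a transition is treated as exactly neutral,
#: so g*N_e == 1 without a 0/0.
NEUTRAL_LOG_RATIO_TOL = 1e-14

# A state label is an int i in 0..z-1, the absorbing "Y", or the tuple
# ("S", i): the subfunctionalized configuration entered from state i.
StateLabel = Union[int, str, Tuple[str, int]]


class Scenario(str, enum.Enum):
    """Duplication scenario: was the interacting partner duplicated too?"""

    WGD = "WGD"  # whole-genome duplication: partner duplicated, balance intact
    SSD = "SSD"  # small-scale duplication: partner single-copy, balance broken


@dataclass(frozen=True)
class GeneArchitecture:
    """Mutational-opportunity description of one duplicated gene.

    Parameters
    ----------
    z
        Number of independently mutable regulatory domains
        (enhancer-like regions), >= 2.
    l_c, l_r
        Coding-region and regulatory-region lengths, nucleotides.
    u_b, u_h
        Per-nucleotide loss-of-function mutation rates per generation:
        regulatory (transcription-factor binding) and coding
        (functional-peptide) classes respectively.
    """

    z: int
    l_c: float
    l_r: float
    u_b: float
    u_h: float

    def __post_init__(self) -> None:
        if self.z < 2:
            raise InvalidParameterError(f"z must be >= 2, got {self.z}")
        for name in ("l_c", "l_r", "u_b", "u_h"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")


@dataclass(frozen=True)
class SelectionParams:
    """Population-level selection parameters.

    ``w`` scales the fitness penalty per unit of hydrophobic-patch
    concentration; ``n_e`` is the effective population size.  ``n_e``
    is accepted as a real number >= 2 (the fixation formula is
    continuous in it, which keeps parameter sweeps smooth).
    """

    w: float
    n_e: float

    def __post_init__(self) -> None:
        if self.w < 0:
            raise InvalidParameterError(f"w must be non-negative, got {self.w}")
        if self.n_e < 2:
            raise InvalidParameterError(f"n_e must be >= 2, got {self.n_e}")


@dataclass(frozen=True)
class ExpressionScenario:
    """Per-domain expression totals for the duplicated gene and partner.

    ``per_copy_concentration`` is the contribution of a single gene
    copy in one domain, so the pair expresses twice that immediately
    after duplication.  ``partner_total`` is the partner subunit's
    total, which under WGD is itself doubled (matching the pair) and
    under SSD stays at single-copy level.
    """

    scenario: Scenario
    per_copy_concentration: float = 1.25e-6
    partner_total: float = 2.5e-6

    def __post_init__(self) -> None:
        if self.per_copy_concentration <= 0 or self.partner_total <= 0:
            raise InvalidParameterError("expression concentrations must be positive")

    @classmethod
    def wgd(cls, per_copy: float = 1.25e-6) -> "ExpressionScenario":
        return cls(Scenario.WGD, per_copy, 2.0 * per_copy)

    @classmethod
    def ssd(cls, per_copy: float = 1.25e-6) -> "ExpressionScenario":
        return cls(Scenario.SSD, per_copy, per_copy)


def _domains_lost(state: StateLabel, z: int) -> int:
    """Number of domains whose expression one copy has lost, 0..z."""
    if isinstance(state, tuple):
        tag, i = state
        if tag != "S" or not 0 <= int(i) <= z - 1:
            raise InvalidStateError(f"unknown state label {state!r}")
        # the subfunctionalized configuration reached from state i fixes
        # one further regulatory loss
        return int(i) + 1
    if state == "Y":
        return z
    if isinstance(state, int) and 0 <= state <= z - 1:
        return state
    raise InvalidStateError(f"unknown state label {state!r}")


def imbalanced_domain_count(state: StateLabel, scenario: ExpressionScenario, z: int) -> int:
    """Count expression domains that are stoichiometrically imbalanced.

    Under WGD the pair starts balanced, so every lost domain becomes
    imbalanced (state i has i, Y has all z, and the S configuration
    entered from state i has i+1).  Under SSD the pair starts
    imbalanced in every domain and each loss *repairs* one, so the
    same counts describe the balanced domains instead.
    """
    lost = _domains_lost(state, z)
    if scenario.scenario is Scenario.WGD:
        return lost
    return z - lost


def state_hp_sum(
    state: StateLabel, scenario: ExpressionScenario, keq: float, z: int
) -> float:
    """Total hydrophobic-patch load of a state, summed across domains.

    Each domain is in one of two per-domain equilibria: the duplicated
    gene expressing both copies (2x per-copy) or one copy (1x), against
    the fixed partner total.  Which of those is the balanced one
    depends on the scenario.
    """
    per_copy = scenario.per_copy_concentration
    partner = scenario.partner_total
    if scenario.scenario is Scenario.WGD:
        balanced_a, imbalanced_a = 2.0 * per_copy, per_copy
    else:
        balanced_a, imbalanced_a = per_copy, 2.0 * per_copy

    hp_bal = solve_dimer_equilibrium(DimerSystem(keq, balanced_a, partner)).hp
    hp_imb = solve_dimer_equilibrium(DimerSystem(keq, imbalanced_a, partner)).hp
    n_imb = imbalanced_domain_count(state, scenario, z)
    return n_imb * hp_imb + (z - n_imb) * hp_bal


def fitness(hp_sum: float, w: float) -> float:
    """Relative fitness 1/(1 + w * hp_sum) in (0, 1]."""
    if hp_sum < 0 or w < 0:
        raise InvalidParameterError("hp_sum and w must be non-negative")
    return 1.0 / (1.0 + w * hp_sum)


def fixation_probability(f_i: float, f_j: float, n_e: float) -> float:
    """Probability that a variant moving the state from fitness f_i to f_j fixes.

    Evaluated in log space with expm1 so that nearly-neutral transitions
    (|s| ~ 1e-6) and strongly selected ones (N_e*|s| up to hundreds) are
    both handled without cancellation or overflow.  Exactly neutral
    transitions return 1/n_e, so g*n_e == 1.0 holds exactly there.
    """
    if not (0.0 < f_i <= 1.0) or not (0.0 < f_j <= 1.0):
        raise InvalidParameterError(
            f"fitness values must be in (0, 1], got f_i={f_i}, f_j={f_j}"
        )
    if n_e < 2:
        raise InvalidParameterError(f"n_e must be >= 2, got {n_e}")

    ln_r = math.log(f_i) - math.log(f_j)
    if abs(ln_r) < NEUTRAL_LOG_RATIO_TOL:
        return 1.0 / n_e

    num = math.expm1(ln_r)  # r - 1
    big = n_e * ln_r
    if big > 700.0:
        # denominator ~ r**n_e overflows: g ~ (r - 1) * r**(-n_e),
        # which underflows smoothly to 0 for strongly deleterious moves
        return num * math.exp(-big)
    return num / math.expm1(big)
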