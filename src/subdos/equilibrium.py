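"""Heterodimer mass-action equilibrium and exposed-hydrophobic-patch load.

A heterodimer A + B <-> AB binds through one hydrophobic patch on each
subunit.  At equilibrium with association constant ``keq`` the bound
concentration ``x = [AB]`` satisfies the mass balance

    keq * (a_total - x) * (b_total - x) = x,

i.e. the quadratic  keq*x**2 - (keq*a_total + keq*b_total + 1)*x
+ keq*a_total*b_total = 0.  Only the smaller root is physical
(0 <= x <= min(a_total, b_total)).  Every unbound subunit exposes its
patch, so the mis-interaction load of one expression domain is
``hp = a_free + b_free``.

Concentrations are carried in mol/mL throughout; ``keq`` is the
reciprocal of a concentration on the same scale and is treated as a
plain number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "DimerSystem",
    "EquilibriumResult",
    "solve_dimer_equilibrium",
    "hp_imbalance_curve",
]


@dataclass(frozen=True)
class DimerSystem:
    """Binding constant and total subunit concentrations for one domain.

    Parameters
    ----------
    keq
        Association constant of A + B <-> AB, in 1/(mol/mL).  Must be
        positive.
    a_total, b_total
        Total (bound + free) subunit concentrations, mol/mL.
    """

    keq: float
    a_total: float
    b_total: float

    def __post_init__(self) -> None:
        if not self.keq > 0:
            raise InvalidParameterError(f"keq must be positive, got {self.keq}")
        if self.a_total < 0 or self.b_total < 0:
            raise InvalidParameterError(
                f"total concentrations must be non-negative, got "
                f"a_total={self.a_total}, b_total={self.b_total}"
            )


@dataclass(frozen=True)
class EquilibriumResult:
    """Equilibrium concentrations for one expression domain (mol/mL)."""

    ab: float
    a_free: float
    b_free: float
    hp: float


def solve_dimer_equilibrium(system: DimerSystem) -> EquilibriumResult:
    """Solve the dimer equilibrium and return bound/free concentrations.

    Uses the conjugate (multiply-through) form of the quadratic root,
    ``x = 2*k*a*b / (b_coef + sqrt(disc))``, which avoids the
    catastrophic cancellation the textbook ``(-b - sqrt(disc)) / 2a``
    form suffers when ``keq * totals >> 1``.
    """
    k = system.keq
    a_t = system.a_total
    b_t = system.b_total

    b_coef = k * a_t + k * b_t + 1.0
    disc = b_coef * b_coef - 4.0 * (k * k) * a_t * b_t
    if disc < 0:
        # analytically impossible for valid inputs; tolerate rounding only
        if disc < -1e-12 * b_coef * b_coef:
            raise ArithmeticError(
                f"negative discriminant {disc} for {system}; "
                "inputs outside the guaranteed regime"
            )
        disc = 0.0

    ab = 2.0 * k * a_t * b_t / (b_coef + math.sqrt(disc))
    # clamp float noise so the conservation invariants hold exactly
    ab = min(max(ab, 0.0), a_t, b_t)
    a_free = a_t - ab
    b_free = b_t - ab
    return EquilibriumResult(ab=ab, a_free=a_free, b_free=b_free, hp=a_free + b_free)


def hp_imbalance_curve(
    keq_list: Iterable[float],
    ratio_grid: Iterable[float],
    reference_total: float,
) -> pd.DataFrame:
    """Hydrophobic-patch load across expression-ratio imbalance.

    For each binding constant and each B:A expression ratio ``r`` the
    equilibrium is solved with ``a_total = reference_total`` and
    ``b_total = r * reference_total``.  Tight binders in balance leave
    the fewest patches exposed; any excess of either partner stays
    unbound and raises the load.

    Returns
    -------
    pandas.DataFrame
        Columns ``keq``, ``ratio``, ``hp``, ordered by (keq, ratio).
    """
    keqs: Sequence[float] = list(keq_list)
    ratios: Sequence[float] = list(ratio_grid)
    if not keqs or not ratios:
        raise InvalidParameterError("keq_list and ratio_grid must be non-empty")
    if any(r <= 0 for r in ratios):
        raise InvalidParameterError("expression ratios must be positive")
    if reference_total <= 0:
        raise InvalidParameterError("reference_total must be positive")

    rows = []
    for keq in sorted(keqs):
        for r in sorted(ratios):
            res = solve_dimer_equilibrium(
                DimerSystem(keq=keq, a_total=reference_total, b_total=r * reference_total)
            )
            rows.append({"keq": keq, "ratio": r, "hp": res.hp})
    return pd.DataFrame(rows, columns=["keq", "ratio", "hp"])
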