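"""Trade equilibrium of the symbiosis in the Edgeworth box.

The box has height ``h`` (C fixed per unit legume mass, h = b_L / a_LC)
and width ``w`` (N fixed by the Rhizobium population).  The legume's
origin is at the bottom-left with N on the horizontal axis and C on the
vertical; Rhizobium's origin is the top-right corner with both axes
reversed.  Both specialization points coincide at the top-left corner
S = (0, h).  A trade line of slope -r through S gives the bundles
reachable by exchanging C for N at ratio r; each species demands the
intersection of the trade line with its own optimality line.  At
equilibrium the box width w* is such that total N demand equals w*
(and, by budget accounting, total C demand equals h), which yields the
closed forms

    x_LN* = h/(c_L+r)          x_LC* = c_L h/(c_L+r)
    x_RN* = r h/(c_R (c_L+r))  x_RC* = r h/(c_L+r)
    w*    = (c_R+r) h / (c_R (c_L+r))

with supplies y_LC* = x_RC* (C from legume to Rhizobium) and
y_RN* = x_LN* (N from Rhizobium to legume).

:func:`solve_equilibrium_geometric` recomputes E without the closed
forms — by numerically intersecting the rays and root-finding on excess
N demand — and serves as an independent oracle for them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .atp_costs import ATPCostSet
from ._interval import midpoint
from .autarky import BudgetLine, autarky_fitness
from .conditions import ExchangeRegime
from .stoichiometry import StoichiometricProfile, Uptake, fitness, optimality_slope


@dataclass(frozen=True)
class EdgeworthBox:
    """Box geometry: total fixed C (height) and N (width), slopes, r."""

    h: float
    w: float
    c_L: float
    c_R: float
    r: float

    def __post_init__(self) -> None:
        for name in ("h", "w", "c_L", "c_R", "r"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")


@dataclass(frozen=True)
class EquilibriumAllocation:
    """The four equilibrium uptakes, the two supplies and the box."""

    legume_uptake: Uptake
    rhizobium_uptake: Uptake
    supply_C: float
    supply_N: float
    box: EdgeworthBox
    feasibility_warning: Optional[str] = None


def equilibrium_allocation(
    h: float,
    c_L: float,
    c_R: float,
    r: float,
    regime: Optional[ExchangeRegime] = None,
) -> EquilibriumAllocation:
    """Closed-form equilibrium allocation for given box height and slopes.

    Feasibility of ``r`` (r_R < r < r_L(1)) is not enforced here so that
    comparative statics can explore any positive r; pass ``regime`` to
    have infeasible ratios flagged with a warning on the result.
    """
    for name, v in (("h", h), ("c_L", c_L), ("c_R", c_R), ("r", r)):
        if not (math.isfinite(v) and v > 0):
            raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    note = None
    if regime is not None:
        lo, hi = regime.interval
        if not (lo < r < hi):
            note = f"exchange ratio r={r} outside feasible interval ({lo}, {hi})"
            warnings.warn(note, stacklevel=2)

    x_LN = h / (c_L + r)
    x_LC = c_L * h / (c_L + r)
    x_RN = r * h / (c_R * (c_L + r))
    x_RC = r * h / (c_L + r)
    w_star = (c_R + r) * h / (c_R * (c_L + r))
    return EquilibriumAllocation(
        legume_uptake=Uptake(x_N=x_LN, x_C=x_LC),
        rhizobium_uptake=Uptake(x_N=x_RN, x_C=x_RC),
        supply_C=x_RC,
        supply_N=x_LN,
        box=EdgeworthBox(h=h, w=w_star, c_L=c_L, c_R=c_R, r=r),
        feasibility_warning=note,
    )


def supply_ratios(c_L: float, c_R: float, r: float) -> Tuple[float, float]:
    """Fraction of fixed C supplied by the legume and of fixed N by Rhizobium.

    Both are unit-free: ``y_LC*/h = r/(c_L+r)`` and
    ``y_RN*/w* = c_R/(c_R+r)``; each lies strictly in (0, 1).
    """
    if c_L <= 0 or c_R <= 0 or r <= 0:
        raise ValueError("c_L, c_R and r must be > 0")
    return (r / (c_L + r), c_R / (c_R + r))


# ---------------------------------------------------------------------------
# Independent geometric solver (the oracle for the closed forms)
# ---------------------------------------------------------------------------

def _intersect(p1, d1, p2, d2):
    """Intersection of two lines given as point + direction (2-vectors)."""
    A = np.column_stack([d1, -np.asarray(d2, dtype=float)])
    rhs = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    t, _ = np.linalg.solve(A, rhs)
    return np.asarray(p1, dtype=float) + t * np.asarray(d1, dtype=float)


def solve_equilibrium_geometric(
    h: float, c_L: float, c_R: float, r: float, tol: float = 1e-12
) -> EquilibriumAllocation:
    """Find E by ray intersection and root-finding, without the closed forms.

    For a trial box width w: the legume demands the intersection of the
    trade line through S = (0, h) (slope -r) with its optimality line
    through the bottom-left origin; Rhizobium, holding the box's N
    endowment w, demands the intersection of its trade line (through
    (w, 0) in its own frame, slope -r) with its optimality line.  The
    equilibrium width is the root of the scalar excess-N-demand function

        g(w) = x_LN + x_RN(w) - w,

    located by bracketed root-finding.  Agreement with
    :func:`equilibrium_allocation` to ``tol`` is the oracle check.
    """
    for name, v in (("h", h), ("c_L", c_L), ("c_R", c_R), ("r", r)):
        if not (math.isfinite(v) and v > 0):
            raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    S = np.array([0.0, h])
    trade_dir = np.array([1.0, -r])

    # Legume demand: trade line through S meets x_C = c_L * x_N.
    legume_pt = _intersect(S, trade_dir, np.array([0.0, 0.0]), np.array([1.0, c_L]))
    x_LN, x_LC = float(legume_pt[0]), float(legume_pt[1])

    def rhizobium_demand(w: float) -> Tuple[float, float]:
        # In Rhizobium's own frame: endowment point (w, 0), trade line of
        # slope -r through it, optimality line x_C = c_R * x_N.
        pt = _intersect(np.array([w, 0.0]), trade_dir,
                        np.array([0.0, 0.0]), np.array([1.0, c_R]))
        return float(pt[0]), float(pt[1])

    def excess_n_demand(w: float) -> float:
        x_RN, _ = rhizobium_demand(w)
        return x_LN + x_RN - w

    # g(0) = x_LN > 0 and g is strictly decreasing; double until bracketed.
    w_hi = max(h, 2.0 * x_LN)
    for _ in range(200):
        if excess_n_demand(w_hi) < 0:
            break
        w_hi *= 2.0
    else:
        raise RuntimeError("could not bracket the equilibrium box width")

    w_star = brentq(excess_n_demand, 0.0, w_hi, xtol=tol, rtol=8.9e-16)
    x_RN, x_RC = rhizobium_demand(w_star)

    return EquilibriumAllocation(
        legume_uptake=Uptake(x_N=x_LN, x_C=x_LC),
        rhizobium_uptake=Uptake(x_N=x_RN, x_C=x_RC),
        supply_C=x_RC,
        supply_N=x_LN,
        box=EdgeworthBox(h=h, w=w_star, c_L=c_L, c_R=c_R, r=r),
    )


# ---------------------------------------------------------------------------
# Welfare comparison against autarky
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WelfareReport:
    """Fitness at equilibrium vs at autarky, for both species."""

    legume_fitness_E: float
    legume_fitness_autarky: float
    rhizobium_fitness_E: float
    rhizobium_fitness_autarky: float
    both_strictly_improved: bool


def welfare_comparison(
    alloc: EquilibriumAllocation,
    legume: StoichiometricProfile,
    rhizobium: StoichiometricProfile,
    costs: ATPCostSet,
    s: int,
) -> WelfareReport:
    """Compare fitness at E with autarky fitness at soil state ``s``.

    The legume's autarky uses its own budget and the direct-uptake costs
    at ``s``.  Rhizobium's budget is fixed at its equilibrium-population
    value ``b_R = a_RN_hat * w*`` (the budget that fixes exactly w* mol N),
    so the comparison isolates the gain from trade at the equilibrium
    population size.  Interval-valued costs are evaluated at their
    midpoint.
    """
    if s not in (0, 1):
        raise ValueError(f"soil state must be 0 or 1, got {s!r}")

    a_LN = midpoint(costs.a_LN[s])
    a_RN = midpoint(costs.a_RN[s])
    a_RC = midpoint(costs.a_RC[s])

    f_L_E = fitness(alloc.legume_uptake, legume)
    f_L_aut = autarky_fitness(
        BudgetLine(a_N=a_LN, a_C=costs.a_LC, b=legume.budget_b), legume
    )

    b_R = costs.a_RN_hat * alloc.box.w
    f_R_E = fitness(alloc.rhizobium_uptake, rhizobium)
    f_R_aut = autarky_fitness(BudgetLine(a_N=a_RN, a_C=a_RC, b=b_R), rhizobium)

    return WelfareReport(
        legume_fitness_E=f_L_E,
        legume_fitness_autarky=f_L_aut,
        rhizobium_fitness_E=f_R_E,
        rhizobium_fitness_autarky=f_R_aut,
        both_strictly_improved=(f_L_E > f_L_aut and f_R_E > f_R_aut),
    )
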