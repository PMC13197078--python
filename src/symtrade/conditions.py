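"""Comparative-advantage and fixation-feasibility conditions for symbiosis.

Trade in C and N can benefit both partners only if Rhizobium's cost of N
in units of C (``r_R``) is lower than the legume's (``r_L``) — the
comparative-advantage condition — and, because symbiotic Rhizobium
switches from direct N uptake to fixation, only if fixation delivers at
least as much N per budget as direct uptake would
(``a_RN(1) >= a_RN_hat``).  When both hold, any exchange ratio r with
``r_R < r < r_L(1)`` makes specialization-and-trade strictly better than
autarky for both species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

from ._interval import Cost, Interval, lower, midpoint, truncate, upper
from .atp_costs import ATPCostSet, uptake_cost_ratio

#: Three-valued verdict for a condition evaluated over an interval.
ALWAYS = "always"
NEVER = "never"
PARTIAL = "partially"

POLICIES = ("lower", "median", "upper", "explicit")


class EmptyExchangeInterval(ValueError):
    """Raised when no exchange ratio can benefit both partners."""


@dataclass(frozen=True)
class ExchangeRegime:
    """Cost ratios and the chosen C-per-N exchange ratio ``r``.

    ``r`` must lie strictly between Rhizobium's cost ratio ``r_R`` and
    the legume's demanding-soil ratio ``r_L1`` for trade to be mutually
    beneficial.
    """

    r_L0: float
    r_L1: Cost
    r_R: float
    r: float
    policy: str = "median"

    def __post_init__(self) -> None:
        if self.policy not in POLICIES:
            raise ValueError(f"policy must be one of {POLICIES}, got {self.policy!r}")
        for name in ("r_L0", "r_R", "r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if lower(self.r_L1) <= 0:
            raise ValueError("r_L1 must be > 0")

    @property
    def interval(self) -> Tuple[float, float]:
        """The open feasibility interval (r_R, anchor of r_L1)."""
        return (self.r_R, _anchor(self.r_L1, self.policy))

    def is_feasible(self) -> bool:
        lo, hi = self.interval
        return lo < self.r < hi


def _anchor(r_L1: Cost, policy: str) -> float:
    """Representative point of an interval-valued r_L1 under a policy."""
    if policy == "lower":
        return lower(r_L1)
    if policy == "upper":
        return upper(r_L1)
    return midpoint(r_L1)  # median and explicit both anchor at the midpoint


def comparative_advantage(r_L: float, r_R: float) -> bool:
    """True iff Rhizobium has the comparative advantage in N (r_L > r_R)."""
    if r_L <= 0 or r_R <= 0:
        raise ValueError("cost ratios must be > 0")
    return r_L > r_R


def fixation_feasible(a_RN_1: Cost, a_RN_hat: float) -> Union[bool, str]:
    """Is N fixation at least as productive as direct uptake at s=1?

    The condition is ``a_RN(1) >= a_RN_hat`` (equality admitted: fixation
    then delivers exactly as much N per budget).  For a scalar cost a
    boolean is returned; for an interval-valued ``a_RN(1)`` the verdict
    is three-valued over the interval: ``"always"``, ``"never"`` or
    ``"partially"`` satisfied.
    """
    if lower(a_RN_1) <= 0 or a_RN_hat <= 0:
        raise ValueError("costs must be > 0")
    if not isinstance(a_RN_1, Interval) or a_RN_1.width == 0:
        return lower(a_RN_1) >= a_RN_hat
    if a_RN_1.lo >= a_RN_hat:
        return ALWAYS
    if a_RN_1.hi < a_RN_hat:
        return NEVER
    return PARTIAL


def feasible_exchange_interval(
    r_L1: Cost, r_R: float, policy: str = "median"
) -> Tuple[float, float]:
    """The open interval of mutually beneficial exchange ratios.

    Returns ``(r_R, anchor)`` where the anchor of an interval-valued
    ``r_L1`` is its lower end, midpoint ("median") or upper end per the
    policy.  Raises :class:`EmptyExchangeInterval` when the anchor does
    not exceed ``r_R`` (no exchange ratio benefits both partners).
    """
    hi = _anchor(r_L1, policy)
    if hi <= r_R:
        raise EmptyExchangeInterval(
            f"no feasible exchange ratio: r_L(1) anchor {hi} <= r_R {r_R}"
        )
    return (r_R, hi)


def choose_exchange_ratio(
    r_L1: Cost, r_R: float, policy: str = "median", explicit_r: Optional[float] = None
) -> float:
    """Pick an exchange ratio from the assumed range ``[r_R, upper(r_L1)]``.

    ``lower`` returns ``r_R`` itself (the range's lower bound, a
    degenerate choice at which the legume's gain from trade is maximal
    and Rhizobium's vanishes at the margin), ``median`` the midpoint
    anchor of ``r_L1`` and ``upper`` its upper end; ``explicit`` returns
    ``explicit_r`` after checking it lies within the closed range.
    All policies first require the interval to be non-empty.
    """
    lo, hi = feasible_exchange_interval(r_L1, r_R, policy="upper")
    if policy == "lower":
        return lo
    if policy == "median":
        _, anchor = feasible_exchange_interval(r_L1, r_R, policy="median")
        return anchor
    if policy == "upper":
        return hi
    if explicit_r is None:
        raise ValueError("policy 'explicit' requires explicit_r")
    if not (lo <= explicit_r <= hi):
        raise EmptyExchangeInterval(
            f"explicit r={explicit_r} outside assumed range [{lo}, {hi}]"
        )
    return explicit_r


@dataclass(frozen=True)
class SymbiosisVerdict:
    """Structured report of all symbiosis conditions.

    Ratios are reported values (2-dp truncation).  ``fixation`` is a
    three-valued verdict when ``a_RN(1)`` is an interval.
    """

    r_L0: float
    r_L1: Cost
    r_L1_anchor: float
    r_R: float
    advantage_s1: bool
    advantage_s0: bool
    fixation: Union[bool, str]
    exchange_interval: Optional[Tuple[float, float]]
    favored_s1: bool
    favored_s0: bool

    def rows(self):
        """Machine-readable (key, value) rows for TSV output."""
        iv = self.exchange_interval
        return [
            ("r_L0", self.r_L0),
            ("r_L1_lo", lower(self.r_L1)),
            ("r_L1_hi", upper(self.r_L1)),
            ("r_L1_anchor", self.r_L1_anchor),
            ("r_R", self.r_R),
            ("comparative_advantage_s1", self.advantage_s1),
            ("comparative_advantage_s0", self.advantage_s0),
            ("fixation_feasible", self.fixation),
            ("exchange_interval_lo", iv[0] if iv else ""),
            ("exchange_interval_hi", iv[1] if iv else ""),
            ("symbiosis_favored_s1", self.favored_s1),
            ("symbiosis_favored_s0", self.favored_s0),
        ]


def symbiosis_verdict(costs: ATPCostSet, policy: str = "median") -> SymbiosisVerdict:
    """Evaluate every symbiosis condition for a cost set.

    Cost ratios are computed with the 2-dp truncation reporting
    convention (the convention all quoted figures use); the interval
    anchor for ``r_L1`` follows ``policy``.  Symbiosis is favored at
    s=1 when Rhizobium has the comparative advantage there and the
    fixation condition is not ruled out over the cost interval; at
    s=0 it requires the (reversed) advantage to hold there.
    """
    r_L0 = float(uptake_cost_ratio(costs.a_LN[0], costs.a_LC, reported=True))
    r_L1 = uptake_cost_ratio(costs.a_LN[1], costs.a_LC, reported=True)
    r_R = float(uptake_cost_ratio(costs.a_RN[0], costs.a_RC[0], reported=True))
    # the "median" anchor: midpoint of the raw costs, then truncated
    anchor = truncate(_anchor(uptake_cost_ratio(costs.a_LN[1], costs.a_LC), policy))

    adv_s1 = comparative_advantage(anchor, r_R) if anchor != r_R else False
    adv_s0 = r_L0 > r_R
    fix = fixation_feasible(costs.a_RN[1], costs.a_RN_hat)
    fix_possible = fix in (ALWAYS, PARTIAL) or fix is True

    interval: Optional[Tuple[float, float]] = None
    if adv_s1:
        interval = (r_R, anchor)

    return SymbiosisVerdict(
        r_L0=r_L0,
        r_L1=r_L1,
        r_L1_anchor=float(anchor),
        r_R=r_R,
        advantage_s1=adv_s1,
        advantage_s0=adv_s0,
        fixation=fix,
        exchange_interval=interval,
        favored_s1=bool(adv_s1 and fix_possible),
        favored_s0=bool(adv_s0),
    )
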