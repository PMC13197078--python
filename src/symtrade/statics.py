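"""Comparative statics: sensitivities of supply ratios and box width.

The equilibrium supply ratios are simple rational functions of the body
C:N ratios and the exchange ratio,

    C ratio = r/(c_L + r),    N ratio = c_R/(c_R + r),

so their partial derivatives have unambiguous signs: the legume's C
supply ratio falls as its body C:N rises, Rhizobium's N supply ratio
falls as its body C:N falls, and the equilibrium box width w* falls in
both.  Because host C:N rises and symbiont C:N falls with age, both
supply ratios are predicted to decline over an aging path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from ._interval import truncate
from .equilibrium import supply_ratios


@dataclass(frozen=True)
class Sensitivities:
    """Analytic partials of the supply ratios and w*, with their signs.

    ``d_C_ratio_d_c_R`` and ``d_N_ratio_d_c_L`` are structural zeros:
    each supply ratio depends on only one body C:N ratio.
    """

    d_C_ratio_d_c_L: float
    d_N_ratio_d_c_R: float
    d_w_d_c_L: float
    d_w_d_c_R: float
    d_C_ratio_d_c_R: float = 0.0
    d_N_ratio_d_c_L: float = 0.0

    @property
    def signs(self) -> Tuple[int, int, int, int]:
        """Signs of the four non-trivial partials (C ratio, N ratio, w*, w*)."""
        return tuple(
            int(np.sign(v))
            for v in (
                self.d_C_ratio_d_c_L,
                self.d_N_ratio_d_c_R,
                self.d_w_d_c_L,
                self.d_w_d_c_R,
            )
        )


def sensitivities(c_L: float, c_R: float, r: float, h: float = 1.0) -> Sensitivities:
    """Closed-form partial derivatives at a parameter point.

    d(C ratio)/dc_L = -r/(c_L+r)^2 < 0,
    d(N ratio)/dc_R =  r/(c_R+r)^2 > 0,
    dw*/dc_L = -(c_R+r) h / (c_R (c_L+r)^2) < 0,
    dw*/dc_R = -r h / (c_R^2 (c_L+r)) < 0.
    """
    for name, v in (("c_L", c_L), ("c_R", c_R), ("r", r), ("h", h)):
        if not (math.isfinite(v) and v > 0):
            raise ValueError(f"{name} must be finite and > 0, got {v!r}")
    return Sensitivities(
        d_C_ratio_d_c_L=-r / (c_L + r) ** 2,
        d_N_ratio_d_c_R=r / (c_R + r) ** 2,
        d_w_d_c_L=-(c_R + r) * h / (c_R * (c_L + r) ** 2),
        d_w_d_c_R=-r * h / (c_R ** 2 * (c_L + r)),
    )


@dataclass(frozen=True)
class SweepGrid:
    """Grid of body C:N ratios and exchange ratios for a parameter sweep.

    Ranges are (lo, hi, step); endpoints are included (the printed range
    bounds are attained at interval endpoints).
    """

    c_L_range: Tuple[float, float, float] = (11.0, 26.0, 0.01)
    c_R_range: Tuple[float, float, float] = (11.0, 12.0, 0.01)
    r_values: Tuple[float, ...] = (1.51, 1.69, 1.88)

    def __post_init__(self) -> None:
        for name, (lo, hi, step) in (("c_L_range", self.c_L_range),
                                     ("c_R_range", self.c_R_range)):
            if lo > hi:
                raise ValueError(f"{name} is empty: lo {lo} > hi {hi}")
            if step <= 0:
                raise ValueError(f"{name} step must be > 0")
        if not self.r_values:
            raise ValueError("r_values must be non-empty")

    @staticmethod
    def _axis(lo: float, hi: float, step: float) -> np.ndarray:
        n = int(round((hi - lo) / step))
        vals = lo + step * np.arange(n + 1)
        vals = vals[vals <= hi + 1e-12]
        if vals[-1] < hi - 1e-12:  # ensure the printed upper bound is attained
            vals = np.append(vals, hi)
        return vals

    def c_L_values(self) -> np.ndarray:
        return self._axis(*self.c_L_range)

    def c_R_values(self) -> np.ndarray:
        return self._axis(*self.c_R_range)


def sweep_supply_ratios(grid: SweepGrid, h: float = 1.0) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate supply ratios and w* over the grid.

    Returns ``(rows, summary)``: ``rows`` holds every full-precision
    (r, c_L, c_R, C_ratio, N_ratio, w_star) combination; ``summary`` has
    one row per exchange ratio with the min/max of each supply ratio
    over its own C:N axis, both full precision and truncated to the 2-dp
    reporting convention.
    """
    c_L = grid.c_L_values()
    c_R = grid.c_R_values()
    records = []
    for r in grid.r_values:
        CL, CR = np.meshgrid(c_L, c_R, indexing="ij")
        C_ratio = r / (CL + r)
        N_ratio = CR / (CR + r)
        w_star = (CR + r) * h / (CR * (CL + r))
        records.append(
            pd.DataFrame(
                {
                    "r": r,
                    "c_L": CL.ravel(),
                    "c_R": CR.ravel(),
                    "C_ratio": C_ratio.ravel(),
                    "N_ratio": N_ratio.ravel(),
                    "w_star": w_star.ravel(),
                }
            )
        )
    rows = pd.concat(records, ignore_index=True)

    summaries = []
    for r in grid.r_values:
        sub = rows[rows["r"] == r]
        c_min, c_max = sub["C_ratio"].min(), sub["C_ratio"].max()
        n_min, n_max = sub["N_ratio"].min(), sub["N_ratio"].max()
        summaries.append(
            {
                "r": r,
                "C_ratio_min": c_min,
                "C_ratio_max": c_max,
                "N_ratio_min": n_min,
                "N_ratio_max": n_max,
                "C_ratio_min_2dp": truncate(c_min),
                "C_ratio_max_2dp": truncate(c_max),
                "N_ratio_min_2dp": truncate(n_min),
                "N_ratio_max_2dp": truncate(n_max),
            }
        )
    return rows, pd.DataFrame(summaries)


def headline_bands(summary: pd.DataFrame) -> Tuple[Tuple[float, float], Tuple[float, float]]:
    """Overall (min, max) bands of both supply ratios across all r values.

    These are the headline predictions: the fraction of fixed C the
    legume supplies and the fraction of fixed N Rhizobium supplies, as
    truncated proportions.
    """
    return (
        (float(summary["C_ratio_min_2dp"].min()), float(summary["C_ratio_max_2dp"].max())),
        (float(summary["N_ratio_min_2dp"].min()), float(summary["N_ratio_max_2dp"].max())),
    )


def aging_trajectory(
    c_L_young: float,
    c_L_old: float,
    c_R_young: float,
    c_R_old: float,
    r: float,
    h: float = 1.0,
    steps: int = 50,
) -> pd.DataFrame:
    """Supply ratios along a linear host/symbiont aging path.

    With age the host's body C:N rises (``c_L_old > c_L_young``) while
    the symbiont's falls (``c_R_old < c_R_young``); both supply ratios
    are then non-increasing along the path.  The w* column is reported
    without a monotonicity guarantee (its two partials pull the same
    way here only through c_L; the net change is indefinite in general).
    """
    if c_L_old < c_L_young:
        raise ValueError("aging requires c_L_old >= c_L_young (host C:N rises with age)")
    if c_R_old > c_R_young:
        raise ValueError("aging requires c_R_old <= c_R_young (symbiont C:N falls with age)")
    if steps < 2:
        raise ValueError("steps must be >= 2")

    t = np.linspace(0.0, 1.0, steps)
    c_L = c_L_young + t * (c_L_old - c_L_young)
    c_R = c_R_young + t * (c_R_old - c_R_young)
    C_ratio = r / (c_L + r)
    N_ratio = c_R / (c_R + r)
    w_star = (c_R + r) * h / (c_R * (c_L + r))
    return pd.DataFrame(
        {"t": t, "c_L": c_L, "c_R": c_R, "C_ratio": C_ratio,
         "N_ratio": N_ratio, "w_star": w_star}
    )
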