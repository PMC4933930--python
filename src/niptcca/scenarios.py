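"""One-way sensitivity analysis, cost-neutral price solving and uptake scenarios."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import evaluate_pathway, incremental
from .params import CURRENT, ParamError, ScreeningParams, Strategy

__all__ = [
    "ThresholdQuery",
    "ScenarioRow",
    "NoCrossingError",
    "solve_cost_neutral_price",
    "price_sweep",
    "one_way_threshold",
    "uptake_scenarios",
]


class NoCrossingError(ValueError):
    """Incremental cost does not cross zero in the search interval."""


@dataclass(frozen=True)
class ThresholdQuery:
    """Specification of a one-way cost-neutrality search.

    ``coupling`` may be ``"none"`` or ``"complement_within_further_testing"``;
    the latter holds u_nipt_high + u_direct_ipd fixed at its base sum while
    the NIPT uptake is varied.

    ``arm`` selects where the varied value applies: ``"both"`` pathways,
    the ``"contingent"`` pathway only, or the ``"current"`` comparator only.
    Shared inputs like the screening uptake enter both arms, so varying
    them in one arm only is a distinct (and published) analysis.
    """

    strategy: Strategy
    param: str
    coupling: str = "none"
    lo: float = 0.0
    hi: float = 1.0
    tol: float = 1e-9
    arm: str = "both"

    def __post_init__(self) -> None:
        if self.param not in ScreeningParams.field_names():
            raise ParamError(f"unknown parameter {self.param!r}")
        if self.coupling not in ("none", "complement_within_further_testing"):
            raise ParamError(f"unknown coupling rule {self.coupling!r}")
        if self.arm not in ("both", "contingent", "current"):
            raise ParamError(f"unknown arm {self.arm!r}")
        if not (np.isfinite(self.lo) and np.isfinite(self.hi) and self.lo < self.hi):
            raise ParamError("search interval must be finite with lo < hi")


@dataclass(frozen=True)
class ScenarioRow:
    """One uptake scenario: high-risk NIPT/direct-IPD uptakes and the
    incremental costs of the 1/150 strategies under them."""

    label: str
    u_nipt_high: float
    u_direct_ipd: float
    u_total: float
    d_cost_direct: float
    d_cost_nodirect: float


def _incremental_cost(params: ScreeningParams, strategy: Strategy) -> float:
    return incremental(params, strategy).d_total_cost


def solve_cost_neutral_price(
    params: ScreeningParams,
    strategy: Strategy,
    lo: float = 0.0,
    hi: float = 2000.0,
    tol: float = 0.001,
) -> float:
    """NIPT laboratory cost at which the strategy is cost neutral.

    Root-finds d_total_cost(c_nipt_lab) = 0 by bisection (Brent); the
    function is affine in the lab cost with slope n_nipt * (1 + repeat
    rate), so a closed form exists and serves as a cross-check in tests.
    """
    if strategy.is_current:
        raise ParamError("cost-neutral price is defined for contingent strategies")
    n_nipt = evaluate_pathway(params, strategy).n_nipt
    if n_nipt == 0:
        raise NoCrossingError("no NIPT tests performed; price has no effect")

    def f(price: float) -> float:
        return _incremental_cost(params.replace(c_nipt_lab=price), strategy)

    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return lo
    if f_lo * f_hi > 0:
        raise NoCrossingError(
            f"incremental cost does not change sign on [{lo}, {hi}]"
        )
    return float(brentq(f, lo, hi, xtol=tol))


def price_sweep(
    params: ScreeningParams,
    strategies: list[Strategy],
    prices: np.ndarray | list[float],
) -> pd.DataFrame:
    """Incremental total cost per strategy over a grid of NIPT lab prices.

    Returns a tidy frame with columns ``price``, ``strategy`` and
    ``d_total_cost`` (GBP).  Each strategy's curve is affine in price.
    """
    prices = np.asarray(prices, dtype=float)
    if prices.size == 0:
        raise ParamError("price grid is empty")
    rows = []
    for strategy in strategies:
        for price in prices:
            d = _incremental_cost(params.replace(c_nipt_lab=float(price)), strategy)
            rows.append({"price": float(price), "strategy": strategy.label, "d_total_cost": d})
    return pd.DataFrame(rows)


def _apply_query(params: ScreeningParams, query: ThresholdQuery, value: float) -> ScreeningParams:
    changes = {query.param: value}
    if query.coupling == "complement_within_further_testing":
        total = params.u_nipt_high + params.u_direct_ipd
        if query.param == "u_nipt_high":
            changes["u_direct_ipd"] = total - value
        elif query.param == "u_direct_ipd":
            changes["u_nipt_high"] = total - value
        else:
            raise ParamError(
                "complement coupling applies only to u_nipt_high / u_direct_ipd"
            )
    return params.replace(**changes)


def one_way_threshold(params: ScreeningParams, query: ThresholdQuery) -> float:
    """Value of the varied parameter at which incremental cost crosses zero."""
    lo, hi = query.lo, query.hi
    if query.coupling == "complement_within_further_testing":
        # keep the coupled complement inside [0, 1]
        total = params.u_nipt_high + params.u_direct_ipd
        lo = max(lo, total - 1.0)
        hi = min(hi, total)
    query = ThresholdQuery(
        query.strategy, query.param, query.coupling, lo, hi, query.tol, query.arm
    )

    def f(value: float) -> float:
        varied = _apply_query(params, query, value)
        p_new = params if query.arm == "current" else varied
        p_cur = params if query.arm == "contingent" else varied
        new = evaluate_pathway(p_new, query.strategy)
        cur = evaluate_pathway(p_cur, CURRENT)
        return new.total_cost - cur.total_cost

    f_lo, f_hi = f(query.lo), f(query.hi)
    if f_lo == 0.0:
        return query.lo
    if f_hi == 0.0:
        return query.hi
    if f_lo * f_hi > 0:
        raise NoCrossingError(
            f"not cost-neutral anywhere in range [{query.lo}, {query.hi}] "
            f"for parameter {query.param!r}"
        )
    return float(brentq(f, query.lo, query.hi, xtol=query.tol))


def uptake_scenarios(
    params: ScreeningParams,
    rows: list[tuple[str, float, float]] | list[tuple[str, float, float, float]],
) -> list[ScenarioRow]:
    """Evaluate the 1/150 strategies under alternative high-risk uptakes.

    Each row gives (label, u_nipt_high, u_direct_ipd) with an optional
    fourth element overriding the combined further-testing total.  The
    no-direct variant assumes direct-IPD choosers switch to NIPT, so its
    NIPT uptake is the row's total (by default the pair's sum).
    """
    direct = Strategy("contingent", 150, direct_ipd_allowed=True)
    nodirect = Strategy("contingent", 150, direct_ipd_allowed=False)
    out = []
    for row in rows:
        label, u_nipt, u_ipd = row[0], row[1], row[2]
        if not (0 <= u_nipt <= 1 and 0 <= u_ipd <= 1 and u_nipt + u_ipd <= 1 + 1e-12):
            raise ParamError(
                f"invalid uptake pair ({u_nipt}, {u_ipd}) in scenario {label!r}"
            )
        total = row[3] if len(row) > 3 else u_nipt + u_ipd
        if not 0 <= total <= 1 + 1e-12:
            raise ParamError(f"invalid total uptake {total} in scenario {label!r}")
        total = min(total, 1.0)
        p_direct = params.replace(u_nipt_high=u_nipt, u_direct_ipd=u_ipd)
        p_nodirect = params.replace(u_nipt_high_nodirect=total)
        out.append(
            ScenarioRow(
                label=label,
                u_nipt_high=u_nipt,
                u_direct_ipd=u_ipd,
                u_total=total,
                d_cost_direct=_incremental_cost(p_direct, direct),
                d_cost_nodirect=_incremental_cost(p_nodirect, nodirect),
            )
        )
    return out


def closed_form_cost_neutral_price(params: ScreeningParams, strategy: Strategy) -> float:
    """Closed-form cross-check: c* = c_base - d/(n_nipt * (1 + repeat))."""
    res = evaluate_pathway(params, strategy)
    if res.n_nipt == 0:
        raise NoCrossingError("no NIPT tests performed; price has no effect")
    d = _incremental_cost(params, strategy)
    slope = res.n_nipt * (1.0 + params.p_nipt_repeat)
    return params.c_nipt_lab - d / slope
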