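"""Table writers following the publication's presentation conventions:
money in GBP thousands, counts as integers, fractional miscarriages to one
decimal, all rounded half-away-from-zero.  Raw (unrounded) variants are
available everywhere; rounding is presentation-only."""

from __future__ import annotations

import math

import pandas as pd

from .model import evaluate_pathway, incremental
from .params import ScreeningParams, Strategy, enumerate_strategies
from .psa import PsaResult
from .scenarios import ScenarioRow

__all__ = [
    "round_half_away",
    "money_thousands",
    "table3_frame",
    "table4_frame",
    "table5_frame",
    "DEFAULT_UPTAKE_ROWS",
]

#: Published uptake scenarios: (label, high-risk NIPT uptake, direct-IPD
#: uptake[, total used for the no-direct variant]).  The main analysis uses
#: the headline 91% no-direct uptake, not the 92.5% pair sum.
DEFAULT_UPTAKE_ROWS: list[tuple] = [
    ("Main analysis", 0.725, 0.200, 0.910),
    ("Lowest NIPT uptake", 0.685, 0.259),
    ("Highest NIPT uptake and highest total uptake", 0.966, 0.034),
    ("Lowest total uptake", 0.745, 0.139),
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (banker's rounding would shift table cells)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def money_thousands(x: float) -> int:
    return int(round_half_away(x / 1000.0))


TABLE3_COLUMNS = [
    "strategy",
    "n_screened",
    "n_screen_positive",
    "cost_screening_k",
    "n_nipt",
    "cost_nipt_k",
    "n_ipd_direct",
    "n_ipd_after_nipt",
    "cost_ipd_k",
    "total_cost_k",
    "n_ds_detected",
    "n_ds_confirmed_ipd",
    "n_miscarriage",
]


def table3_frame(params: ScreeningParams, raw: bool = False) -> pd.DataFrame:
    """All seven strategy rows: counts, per-component costs, totals."""
    rows = []
    for strategy in enumerate_strategies():
        r = evaluate_pathway(params, strategy)
        if raw:
            rows.append(
                {
                    "strategy": strategy.label,
                    "n_screened": r.n_screened,
                    "n_screen_positive": r.n_screen_positive_at_threshold,
                    "cost_screening_k": r.cost_screening / 1000.0,
                    "n_nipt": r.n_nipt,
                    "cost_nipt_k": r.cost_nipt / 1000.0,
                    "n_ipd_direct": r.n_ipd_direct,
                    "n_ipd_after_nipt": r.n_ipd_after_nipt,
                    "cost_ipd_k": r.cost_ipd / 1000.0,
                    "total_cost_k": r.total_cost / 1000.0,
                    "n_ds_detected": r.n_ds_detected,
                    "n_ds_confirmed_ipd": r.n_ds_confirmed_ipd,
                    "n_miscarriage": r.n_miscarriage,
                }
            )
        else:
            rows.append(
                {
                    "strategy": strategy.label,
                    "n_screened": int(round_half_away(r.n_screened)),
                    "n_screen_positive": int(
                        round_half_away(r.n_screen_positive_at_threshold)
                    ),
                    "cost_screening_k": money_thousands(r.cost_screening),
                    "n_nipt": int(round_half_away(r.n_nipt)),
                    "cost_nipt_k": money_thousands(r.cost_nipt),
                    "n_ipd_direct": int(round_half_away(r.n_ipd_direct)),
                    "n_ipd_after_nipt": int(round_half_away(r.n_ipd_after_nipt)),
                    "cost_ipd_k": money_thousands(r.cost_ipd),
                    "total_cost_k": money_thousands(r.total_cost),
                    "n_ds_detected": int(round_half_away(r.n_ds_detected)),
                    "n_ds_confirmed_ipd": int(round_half_away(r.n_ds_confirmed_ipd)),
                    "n_miscarriage": int(round_half_away(r.n_miscarriage)),
                }
            )
    return pd.DataFrame(rows, columns=TABLE3_COLUMNS)


def _fmt_count(x: float, raw: bool) -> float:
    return x if raw else int(round_half_away(x))


def table4_frame(
    params: ScreeningParams,
    psa: PsaResult | None = None,
    raw: bool = False,
) -> pd.DataFrame:
    """Incremental outcomes versus the current pathway, with 95%
    uncertainty intervals when a PSA result is supplied."""
    strategies = [s for s in enumerate_strategies() if not s.is_current]
    rows = []
    for s in strategies:
        inc = incremental(params, s)
        row: dict[str, object] = {
            "strategy": s.label,
            "d_ds_detected": _fmt_count(inc.d_ds_detected, raw),
            "d_ds_confirmed_ipd": _fmt_count(inc.d_ds_confirmed_ipd, raw),
            "ipd_avoided": _fmt_count(inc.ipd_avoided, raw),
            "miscarriage_avoided": inc.miscarriage_avoided
            if raw
            else round_half_away(inc.miscarriage_avoided, 1),
            "d_total_cost_k": inc.d_total_cost / 1000.0
            if raw
            else money_thousands(inc.d_total_cost),
        }
        if psa is not None:
            for fld, col in [
                ("d_ds_detected", "d_ds_detected"),
                ("d_ds_confirmed_ipd", "d_ds_confirmed_ipd"),
                ("ipd_avoided", "ipd_avoided"),
                ("miscarriage_avoided", "miscarriage_avoided"),
                ("d_total_cost", "d_total_cost_k"),
            ]:
                lo = psa.lo.loc[s.label, fld]
                hi = psa.hi.loc[s.label, fld]
                if fld == "d_total_cost":
                    lo, hi = lo / 1000.0, hi / 1000.0
                if not raw:
                    nd = 1 if fld == "miscarriage_avoided" else 0
                    lo, hi = round_half_away(lo, nd), round_half_away(hi, nd)
                    if nd == 0:
                        lo, hi = int(lo), int(hi)
                row[f"{col}_lo"], row[f"{col}_hi"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows)


def table5_frame(rows: list[ScenarioRow], raw: bool = False) -> pd.DataFrame:
    out = []
    for r in rows:
        out.append(
            {
                "scenario": r.label,
                "u_nipt_pct": round_half_away(100 * r.u_nipt_high, 1),
                "u_ipd_pct": round_half_away(100 * r.u_direct_ipd, 1),
                "u_total_pct": round_half_away(100 * r.u_total, 1),
                "d_cost_direct_k": r.d_cost_direct / 1000.0
                if raw
                else money_thousands(r.d_cost_direct),
                "d_cost_nodirect_k": r.d_cost_nodirect / 1000.0
                if raw
                else money_thousands(r.d_cost_nodirect),
            }
        )
    return pd.DataFrame(out)
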