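"""Deterministic decision-tree evaluation of each testing strategy.

The model propagates the annual screening population through the pathway
with expected-value (cohort-mean) arithmetic: fractional people are carried
internally and rounded only at presentation.  Money is in GBP.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .params import CURRENT, ParamError, ScreeningParams, Strategy

__all__ = [
    "PathwayResult",
    "IncrementalResult",
    "per_screen_cost",
    "nipt_unit_cost",
    "evaluate_pathway",
    "incremental",
]


@dataclass(frozen=True)
class PathwayResult:
    """Counts, costs and outcomes of one strategy at population scale."""

    strategy: Strategy
    n_screened: float
    n_screen_positive_at_threshold: float
    cost_screening: float
    n_nipt: float
    cost_nipt: float
    n_ipd_direct: float
    n_ipd_after_nipt: float
    cost_ipd: float
    total_cost: float
    n_ds_detected: float
    n_ds_confirmed_ipd: float
    n_miscarriage: float

    @property
    def n_ipd_total(self) -> float:
        return self.n_ipd_direct + self.n_ipd_after_nipt


@dataclass(frozen=True)
class IncrementalResult:
    """Differences of one contingent strategy versus the current pathway.

    ``ipd_avoided`` and ``miscarriage_avoided`` are sign-flipped
    (current minus strategy) so that positive values are benefits.
    Interval fields are populated only by the probabilistic sensitivity
    analysis.
    """

    strategy: Strategy
    d_ds_detected: float
    d_ds_confirmed_ipd: float
    ipd_avoided: float
    miscarriage_avoided: float
    d_total_cost: float
    d_ds_detected_ci: tuple[float, float] | None = None
    d_ds_confirmed_ipd_ci: tuple[float, float] | None = None
    ipd_avoided_ci: tuple[float, float] | None = None
    miscarriage_avoided_ci: tuple[float, float] | None = None
    d_total_cost_ci: tuple[float, float] | None = None

    def with_intervals(self, **cis: tuple[float, float]) -> "IncrementalResult":
        return replace(self, **{f"{k}_ci": v for k, v in cis.items()})


#: Fields of :class:`IncrementalResult` carrying model outputs.
INCREMENTAL_FIELDS = (
    "d_ds_detected",
    "d_ds_confirmed_ipd",
    "ipd_avoided",
    "miscarriage_avoided",
    "d_total_cost",
)


def per_screen_cost(params: ScreeningParams) -> float:
    """Mix-weighted cost of one first-line screen."""
    return params.p_combined * params.c_combined + params.p_quadruple * params.c_quadruple


def nipt_unit_cost(params: ScreeningParams) -> float:
    """Cost of one NIPT episode.

    A repeated test incurs the laboratory component only, weighted by the
    repeat probability; counselling and phlebotomy are not repeated.
    """
    base = params.c_nipt_lab + params.c_nipt_counsel + params.c_nipt_phleb
    return base + params.p_nipt_repeat * params.c_nipt_lab


def _intermediate_fraction(params: ScreeningParams, strategy: Strategy) -> float:
    if strategy.threshold == 500:
        return params.p_risk_int500
    if strategy.threshold == 1000:
        return params.p_risk_int1000
    return 0.0


def evaluate_pathway(params: ScreeningParams, strategy: Strategy) -> PathwayResult:
    """Evaluate one strategy over the whole screening population."""
    n_screened = params.population_size * params.u_screen
    high = n_screened * params.p_risk_high
    cost_screening = n_screened * per_screen_cost(params)

    if strategy.is_current:
        n_ipd_direct = high * params.u_ipd_current
        n_detected = n_confirmed = n_ipd_direct * params.p_ipd_pos_current
        n_nipt = 0.0
        n_ipd_after = 0.0
        cost_nipt = 0.0
        # the group offered further testing is the >=1/150 band
        n_positive = high
    else:
        intermediate = n_screened * _intermediate_fraction(params, strategy)
        n_positive = high + intermediate
        if strategy.direct_ipd_allowed:
            nipt_high = high * params.u_nipt_high
            n_ipd_direct = high * params.u_direct_ipd
            p_pos_high = params.p_nipt_pos_high
        else:
            nipt_high = high * params.u_nipt_high_nodirect
            n_ipd_direct = 0.0
            p_pos_high = params.p_nipt_pos_high_nodirect
        nipt_int = intermediate * params.u_nipt_int
        n_nipt = nipt_high + nipt_int
        p_pos_int = (
            params.p_nipt_pos_int500
            if strategy.threshold == 500
            else params.p_nipt_pos_int1000
        )
        nipt_positive = nipt_high * p_pos_high + nipt_int * p_pos_int
        n_ipd_after = nipt_positive * params.u_ipd_after_nipt
        n_detected = n_ipd_direct * params.p_ipd_pos_direct + nipt_positive
        n_confirmed = (
            n_ipd_direct * params.p_ipd_pos_direct
            + n_ipd_after * params.p_ipd_pos_after_nipt
        )
        cost_nipt = n_nipt * nipt_unit_cost(params)

    n_ipd_total = n_ipd_direct + n_ipd_after
    cost_ipd = n_ipd_total * params.c_ipd
    return PathwayResult(
        strategy=strategy,
        n_screened=n_screened,
        n_screen_positive_at_threshold=n_positive,
        cost_screening=cost_screening,
        n_nipt=n_nipt,
        cost_nipt=cost_nipt,
        n_ipd_direct=n_ipd_direct,
        n_ipd_after_nipt=n_ipd_after,
        cost_ipd=cost_ipd,
        total_cost=cost_screening + cost_nipt + cost_ipd,
        n_ds_detected=n_detected,
        n_ds_confirmed_ipd=n_confirmed,
        n_miscarriage=n_ipd_total * params.p_ipd_miscarriage,
    )


def incremental(params: ScreeningParams, strategy: Strategy) -> IncrementalResult:
    """Point-estimate deltas of ``strategy`` versus the current pathway."""
    if strategy.is_current:
        raise ParamError("incremental comparison requires a contingent strategy")
    new = evaluate_pathway(params, strategy)
    cur = evaluate_pathway(params, CURRENT)
    return IncrementalResult(
        strategy=strategy,
        d_ds_detected=new.n_ds_detected - cur.n_ds_detected,
        d_ds_confirmed_ipd=new.n_ds_confirmed_ipd - cur.n_ds_confirmed_ipd,
        ipd_avoided=cur.n_ipd_total - new.n_ipd_total,
        miscarriage_avoided=cur.n_miscarriage - new.n_miscarriage,
        d_total_cost=new.total_cost - cur.total_cost,
    )
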