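"""Individual-level synthetic cohorts with the screening-pathway flow.

Each woman's trajectory (booking → screening → risk band → testing choice →
test result → confirmatory testing → outcome) is drawn by sequential
Bernoulli/multinomial draws from a :class:`ScreeningParams` set, under a
given testing strategy.  Cohorts are held as a :class:`pandas.DataFrame`
with one row per woman and columns named after :class:`CohortRecord`
fields, and can be written/read as plain CSV.

The module also estimates the generating parameters back from a cohort
(with exact binomial intervals) and computes diagnostic accuracy summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .params import ParamError, ScreeningParams, Strategy

__all__ = [
    "CohortConfig",
    "CohortRecord",
    "AccuracyCounts",
    "ParamEstimates",
    "simulate_cohort",
    "estimate_params",
    "diagnostic_accuracy",
    "accuracy_counts",
    "cohort_counts",
    "clopper_pearson",
    "write_cohort",
    "read_cohort",
]

NONE = "none"

COHORT_COLUMNS = [
    "id",
    "booked",
    "screened",
    "screen_type",
    "risk_band",
    "sub_band",
    "true_status",
    "choice",
    "nipt_result",
    "nipt_repeated",
    "confirmatory_ipd",
    "ipd_result",
    "procedure_miscarriage",
    "outcome",
]

BAND_BELOW = "<1/1000"
BAND_INT = "1/151-1/1000"
BAND_HIGH = ">=1/150"
SUB_500 = "1/151-1/500"
SUB_1000 = "1/501-1/1000"


@dataclass(frozen=True)
class CohortRecord:
    """One woman's trajectory; mirrors one row of the cohort frame."""

    id: int
    booked: bool
    screened: bool
    screen_type: str  # combined | quadruple | none
    risk_band: str  # <1/1000 | 1/151-1/1000 | >=1/150 | none
    sub_band: str  # 1/151-1/500 | 1/501-1/1000 | none
    true_status: str  # unaffected | DS
    choice: str  # nipt | direct_ipd | decline | none
    nipt_result: str  # negative | positive | none
    nipt_repeated: bool
    confirmatory_ipd: bool
    ipd_result: str  # negative | positive | none
    procedure_miscarriage: bool
    outcome: str  # continue | termination | miscarriage | lost_to_followup


@dataclass(frozen=True)
class CohortConfig:
    """Generation knobs not part of the pathway parameter set."""

    #: probability a tested woman is lost to follow-up after her testing choice
    loss_to_followup: float = 0.06
    #: probability a positive NIPT is discordant (unaffected pregnancy);
    #: None derives 1 - p_ipd_pos_after_nipt from the parameter set, the
    #: study-observed alternative being 5/55
    discordant_positive_rate: float | None = None
    #: continuation probability given a confirmed diagnosis
    continuation_after_nipt: float = 13 / 42
    continuation_after_direct: float = 2 / 29


@dataclass(frozen=True)
class AccuracyCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ParamError("accuracy counts must be non-negative")


def simulate_cohort(
    params: ScreeningParams,
    n_booked: int,
    scenario: Strategy,
    seed: int,
    config: CohortConfig | None = None,
) -> pd.DataFrame:
    """Draw a synthetic cohort of ``n_booked`` women under ``scenario``."""
    if n_booked < 1:
        raise ParamError(f"n_booked must be >= 1, got {n_booked}")
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    n = n_booked

    screened = rng.random(n) < params.u_screen
    screen_type = np.full(n, NONE, dtype=object)
    screen_type[screened] = np.where(
        rng.random(screened.sum()) < params.p_combined, "combined", "quadruple"
    )

    # risk band among screened women
    band = np.full(n, NONE, dtype=object)
    u = rng.random(n)
    band[screened] = BAND_BELOW
    band[screened & (u < params.p_risk_high + params.p_risk_int1000)] = BAND_INT
    band[screened & (u < params.p_risk_high)] = BAND_HIGH
    high = band == BAND_HIGH
    inter = band == BAND_INT

    sub_band = np.full(n, NONE, dtype=object)
    p_sub500 = (
        params.p_risk_int500 / params.p_risk_int1000
        if params.p_risk_int1000 > 0
        else 0.0
    )
    sub_band[inter] = np.where(
        rng.random(inter.sum()) < p_sub500, SUB_500, SUB_1000
    )

    # testing choice
    choice = np.full(n, NONE, dtype=object)
    u = rng.random(n)
    if scenario.is_current:
        choice[high] = np.where(u[high] < params.u_ipd_current, "direct_ipd", "decline")
        p_pos_high_nipt = 0.0
        p_pos_int = 0.0
        p_pos_direct = params.p_ipd_pos_current
        offered_int = np.zeros(n, dtype=bool)
    else:
        if scenario.direct_ipd_allowed:
            c = np.full(high.sum(), "decline", dtype=object)
            uh = u[high]
            c[uh < params.u_nipt_high + params.u_direct_ipd] = "direct_ipd"
            c[uh < params.u_nipt_high] = "nipt"
            choice[high] = c
            p_pos_high_nipt = params.p_nipt_pos_high
        else:
            choice[high] = np.where(
                u[high] < params.u_nipt_high_nodirect, "nipt", "decline"
            )
            p_pos_high_nipt = params.p_nipt_pos_high_nodirect
        if scenario.threshold == 1000:
            offered_int = inter
            p_pos_int = params.p_nipt_pos_int1000
        elif scenario.threshold == 500:
            offered_int = inter & (sub_band == SUB_500)
            p_pos_int = params.p_nipt_pos_int500
        else:
            offered_int = np.zeros(n, dtype=bool)
            p_pos_int = 0.0
        choice[offered_int] = np.where(
            u[offered_int] < params.u_nipt_int, "nipt", "decline"
        )
        p_pos_direct = params.p_ipd_pos_direct

    chose_nipt = choice == "nipt"
    chose_direct = choice == "direct_ipd"

    # NIPT result: band-specific positive rate; failed/inconclusive tests
    # are folded into a repeat flag on the final result
    nipt_result = np.full(n, NONE, dtype=object)
    p_pos = np.where(high, p_pos_high_nipt, p_pos_int)
    nipt_pos = chose_nipt & (rng.random(n) < p_pos)
    nipt_result[chose_nipt] = "negative"
    nipt_result[nipt_pos] = "positive"
    nipt_repeated = chose_nipt & (rng.random(n) < params.p_nipt_repeat)

    # true status: NIPT is fully sensitive, so negatives are unaffected;
    # positives are discordant at a configurable per-positive rate
    discordant = (
        config.discordant_positive_rate
        if config.discordant_positive_rate is not None
        else 1.0 - params.p_ipd_pos_after_nipt
    )
    direct_pos = chose_direct & (rng.random(n) < p_pos_direct)
    true_ds = (nipt_pos & (rng.random(n) >= discordant)) | direct_pos

    lost = (chose_nipt | chose_direct) & (rng.random(n) < config.loss_to_followup)

    confirmatory = nipt_pos & ~lost & (rng.random(n) < params.u_ipd_after_nipt)
    had_ipd = chose_direct | confirmatory
    ipd_result = np.full(n, NONE, dtype=object)
    ipd_result[had_ipd] = "negative"
    ipd_result[had_ipd & true_ds] = "positive"

    miscarried = had_ipd & (rng.random(n) < params.p_ipd_miscarriage)

    diagnosed = ipd_result == "positive"
    p_cont = np.where(chose_direct, config.continuation_after_direct, config.continuation_after_nipt)
    continues = rng.random(n) < p_cont
    outcome = np.full(n, "continue", dtype=object)
    outcome[diagnosed & ~continues] = "termination"
    outcome[miscarried] = "miscarriage"
    outcome[lost] = "lost_to_followup"

    return pd.DataFrame(
        {
            "id": np.arange(n),
            "booked": np.ones(n, dtype=bool),
            "screened": screened,
            "screen_type": screen_type,
            "risk_band": band,
            "sub_band": sub_band,
            "true_status": np.where(true_ds, "DS", "unaffected"),
            "choice": choice,
            "nipt_result": nipt_result,
            "nipt_repeated": nipt_repeated,
            "confirmatory_ipd": confirmatory,
            "ipd_result": ipd_result,
            "procedure_miscarriage": miscarried,
            "outcome": outcome,
        }
    )


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact equal-tailed binomial interval from beta quantiles."""
    if n <= 0:
        raise ParamError(f"denominator must be positive, got {n}")
    if not 0 <= k <= n:
        raise ParamError(f"need 0 <= k <= n, got k={k}, n={n}")
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(beta_dist.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1.0 - a, k + 1, n - k))
    return lo, hi


@dataclass
class ParamEstimates:
    """Cohort-estimated parameters with exact binomial intervals.

    ``params`` carries estimated proportions where a denominator existed,
    falling back to ``base`` values (and costs unchanged) elsewhere;
    ``intervals``/``counts`` are keyed by field name and cover only the
    estimable fields.
    """

    params: ScreeningParams
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def estimable(self) -> set[str]:
        return set(self.intervals)


def _add(
    est: dict, intervals: dict, counts: dict, name: str, k: int, n: int
) -> None:
    if n <= 0:
        return
    est[name] = k / n
    intervals[name] = clopper_pearson(k, n)
    counts[name] = (k, n)


def estimate_params(
    cohort: pd.DataFrame, base: ScreeningParams | None = None
) -> ParamEstimates:
    """Estimate every recoverable proportion from a cohort frame.

    Whether high-band uptake refers to the direct-allowed or the no-direct
    scenario is inferred from the observed choices.  Fields whose
    denominator is empty are left at the base value and excluded from the
    interval map.
    """
    if len(cohort) == 0:
        raise ParamError("cohort is empty")
    base = base or ScreeningParams()
    est: dict[str, float] = {}
    intervals: dict[str, tuple[float, float]] = {}
    counts: dict[str, tuple[int, int]] = {}

    def add(name: str, k: int, n: int) -> None:
        _add(est, intervals, counts, name, int(k), int(n))

    booked = cohort["booked"]
    screened = cohort["screened"]
    add("u_screen", screened.sum(), booked.sum())
    add("p_combined", (cohort["screen_type"] == "combined").sum(), screened.sum())

    high = cohort["risk_band"] == BAND_HIGH
    inter = cohort["risk_band"] == BAND_INT
    sub500 = cohort["sub_band"] == SUB_500
    add("p_risk_high", high.sum(), screened.sum())
    add("p_risk_int1000", inter.sum(), screened.sum())
    add("p_risk_int500", (inter & sub500).sum(), screened.sum())

    nipt = cohort["choice"] == "nipt"
    direct = cohort["choice"] == "direct_ipd"
    declined = cohort["choice"] == "decline"
    contingent = bool(nipt.any())
    nipt_pos = cohort["nipt_result"] == "positive"
    ipd_pos = cohort["ipd_result"] == "positive"
    confirmatory = cohort["confirmatory_ipd"]
    lost = cohort["outcome"] == "lost_to_followup"

    if not contingent:
        # current pathway: only the invasive-testing arm is observable
        add("u_ipd_current", (high & direct).sum(), high.sum())
        add("p_ipd_pos_current", (high & direct & ipd_pos).sum(), direct.sum())
    else:
        direct_allowed = bool((high & direct).any())
        if direct_allowed:
            add("u_nipt_high", (high & nipt).sum(), high.sum())
            add("u_direct_ipd", (high & direct).sum(), high.sum())
            add("p_nipt_pos_high", (high & nipt & nipt_pos).sum(), (high & nipt).sum())
        else:
            add("u_nipt_high_nodirect", (high & nipt).sum(), high.sum())
            add(
                "p_nipt_pos_high_nodirect",
                (high & nipt & nipt_pos).sum(),
                (high & nipt).sum(),
            )
        offered_int = inter & (nipt | declined)
        add("u_nipt_int", (offered_int & nipt).sum(), offered_int.sum())
        int_nipt = inter & nipt
        if bool((int_nipt & ~sub500).any()):
            add("p_nipt_pos_int1000", (int_nipt & nipt_pos).sum(), int_nipt.sum())
        else:
            add("p_nipt_pos_int500", (int_nipt & nipt_pos).sum(), int_nipt.sum())
        add("p_nipt_repeat", cohort["nipt_repeated"].sum(), nipt.sum())
        add("u_ipd_after_nipt", confirmatory.sum(), (nipt_pos & ~lost).sum())
        add("p_ipd_pos_after_nipt", (confirmatory & ipd_pos).sum(), confirmatory.sum())
        add("p_ipd_pos_direct", (direct & ipd_pos).sum(), direct.sum())

    had_ipd = direct | confirmatory
    add("p_ipd_miscarriage", cohort["procedure_miscarriage"].sum(), had_ipd.sum())

    merged = base.to_dict()
    merged.update(est)
    if "p_combined" in est:
        merged["p_quadruple"] = 1.0 - est["p_combined"]
    return ParamEstimates(ScreeningParams(**merged), intervals, counts)


def diagnostic_accuracy(
    counts: AccuracyCounts, level: float = 0.95
) -> dict[str, tuple[float, float, float] | None]:
    """Sensitivity, specificity and PPV with exact equal-tailed intervals.

    Returns ``{stat: (point, lo, hi)}``; a statistic whose denominator is
    zero maps to ``None``.  All-zero counts are an error.
    """
    if counts.tp + counts.fp + counts.tn + counts.fn == 0:
        raise ParamError("all accuracy counts are zero")

    def stat(k: int, n: int) -> tuple[float, float, float] | None:
        if n == 0:
            return None
        lo, hi = clopper_pearson(k, n, level)
        return k / n, lo, hi

    return {
        "sensitivity": stat(counts.tp, counts.tp + counts.fn),
        "specificity": stat(counts.tn, counts.tn + counts.fp),
        "ppv": stat(counts.tp, counts.tp + counts.fp),
    }


def accuracy_counts(cohort: pd.DataFrame) -> AccuracyCounts:
    """NIPT accuracy counts against true pregnancy status.

    Positives count as confirmed only when a confirmatory invasive test was
    done or the pregnancy outcome is known (not lost to follow-up).
    """
    tested = cohort["choice"] == "nipt"
    known = cohort["confirmatory_ipd"] | (cohort["outcome"] != "lost_to_followup")
    pos = tested & known & (cohort["nipt_result"] == "positive")
    neg = tested & known & (cohort["nipt_result"] == "negative")
    ds = cohort["true_status"] == "DS"
    return AccuracyCounts(
        tp=int((pos & ds).sum()),
        fp=int((pos & ~ds).sum()),
        tn=int((neg & ~ds).sum()),
        fn=int((neg & ds).sum()),
    )


def cohort_counts(cohort: pd.DataFrame) -> dict[str, float]:
    """Pathway-level counts from a cohort, comparable (after scaling) with
    the deterministic :class:`~niptcca.model.PathwayResult` fields."""
    nipt = cohort["choice"] == "nipt"
    direct = cohort["choice"] == "direct_ipd"
    nipt_pos = cohort["nipt_result"] == "positive"
    confirmatory = cohort["confirmatory_ipd"]
    ipd_pos = cohort["ipd_result"] == "positive"
    return {
        "n_screened": float(cohort["screened"].sum()),
        "n_nipt": float(nipt.sum()),
        "n_ipd_direct": float(direct.sum()),
        "n_ipd_after_nipt": float(confirmatory.sum()),
        "n_ds_detected": float((nipt_pos | (direct & ipd_pos)).sum()),
        "n_ds_confirmed_ipd": float(ipd_pos.sum()),
        "n_miscarriage": float(cohort["procedure_miscarriage"].sum()),
    }


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ParamError(f"cohort file missing columns: {sorted(missing)}")
    for col in ("booked", "screened", "nipt_repeated", "confirmatory_ipd", "procedure_miscarriage"):
        df[col] = df[col].astype(bool)
    return df[COHORT_COLUMNS]
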