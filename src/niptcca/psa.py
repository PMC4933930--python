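"""Probabilistic sensitivity analysis.

Parameter uncertainty is propagated by Monte-Carlo sampling: beta
distributions for proportions (hyperparameters built from effective study
denominators), gamma distributions for the uncertain unit costs, and fixed
point values elsewhere.  High-risk NIPT uptake and direct-invasive uptake
are sampled jointly via a Dirichlet over {NIPT, direct IPD, decline} so the
two complementary choices stay negatively correlated.  Equal-tailed
percentile intervals summarise each output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import INCREMENTAL_FIELDS, IncrementalResult, incremental
from .params import ParamError, ScreeningParams, Strategy, enumerate_strategies

__all__ = ["DistSpec", "PsaConfig", "PsaResult", "run_psa", "default_specs"]


@dataclass(frozen=True)
class DistSpec:
    """Sampling distribution for one parameter.

    ``kind`` is ``beta``, ``gamma`` or ``fixed``.  A beta may be given
    explicit ``(alpha, beta)`` hyperparameters or an effective denominator
    ``n_eff`` from which ``alpha = p * n_eff``, ``beta = (1 - p) * n_eff``
    are built around the point estimate ``p``.  A gamma may be given
    ``(shape, scale)`` or a coefficient of variation ``cv`` around the
    point estimate.
    """

    kind: str
    alpha: float | None = None
    beta: float | None = None
    n_eff: float | None = None
    shape: float | None = None
    scale: float | None = None
    cv: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("beta", "gamma", "fixed"):
            raise ParamError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "beta" and self.n_eff is None and (
            self.alpha is None or self.beta is None
        ):
            raise ParamError("beta spec needs (alpha, beta) or n_eff")
        if self.kind == "gamma" and self.cv is None and (
            self.shape is None or self.scale is None
        ):
            raise ParamError("gamma spec needs (shape, scale) or cv")

    def sample(self, rng: np.random.Generator, point: float, size: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(size, point)
        if self.kind == "beta":
            if self.n_eff is not None:
                a = point * self.n_eff
                b = (1.0 - point) * self.n_eff
            else:
                a, b = self.alpha, self.beta
            if a <= 0 or b <= 0:
                raise ParamError(
                    f"beta hyperparameters must be positive, got alpha={a}, beta={b}"
                )
            return rng.beta(a, b, size)
        # gamma
        if self.cv is not None:
            shape = 1.0 / self.cv**2
            scale = point * self.cv**2
        else:
            shape, scale = self.shape, self.scale
        if shape <= 0 or scale <= 0:
            raise ParamError("gamma shape and scale must be positive")
        return rng.gamma(shape, scale, size)


FIXED = DistSpec("fixed")

# Effective denominators for the beta distributions: cohort-study group
# sizes where the parameter was observed, historical-audit sizes for the
# pre-NIPT pathway quantities.
_DEFAULT_N_EFF: dict[str, float] = {
    "u_screen": 40_527,
    "p_risk_high": 30_790,
    "p_risk_int500": 30_790,
    "p_risk_int1000": 30_790,
    "u_nipt_high": 934,
    "u_direct_ipd": 934,
    "u_nipt_high_nodirect": 934,
    "u_nipt_int": 2_241,
    "u_ipd_current": 1_111,
    "u_ipd_after_nipt": 59,
    "p_nipt_pos_high": 695,
    "p_nipt_pos_high_nodirect": 861,
    "p_nipt_pos_int500": 1_799,
    "p_nipt_pos_int1000": 1_799,
    "p_nipt_repeat": 2_494,
    "p_ipd_pos_current": 667,
    "p_ipd_pos_direct": 166,
    "p_ipd_pos_after_nipt": 47,
    "p_ipd_miscarriage": 1_000,
}

_DEFAULT_COST_CV = 0.2


def default_specs() -> dict[str, DistSpec]:
    """Default distribution assignment: beta for every proportion, gamma
    (CV 20%) for the two uncertain unit costs, everything else fixed."""
    specs = {name: FIXED for name in ScreeningParams.field_names()}
    for name, n_eff in _DEFAULT_N_EFF.items():
        specs[name] = DistSpec("beta", n_eff=n_eff)
    specs["c_ipd"] = DistSpec("gamma", cv=_DEFAULT_COST_CV)
    specs["c_nipt_lab"] = DistSpec("gamma", cv=_DEFAULT_COST_CV)
    return specs


@dataclass
class PsaConfig:
    n_sims: int = 1000
    seed: int = 0
    specs: dict[str, DistSpec] = field(default_factory=default_specs)
    #: sample u_nipt_high / u_direct_ipd jointly (Dirichlet over
    #: {NIPT, direct IPD, decline}); disabled automatically when either
    #: is fixed.
    couple_further_testing: bool = True

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ParamError(f"n_sims must be >= 1, got {self.n_sims}")
        unknown = set(self.specs) - set(ScreeningParams.field_names())
        if unknown:
            raise ParamError(f"distribution specs for unknown parameters: {sorted(unknown)}")


@dataclass
class PsaResult:
    """Per-strategy simulated distributions of the incremental outputs.

    ``draws`` holds one row per simulation with a column per
    (strategy label, output field); ``point`` the deterministic values and
    ``lo``/``hi`` the 2.5th/97.5th percentiles, each indexed by strategy
    label with the output fields as columns.
    """

    draws: pd.DataFrame
    point: pd.DataFrame
    lo: pd.DataFrame
    hi: pd.DataFrame
    n_sims: int
    seed: int

    def to_incrementals(self, strategies: list[Strategy]) -> list[IncrementalResult]:
        out = []
        for s in strategies:
            base = IncrementalResult(
                strategy=s,
                **{f: self.point.loc[s.label, f] for f in INCREMENTAL_FIELDS},
            )
            cis = {
                f: (self.lo.loc[s.label, f], self.hi.loc[s.label, f])
                for f in INCREMENTAL_FIELDS
            }
            out.append(base.with_intervals(**cis))
        return out


def _sample_parameter_draws(
    params: ScreeningParams, config: PsaConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    n = config.n_sims
    draws: dict[str, np.ndarray] = {}
    coupled = (
        config.couple_further_testing
        and config.specs.get("u_nipt_high", FIXED).kind == "beta"
        and config.specs.get("u_direct_ipd", FIXED).kind == "beta"
    )
    if coupled:
        p_nipt, p_direct = params.u_nipt_high, params.u_direct_ipd
        p_decline = max(1.0 - p_nipt - p_direct, 1e-12)
        spec = config.specs["u_nipt_high"]
        conc = spec.n_eff if spec.n_eff is not None else (spec.alpha + spec.beta)
        alpha = conc * np.array([p_nipt, p_direct, p_decline])
        if np.any(alpha <= 0):
            raise ParamError("Dirichlet concentrations must be positive")
        sample = rng.dirichlet(alpha, size=n)
        draws["u_nipt_high"] = sample[:, 0]
        draws["u_direct_ipd"] = sample[:, 1]
    for name in ScreeningParams.field_names():
        if name in draws:
            continue
        spec = config.specs.get(name, FIXED)
        draws[name] = spec.sample(rng, getattr(params, name), n)
    # keep the nested risk bands ordered; independent betas can in
    # principle invert them at tiny effective denominators
    lo = np.minimum(draws["p_risk_int500"], draws["p_risk_int1000"])
    hi = np.maximum(draws["p_risk_int500"], draws["p_risk_int1000"])
    draws["p_risk_int500"], draws["p_risk_int1000"] = lo, hi
    return draws


def run_psa(
    params: ScreeningParams,
    config: PsaConfig,
    strategies: list[Strategy] | None = None,
) -> PsaResult:
    """Run the PSA: identical seed and config give a bit-identical result."""
    if strategies is None:
        strategies = [s for s in enumerate_strategies() if not s.is_current]
    if any(s.is_current for s in strategies):
        raise ParamError("PSA summarises incremental outputs; drop the current strategy")

    rng = np.random.default_rng(config.seed)
    draws = _sample_parameter_draws(params, config, rng)

    columns: dict[tuple[str, str], np.ndarray] = {
        (s.label, f): np.empty(config.n_sims) for s in strategies for f in INCREMENTAL_FIELDS
    }
    names = list(draws)
    for i in range(config.n_sims):
        sampled = params.replace(**{k: float(draws[k][i]) for k in names})
        for s in strategies:
            inc = incremental(sampled, s)
            for f in INCREMENTAL_FIELDS:
                columns[(s.label, f)][i] = getattr(inc, f)

    draw_df = pd.DataFrame(columns)
    draw_df.columns = pd.MultiIndex.from_tuples(draw_df.columns, names=["strategy", "field"])

    labels = [s.label for s in strategies]
    point = pd.DataFrame(
        {
            f: [getattr(incremental(params, s), f) for s in strategies]
            for f in INCREMENTAL_FIELDS
        },
        index=labels,
    )
    qs = draw_df.quantile([0.025, 0.975], interpolation="linear")
    lo = qs.loc[0.025].unstack("field").loc[labels, list(INCREMENTAL_FIELDS)]
    hi = qs.loc[0.975].unstack("field").loc[labels, list(INCREMENTAL_FIELDS)]
    return PsaResult(
        draws=draw_df, point=point, lo=lo, hi=hi, n_sims=config.n_sims, seed=config.seed
    )
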