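"""Model parameterisation: screening-programme inputs and testing strategies.

The parameter set covers uptake proportions, risk-band frequencies, test
outcome probabilities and unit costs (2012/13 GBP).  Two named presets ship
with the package: ``rapid`` (study-cohort derived) and ``national``
(routine-statistics derived).  Probabilities are stored as proportions in
[0, 1]; the file reader accepts percentages when the file declares
``units: percent``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterator

import yaml

__all__ = [
    "ScreeningParams",
    "Strategy",
    "PRESETS",
    "THRESHOLDS",
    "enumerate_strategies",
    "get_preset",
    "load_params",
    "write_params",
]

#: Risk thresholds at which contingent testing may be offered, as the
#: denominator of the 1/N screening risk.
THRESHOLDS = (150, 500, 1000)

_PROPORTION_FIELDS = frozenset(
    {
        "p_combined",
        "p_quadruple",
        "u_screen",
        "p_risk_high",
        "p_risk_int500",
        "p_risk_int1000",
        "u_nipt_high",
        "u_nipt_high_nodirect",
        "u_nipt_int",
        "u_direct_ipd",
        "u_ipd_current",
        "u_ipd_after_nipt",
        "p_nipt_pos_high",
        "p_nipt_pos_high_nodirect",
        "p_nipt_pos_int500",
        "p_nipt_pos_int1000",
        "p_nipt_repeat",
        "p_ipd_pos_current",
        "p_ipd_pos_direct",
        "p_ipd_pos_after_nipt",
        "p_ipd_miscarriage",
    }
)

_COST_FIELDS = frozenset(
    {
        "c_combined",
        "c_quadruple",
        "c_nipt_lab",
        "c_nipt_counsel",
        "c_nipt_phleb",
        "c_ipd",
    }
)


class ParamError(ValueError):
    """Raised when a parameter file or value violates the model contract."""


@dataclass(frozen=True)
class ScreeningParams:
    """Complete numeric parameterisation of the screening pathway model.

    Proportions are stored on the [0, 1] scale; costs in GBP per test.
    """

    population_size: float = 698_500
    # screening test mix
    p_combined: float = 0.869
    p_quadruple: float = 0.131
    # uptake
    u_screen: float = 0.662
    u_nipt_high: float = 0.725
    u_nipt_high_nodirect: float = 0.91
    u_nipt_int: float = 0.705
    u_direct_ipd: float = 0.20
    u_ipd_current: float = 0.54
    u_ipd_after_nipt: float = 0.804
    # risk-band frequencies among screened women
    p_risk_high: float = 0.023
    p_risk_int500: float = 0.034
    p_risk_int1000: float = 0.075
    # test outcome probabilities
    p_nipt_pos_high: float = 0.04
    p_nipt_pos_high_nodirect: float = 0.079
    p_nipt_pos_int500: float = 0.0038
    p_nipt_pos_int1000: float = 0.0025
    p_nipt_repeat: float = 0.012
    p_ipd_pos_current: float = 0.101
    p_ipd_pos_direct: float = 0.219
    p_ipd_pos_after_nipt: float = 0.901
    p_ipd_miscarriage: float = 0.005
    # unit costs, GBP 2012/13
    c_combined: float = 27.52
    c_quadruple: float = 37.20
    c_nipt_lab: float = 250.0
    c_nipt_counsel: float = 15.96
    c_nipt_phleb: float = 9.0

    c_ipd: float = 650.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check every invariant; raise :class:`ParamError` naming the field."""
        if not self.population_size > 0:
            raise ParamError(
                f"population_size must be > 0, got {self.population_size}"
            )
        for name in sorted(_PROPORTION_FIELDS):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParamError(f"{name} must lie in [0, 1], got {v}")
        for name in sorted(_COST_FIELDS):
            v = getattr(self, name)
            if v < 0:
                raise ParamError(f"{name} must be >= 0, got {v}")
        if abs(self.p_combined + self.p_quadruple - 1.0) > 1e-9:
            raise ParamError(
                "p_combined + p_quadruple must equal 1 (within 1e-9), got "
                f"{self.p_combined} + {self.p_quadruple} = "
                f"{self.p_combined + self.p_quadruple}"
            )
        if self.p_risk_int500 > self.p_risk_int1000:
            raise ParamError(
                "p_risk_int500 must not exceed p_risk_int1000, got "
                f"{self.p_risk_int500} > {self.p_risk_int1000}"
            )

    def replace(self, **changes: float) -> "ScreeningParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


#: Named parameter presets corresponding to the two published input columns.
PRESETS: dict[str, ScreeningParams] = {
    "national": ScreeningParams(),
    "rapid": ScreeningParams(
        p_combined=0.885,
        p_quadruple=0.115,
        u_screen=0.787,
        p_risk_high=0.027,
        p_risk_int500=0.032,
        p_risk_int1000=0.071,
    ),
}


def get_preset(name: str) -> ScreeningParams:
    try:
        return PRESETS[name]
    except KeyError:
        raise ParamError(
            f"unknown preset {name!r}; valid presets: {sorted(PRESETS)}"
        ) from None


@dataclass(frozen=True)
class Strategy:
    """A testing policy: the current pathway or a contingent-NIPT variant.

    ``threshold`` is the denominator of the offer risk (150, 500 or 1000)
    and ``direct_ipd_allowed`` records whether high-risk women may choose
    invasive testing without NIPT first.  Both are meaningful only for
    ``mode == "contingent"``.
    """

    mode: str  # "current" | "contingent"
    threshold: int | None = None
    direct_ipd_allowed: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("current", "contingent"):
            raise ParamError(f"unknown strategy mode {self.mode!r}")
        if self.mode == "contingent" and self.threshold not in THRESHOLDS:
            raise ParamError(
                f"contingent threshold must be one of {THRESHOLDS}, "
                f"got {self.threshold}"
            )

    @property
    def is_current(self) -> bool:
        return self.mode == "current"

    @property
    def label(self) -> str:
        if self.is_current:
            return "Current"
        s = f"NIPT >=1/{self.threshold}"
        if not self.direct_ipd_allowed:
            s += " - no direct IPD"
        return s


CURRENT = Strategy("current")


def enumerate_strategies() -> list[Strategy]:
    """All seven strategies in presentation order: current, the three
    contingent thresholds with direct invasive testing, then the three
    no-direct variants."""
    out: list[Strategy] = [CURRENT]
    for allowed in (True, False):
        for thr in (1000, 500, 150):
            out.append(Strategy("contingent", thr, direct_ipd_allowed=allowed))
    return out


def _iter_flat(d: dict) -> Iterator[tuple[str, object]]:
    for k, v in d.items():
        yield str(k), v


def load_params(path: str | Path) -> ScreeningParams:
    """Read a flat key-value (YAML) parameter file.

    Recognised special keys: ``preset`` (name supplying defaults for keys
    not present in the file) and ``units`` (``proportion``, the default, or
    ``percent`` — in which case every proportion field is divided by 100).
    Unknown keys are rejected.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParamError(f"could not parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ParamError(f"{path} must contain a flat key-value mapping")

    preset_name = raw.pop("preset", None)
    units = raw.pop("units", "proportion")
    if units not in ("proportion", "percent"):
        raise ParamError(f"units must be 'proportion' or 'percent', got {units!r}")

    known = set(ScreeningParams.field_names())
    values: dict[str, float] = {}
    for key, value in _iter_flat(raw):
        if key not in known:
            raise ParamError(f"unknown parameter key {key!r} in {path}")
        v = float(value)  # type: ignore[arg-type]
        if units == "percent" and key in _PROPORTION_FIELDS:
            v /= 100.0
        values[key] = v

    if preset_name is not None:
        base = get_preset(str(preset_name))
        merged = base.to_dict()
        merged.update(values)
        return ScreeningParams(**merged)
    missing = known - values.keys()
    if missing:
        raise ParamError(
            f"missing parameter keys (no preset declared): {sorted(missing)}"
        )
    return ScreeningParams(**values)


def write_params(params: ScreeningParams, path: str | Path) -> None:
    """Write a parameter file that :func:`load_params` round-trips exactly."""
    doc = {"units": "proportion"}
    doc.update(params.to_dict())
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
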