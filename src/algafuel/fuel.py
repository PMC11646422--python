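"""Empirical biodiesel fuel-property prediction and standard compliance.

Eleven fuel properties are predicted from a FAME profile's composition
through published empirical correlations.  Six are affine in the average
degree of unsaturation (ADU):

    KV   = -0.6313 ADU + 5.2065        kinematic viscosity, mm^2/s
    rho  =  0.0055 ADU + 0.8726        density, kg/L
    CP   = -13.356 ADU + 19.994        cloud point, degC
    CN   = -6.6684 ADU + 62.876        cetane number
    IV   =  74.373 ADU + 12.71         iodine value, g I2 / 100 g
    HHV  =  1.7601 ADU + 38.534        higher heating value, MJ/kg

The cold-filter plugging point follows the long-chain saturated factor,
CFPP = 3.1417 LCSF - 16.477.  Oxidative stability follows the combined
linoleic + linolenic content X as OS = 117.9295 / X + 2.5905 hours — the
inverse form: stability worsens as polyunsaturate content rises, and only
the inverse form reproduces measured induction periods on reference
profiles.  The flash point is a multi-term correlation over individual
acid contents (the C18:3 term covering both linolenic isomers).

Predicted properties are screened against the automotive biodiesel
standards ASTM D6751 and EN 14214 and the heating-fuel standard EN 14213,
whose limits ship as an editable JSON data file.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

from .exceptions import ConfigurationError, DomainError
from .fame import FameProfile, ProfileSummary, summarize

__all__ = [
    "FuelProperties",
    "FuelStandard",
    "Bound",
    "Verdict",
    "PropertyVerdict",
    "ComplianceReport",
    "adu_linear_properties",
    "cfpp",
    "oxidative_stability",
    "flash_point",
    "predict_all",
    "check_compliance",
    "load_standard",
    "STANDARD_NAMES",
]

# Slope/intercept pairs of the six ADU-affine correlations.
_ADU_LINEAR = {
    "kv": (-0.6313, 5.2065),
    "rho": (0.0055, 0.8726),
    "cp": (-13.356, 19.994),
    "cn": (-6.6684, 62.876),
    "iv": (74.373, 12.71),
    "hhv": (1.7601, 38.534),
}

_CFPP_SLOPE, _CFPP_INTERCEPT = 3.1417, -16.477
_OS_NUMERATOR, _OS_INTERCEPT = 117.9295, 2.5905

# Flash-point correlation: intercept plus per-acid terms on wt %.
_FP_INTERCEPT = 205.226
_FP_TERMS = {
    (16, 0): 0.083,
    (18, 0): -1.723,
    (18, 1): -0.5717,
    (18, 2): -0.3557,
    (18, 3): -0.46,
    (22, 0): -0.2287,
}

STANDARD_NAMES = ("ASTM D6751", "EN 14214", "EN 14213")


@dataclass(frozen=True)
class FuelProperties:
    """The eleven predicted fuel properties plus the compliance contents.

    Units: kv mm^2/s, rho kg/L, cp/cfpp/fp degC, iv g I2/100 g, hhv MJ/kg,
    os hours; adu, cn, lcsf dimensionless; the two contents wt %.
    """

    condition_label: str
    adu: float
    kv: float
    rho: float
    cp: float
    cn: float
    iv: float
    hhv: float
    lcsf: float
    cfpp: float
    os: float | None
    fp: float
    linolenic_percent: float
    pufa_ge4db_percent: float

    def as_dict(self) -> dict[str, float | None | str]:
        return {
            "condition": self.condition_label,
            "adu": self.adu,
            "kv": self.kv,
            "rho": self.rho,
            "cp": self.cp,
            "cn": self.cn,
            "iv": self.iv,
            "hhv": self.hhv,
            "lcsf": self.lcsf,
            "cfpp": self.cfpp,
            "os": self.os,
            "fp": self.fp,
            "linolenic": self.linolenic_percent,
            "pufa_ge4db": self.pufa_ge4db_percent,
        }


def adu_linear_properties(adu: float) -> dict[str, float]:
    """Evaluate the six ADU-affine correlations.

    Returns ``{"kv", "rho", "cp", "cn", "iv", "hhv"}`` from the *unrounded*
    ADU.  Raises :class:`DomainError` for negative ADU.
    """
    if adu < 0:
        raise DomainError(f"ADU must be >= 0, got {adu}")
    return {name: slope * adu + intercept for name, (slope, intercept) in _ADU_LINEAR.items()}


def cfpp(lcsf: float) -> float:
    """Cold-filter plugging point (degC) from the long-chain saturated factor."""
    if lcsf < 0:
        raise DomainError(f"LCSF must be >= 0, got {lcsf}")
    return _CFPP_SLOPE * lcsf + _CFPP_INTERCEPT


def oxidative_stability(x: float) -> float:
    """Rancimat induction period (hours) from X = linoleic + linolenic wt %.

    Undefined for a profile without polyunsaturates (X <= 0); approaches the
    2.59 h floor as X grows.
    """
    if x <= 0:
        raise DomainError(
            "oxidative stability is undefined for X <= 0 "
            f"(no linoleic/linolenic content); got X = {x}"
        )
    return _OS_NUMERATOR / x + _OS_INTERCEPT


def flash_point(profile: FameProfile) -> float:
    """Flash point (degC) from individual fatty-acid contents.

    Acids are addressed by structure, so the C18:1 term covers any omega
    variant of oleic acid and the C18:3 term the sum of gamma- and
    alpha-linolenic acid; absent acids contribute zero.
    """
    fp = _FP_INTERCEPT
    for (carbons, db), coeff in _FP_TERMS.items():
        fp += coeff * profile.mass_percent_by_structure(carbons, db)
    return fp


def predict_all(profile: FameProfile) -> FuelProperties:
    """Predict all eleven fuel properties for one FAME profile.

    Composes :func:`algafuel.fame.summarize` with the correlations above.
    Every correlation uses the unrounded ADU/LCSF/X.  ``os`` is ``None``
    when the profile has no polyunsaturate content (X = 0).
    """
    s = summarize(profile)
    linear = adu_linear_properties(s.adu)
    os_hours = (
        oxidative_stability(s.x_linoleic_plus_linolenic)
        if s.x_linoleic_plus_linolenic > 0
        else None
    )
    return FuelProperties(
        condition_label=profile.condition_label,
        adu=s.adu,
        lcsf=s.lcsf,
        cfpp=cfpp(s.lcsf),
        os=os_hours,
        fp=flash_point(profile),
        linolenic_percent=s.linolenic_percent,
        pufa_ge4db_percent=s.pufa_ge4db_percent,
        **linear,
    )


# ---------------------------------------------------------------------------
# Standards and compliance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Bound:
    """One property limit of a fuel standard.

    ``lower``/``upper`` may each be ``None`` (one-sided limits).  A strict
    bound excludes equality: a value exactly at a strict lower bound fails
    (e.g. the "> 3 h" oxidative stability minimum), while a value exactly at
    a non-strict bound passes.
    """

    lower: float | None = None
    upper: float | None = None
    lower_strict: bool = False
    upper_strict: bool = False
    units: str = ""

    def check(self, value: float) -> bool:
        if self.lower is not None:
            if value < self.lower or (self.lower_strict and value == self.lower):
                return False
        if self.upper is not None:
            if value > self.upper or (self.upper_strict and value == self.upper):
                return False
        return True

    def margin(self, value: float) -> float:
        """Signed distance to the nearest bound (value - bound)."""
        candidates = [b for b in (self.lower, self.upper) if b is not None]
        nearest = min(candidates, key=lambda b: abs(value - b))
        return value - nearest


@dataclass(frozen=True)
class FuelStandard:
    """A named fuel standard: per-property bounds, others not specified."""

    name: str
    limits: Mapping[str, Bound]

    def __post_init__(self) -> None:
        object.__setattr__(self, "limits", dict(self.limits))


class Verdict(str, enum.Enum):
    PASS = "pass"
    FAIL = "fail"
    NOT_SPECIFIED = "not_specified"


@dataclass(frozen=True)
class PropertyVerdict:
    property: str
    value: float | None
    verdict: Verdict
    margin: float | None  # value - nearest bound; None when not specified


@dataclass(frozen=True)
class ComplianceReport:
    """Per-property verdicts of one property set against one standard."""

    standard_name: str
    condition_label: str
    verdicts: tuple[PropertyVerdict, ...]

    @property
    def overall_pass(self) -> bool:
        return all(v.verdict is not Verdict.FAIL for v in self.verdicts)

    @property
    def failures(self) -> tuple[PropertyVerdict, ...]:
        return tuple(v for v in self.verdicts if v.verdict is Verdict.FAIL)

    def as_dict(self) -> dict:
        return {
            "standard": self.standard_name,
            "condition": self.condition_label,
            "overall": "pass" if self.overall_pass else "fail",
            "properties": [
                {
                    "property": v.property,
                    "value": v.value,
                    "verdict": v.verdict.value,
                    "margin": v.margin,
                }
                for v in self.verdicts
            ],
        }


def _builtin_standards() -> dict:
    with resources.files("algafuel.data").joinpath("fuel_standards.json").open() as fh:
        return json.load(fh)


def load_standard(name: str, cfpp_grade: float | None = None) -> FuelStandard:
    """Load a fuel standard from the packaged limits file.

    ``cfpp_grade`` overrides the seasonal CFPP grade bound (EN 14214 states
    climate-dependent grades from +5 to -20 degC; the packaged default is the
    +5 degC grade).
    """
    data = _builtin_standards()
    key = name.strip().upper().replace(" ", "")
    for std_name, limits in data.items():
        if std_name.upper().replace(" ", "") == key:
            bounds: dict[str, Bound] = {}
            for prop, spec in limits.items():
                bound = Bound(
                    lower=spec.get("lower"),
                    upper=spec.get("upper"),
                    lower_strict=spec.get("lower_strict", False),
                    upper_strict=spec.get("upper_strict", False),
                    units=spec.get("units", ""),
                )
                if prop == "cfpp" and cfpp_grade is not None:
                    bound = Bound(upper=cfpp_grade, units=bound.units)
                bounds[prop] = bound
            return FuelStandard(name=std_name, limits=bounds)
    raise ConfigurationError(
        f"unknown fuel standard {name!r}; known: {', '.join(data)}"
    )


def check_compliance(props: FuelProperties, standard: FuelStandard) -> ComplianceReport:
    """Screen a property set against a standard's limits.

    Properties the standard does not limit are reported ``not_specified``.
    A missing value (``os`` is None for a polyunsaturate-free profile) fails
    any limit on that property, since the standard cannot be demonstrated.
    """
    verdicts = []
    values = props.as_dict()
    for prop in ("kv", "rho", "cn", "iv", "fp", "hhv", "cp", "cfpp", "os",
                 "linolenic", "pufa_ge4db"):
        value = values[prop]
        bound = standard.limits.get(prop)
        if bound is None:
            verdicts.append(PropertyVerdict(prop, value, Verdict.NOT_SPECIFIED, None))
            continue
        if value is None:
            verdicts.append(PropertyVerdict(prop, None, Verdict.FAIL, None))
            continue
        verdict = Verdict.PASS if bound.check(value) else Verdict.FAIL
        verdicts.append(PropertyVerdict(prop, value, verdict, bound.margin(value)))
    return ComplianceReport(
        standard_name=standard.name,
        condition_label=props.condition_label,
        verdicts=tuple(verdicts),
    )
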