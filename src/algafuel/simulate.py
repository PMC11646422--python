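"""Seeded synthetic study generator.

Emulates the structure of a salinity-gradient batch-culture study on a
euryhaline *Dunaliella*-type microalga so that every analysis stage can be
tested without measured data:

* growth curves with a lag phase, an exponential phase and logistic
  saturation, sampled every two days over a 35-day run in triplicate;
* compositional FAME profiles that always close to 100 % (identified
  species + unidentified share), perturbed in log-ratio space so noise can
  never produce negative masses or introduce acids absent from the
  template;
* assay readings (vial weights, extract absorbances, elemental nitrogen)
  obtained by exactly inverting the assay formulas at a configured true
  composition, so zero-noise readings round-trip to the truth to machine
  precision.

Every generator is a pure function of (config, salinity, replicate seed):
one master seed spawns independent per-replicate streams, so changing the
replicate count never shifts the other replicates' draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

from .assays import NITROGEN_TO_PROTEIN_FACTOR, LipidAssay, PigmentAssay
from .exceptions import ConfigurationError, ValidationError
from .fame import FameProfile, profile_from_mass_percents
from .growth import GrowthCurve

__all__ = [
    "CompositionTruth",
    "SyntheticStudyConfig",
    "condition_label",
    "simulate_growth_curve",
    "simulate_fame_profile",
    "simulate_assay_readings",
    "simulate_study",
]

# Fixed apparatus constants of the synthetic assays (typical bench values).
_LIPID_BIOMASS_G = 0.05     # dry biomass per lipid extraction
_LIPID_VIAL_G = 10.0        # empty-vial tare weight
_PIGMENT_VOLUME_ML = 100.0  # final acetone extract volume
_PIGMENT_MASS_G = 0.02      # biomass per pigment extraction
_A645_OVER_A663 = 0.35      # red-peak shape of a chl-a acetone extract
_A510_OVER_A480 = 0.20      # carotenoid band shape

# Stream tags keeping the three generators' draws independent.
_STREAM_GROWTH, _STREAM_FAME, _STREAM_ASSAY = 1, 2, 3


def condition_label(salinity: float) -> str:
    """Canonical condition label for a salinity, e.g. ``1.0 M NaCl``."""
    return f"{salinity:.1f} M NaCl"


@dataclass(frozen=True)
class CompositionTruth:
    """True biochemical composition of one condition (% DCW and mg/g)."""

    protein_percent: float
    lipid_percent: float
    carbohydrate_percent: float
    chl_a_mg_g: float
    car_mg_g: float

    def __post_init__(self) -> None:
        for name in ("protein_percent", "lipid_percent", "carbohydrate_percent"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ConfigurationError(f"{name} must lie in [0, 100] %, got {v}")
        if self.chl_a_mg_g < 0 or self.car_mg_g < 0:
            raise ConfigurationError("pigment contents must be >= 0")


def _default_mu() -> dict[float, float]:
    # 1.0 M optimum 0.39/d and 4.0 M minimum 0.11/d are the study
    # conditions; intermediate salinities interpolate the reported
    # monotone decline away from the optimum.
    return {0.5: 0.35, 1.0: 0.39, 2.0: 0.30, 3.0: 0.22, 4.0: 0.11}


def _default_capacity() -> dict[float, float]:
    # Plateau densities consistent with the day-30 counts (4.6e7 at 0.5 M
    # down to 1.6e7 at 4.0 M, 5.7e7 at the optimum).
    return {0.5: 5.2e7, 1.0: 6.0e7, 2.0: 5.0e7, 3.0: 4.4e7, 4.0: 2.2e7}


def _default_truth() -> dict[float, CompositionTruth]:
    return {
        0.5: CompositionTruth(21.45, 15.71, 53.14, 7.36, 2.75),
        1.0: CompositionTruth(30.35, 17.81, 42.02, 9.45, 3.21),
        2.0: CompositionTruth(26.26, 16.96, 27.87, 8.71, 2.11),
        3.0: CompositionTruth(24.50, 16.17, 25.68, 8.51, 1.82),
        4.0: CompositionTruth(18.48, 12.67, 18.67, 5.88, 1.54),
    }


def _default_templates() -> dict[float, FameProfile]:
    # Imported lazily to avoid a cycle (io uses fame/growth types).
    from .io import load_reference_profiles

    by_label = load_reference_profiles()
    out = {}
    for salinity in (0.5, 1.0, 2.0, 3.0, 4.0):
        out[salinity] = by_label[condition_label(salinity)]
    return out


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """The study conditions the generators emulate.

    Defaults mirror the salinity-gradient design: five NaCl molarities in
    triplicate 2 L batch flasks, ~1e6 cells/mL inoculum, a 3-day lag,
    condition-specific exponential rates (0.39/d at the 1.0 M optimum down
    to 0.11/d at 4.0 M) and logistic saturation near the observed plateau
    densities.  ``noise_cv`` is the multiplicative coefficient of variation
    applied to counts, compositions (as log-ratio sd) and assay readings.
    """

    salinities: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0)
    mu_by_salinity: Mapping[float, float] = field(default_factory=_default_mu)
    n0: float = 1.0e6
    lag_days: float = 3.0
    carrying_capacity: Mapping[float, float] = field(default_factory=_default_capacity)
    noise_cv: float = 0.05
    replicates: int = 3
    fame_template: Mapping[float, FameProfile] | None = None
    composition_truth: Mapping[float, CompositionTruth] = field(
        default_factory=_default_truth
    )
    duration_days: float = 35.0
    sampling_interval_days: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(mu < 0 for mu in self.mu_by_salinity.values()):
            raise ConfigurationError("growth rates must be >= 0")
        if not 0.0 <= self.noise_cv <= 0.5:
            raise ConfigurationError(
                f"noise_cv must lie in [0, 0.5], got {self.noise_cv}"
            )
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if self.n0 <= 0 or self.lag_days < 0:
            raise ConfigurationError("n0 must be > 0 and lag_days >= 0")

    def templates(self) -> Mapping[float, FameProfile]:
        return self.fame_template if self.fame_template is not None else _default_templates()

    @classmethod
    def from_yaml(cls, path) -> "SyntheticStudyConfig":
        """Load overrides for the scalar fields from a YAML mapping."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {
            "salinities", "mu_by_salinity", "n0", "lag_days",
            "carrying_capacity", "noise_cv", "replicates",
            "duration_days", "sampling_interval_days", "seed",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "salinities" in raw:
            raw["salinities"] = tuple(float(s) for s in raw["salinities"])
        for key in ("mu_by_salinity", "carrying_capacity"):
            if key in raw:
                raw[key] = {float(k): float(v) for k, v in raw[key].items()}
        return cls(**raw)


def _rng(config: SyntheticStudyConfig, stream: int, salinity: float, replicate_seed: int):
    seq = np.random.SeedSequence(
        entropy=int(config.seed),
        spawn_key=(stream, int(round(salinity * 1000)), int(replicate_seed)),
    )
    return np.random.default_rng(seq)


def _mean_one_lognormal(rng, cv: float, size=None):
    """Multiplicative noise factors with mean exactly 1 and CV ``cv``."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _require_salinity(config: SyntheticStudyConfig, salinity: float, mapping, what: str):
    if salinity not in mapping:
        raise ConfigurationError(
            f"salinity {salinity} has no {what}; configured: {sorted(mapping)}"
        )


def simulate_growth_curve(
    config: SyntheticStudyConfig, salinity: float, replicate_seed: int
) -> GrowthCurve:
    """One replicate growth curve: lag, then logistic growth, then noise.

    N(t) holds at the inoculum density through the lag, then follows
    ``K / (1 + (K/N0 - 1) exp(-mu (t - lag)))``; an absent or infinite
    carrying capacity degenerates to pure exponential growth.  Counts carry
    mean-one lognormal noise with CV ``noise_cv``.
    """
    _require_salinity(config, salinity, config.mu_by_salinity, "growth rate")
    mu = config.mu_by_salinity[salinity]
    capacity = dict(config.carrying_capacity).get(salinity, math.inf)
    times = np.arange(
        0.0, config.duration_days + 1e-9, config.sampling_interval_days
    )
    elapsed = np.clip(times - config.lag_days, 0.0, None)
    if math.isfinite(capacity):
        n = capacity / (1.0 + (capacity / config.n0 - 1.0) * np.exp(-mu * elapsed))
    else:
        n = config.n0 * np.exp(mu * elapsed)
    rng = _rng(config, _STREAM_GROWTH, salinity, replicate_seed)
    n = n * _mean_one_lognormal(rng, config.noise_cv, size=len(times))
    return GrowthCurve(
        condition_label=condition_label(salinity),
        replicate_id=str(replicate_seed),
        observations=tuple(zip(times, n)),
    )


def simulate_fame_profile(
    config: SyntheticStudyConfig, salinity: float, replicate_seed: int
) -> FameProfile:
    """One replicate FAME profile from the condition's template.

    Each non-zero component (identified species and the unidentified
    share) is perturbed in log space with sd ``noise_cv`` and the whole
    composition renormalised to 100 %, so closure is exact, masses stay
    positive, and acids absent from the template stay absent.
    """
    templates = config.templates()
    _require_salinity(config, salinity, templates, "FAME template")
    template = templates[salinity]
    rng = _rng(config, _STREAM_FAME, salinity, replicate_seed)

    notations = [fa.notation for fa in template.species]
    masses = np.array([fa.mass_percent for fa in template.species], dtype=float)
    parts = np.append(masses, template.others_percent)
    if config.noise_cv > 0:
        positive = parts > 0
        parts = parts.copy()
        parts[positive] = np.exp(
            np.log(parts[positive])
            + rng.normal(0.0, config.noise_cv, size=int(positive.sum()))
        )
    parts = parts / parts.sum() * 100.0
    return profile_from_mass_percents(
        condition_label(salinity),
        dict(zip(notations, parts[:-1])),
        others_percent=float(parts[-1]),
        sum_tolerance=1e-6,
    )


def simulate_assay_readings(
    config: SyntheticStudyConfig, salinity: float, replicate_seed: int
) -> tuple[LipidAssay, PigmentAssay, float]:
    """One replicate's raw assay readings, inverted from the configured truth.

    Returns ``(lipid assay, pigment assay, elemental N %)``.  The inversion
    fixes the bench constants (50 mg lipid input, 10 g vial tare, 100 mL
    extract from 20 mg biomass, red/blue band shape ratios) and solves each
    assay formula for its reading; with ``noise_cv`` = 0 the corresponding
    assay operation recovers the truth to machine precision.
    """
    truth_map = dict(config.composition_truth)
    _require_salinity(config, salinity, truth_map, "composition truth")
    truth = truth_map[salinity]
    rng = _rng(config, _STREAM_ASSAY, salinity, replicate_seed)
    noise = lambda: float(_mean_one_lognormal(rng, config.noise_cv))

    lipid_delta = truth.lipid_percent / 100.0 * _LIPID_BIOMASS_G * noise()
    lipid = LipidAssay(
        w1=_LIPID_VIAL_G, w2=_LIPID_VIAL_G + lipid_delta, m=_LIPID_BIOMASS_G
    )

    scale = 1000.0 * _PIGMENT_MASS_G / _PIGMENT_VOLUME_ML
    a663 = truth.chl_a_mg_g * scale / (12.7 - 2.69 * _A645_OVER_A663)
    a480 = truth.car_mg_g * scale / (7.6 - 1.49 * _A510_OVER_A480)
    pigments = PigmentAssay(
        a663=a663 * noise(),
        a645=_A645_OVER_A663 * a663 * noise(),
        a510=_A510_OVER_A480 * a480 * noise(),
        a480=a480 * noise(),
        volume_ml=_PIGMENT_VOLUME_ML,
        mass_g=_PIGMENT_MASS_G,
    )

    n_percent = truth.protein_percent / NITROGEN_TO_PROTEIN_FACTOR * noise()
    return lipid, pigments, float(np.clip(n_percent, 0.0, 100.0))


def simulate_study(config: SyntheticStudyConfig) -> dict:
    """All replicates of all conditions: the full synthetic study.

    Returns ``{"growth": [GrowthCurve], "fame": {label: FameProfile},
    "assays": [(label, replicate, LipidAssay, PigmentAssay, n_percent)]}``.
    FAME profiles are per condition (replicate 1), matching a pooled-lipid
    GC-FID run; growth and assays are per replicate.
    """
    growth = [
        simulate_growth_curve(config, s, r)
        for s in config.salinities
        for r in range(1, config.replicates + 1)
    ]
    fame = {
        condition_label(s): simulate_fame_profile(config, s, 1)
        for s in config.salinities
    }
    assays = []
    for s in config.salinities:
        for r in range(1, config.replicates + 1):
            lipid, pigments, n_percent = simulate_assay_readings(config, s, r)
            assays.append((condition_label(s), str(r), lipid, pigments, n_percent))
    return {"growth": growth, "fame": fame, "assays": assays}
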