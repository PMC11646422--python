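"""Fatty-acid shorthand parsing, FAME profiles and unsaturation summaries.

A GC-FID fatty-acid-methyl-ester (FAME) analysis reports each identified
fatty acid as a mass percentage of the total fatty acid mixture, labelled
with the ``C<carbons>:<double bonds>[n-<omega series>]`` shorthand (e.g.
``C18:3n-3`` for alpha-linolenic acid).  This module parses that shorthand,
represents a condition-labelled profile, and condenses it into the class
totals (SFA/MUFA/PUFA) and unsaturation statistics that drive the empirical
biodiesel property correlations in :mod:`algafuel.fuel`.

The key summary quantity is the average degree of unsaturation

    ADU = sum(N_i * Mf_i)

where ``N_i`` is the number of C=C double bonds of identified species *i*
and ``Mf_i`` its mass fraction (mass % / 100).  Unidentified peaks (the
"others" share of the chromatogram) carry no structural information and are
excluded from ADU and from every downstream formula term; they participate
only in the closure check that a profile sums to 100 %.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, replace
from typing import Mapping

from .exceptions import NotationParseError, ValidationError

__all__ = [
    "LipidClass",
    "FattyAcid",
    "FameProfile",
    "ProfileSummary",
    "parse_fatty_acid",
    "classify",
    "summarize",
    "mass_percent_of",
    "COMMON_NAMES",
]

#: Reserved notation for the unidentified ("Others") share in file formats.
OTHERS_NOTATION = "OTHERS"

#: Common names for the fatty acids a Dunaliella-type FAME run identifies,
#: plus the long-chain saturates entering the CFPP correlation.
COMMON_NAMES: Mapping[str, str] = {
    "C12:0": "lauric acid",
    "C14:0": "myristic acid",
    "C16:0": "palmitic acid",
    "C16:1": "palmitoleic acid",
    "C18:0": "stearic acid",
    "C18:1": "oleic acid",
    "C18:2": "linoleic acid",
    "C18:3n-6": "gamma-linolenic acid",
    "C18:3n-3": "alpha-linolenic acid",
    "C20:0": "arachidic acid",
    "C20:5n-3": "eicosapentaenoic acid",
    "C22:0": "behenic acid",
    "C22:6n-3": "docosahexaenoic acid",
    "C24:0": "lignoceric acid",
}

_NOTATION_RE = re.compile(
    r"^\s*C\s*(?P<carbons>\d+)\s*:\s*(?P<db>\d+)\s*"
    r"(?:n\s*-\s*(?P<omega>\d+)\s*)?$",
    re.IGNORECASE,
)


class LipidClass(str, enum.Enum):
    """Saturation class of a fatty acid."""

    SFA = "SFA"   # saturated, 0 double bonds
    MUFA = "MUFA" # monounsaturated, 1 double bond
    PUFA = "PUFA" # polyunsaturated, >= 2 double bonds


def _canonical_notation(carbons: int, double_bonds: int, omega: int | None) -> str:
    base = f"C{carbons}:{double_bonds}"
    return f"{base}n-{omega}" if omega is not None else base


@dataclass(frozen=True)
class FattyAcid:
    """One identified FAME species.

    ``mass_percent`` is the species' share of total fatty acids (Table-style
    mass %); ``mass_fraction`` is the same number divided by 100 and is the
    ``Mf`` entering the ADU sum.  ``mass_percent`` may be ``None`` for a
    species parsed from shorthand alone.
    """

    carbons: int
    double_bonds: int
    omega_series: int | None = None
    mass_percent: float | None = None
    common_name: str | None = None

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValidationError(f"carbons must be >= 2, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValidationError("double_bonds must be >= 0")
        if self.double_bonds > self.carbons / 2:
            raise ValidationError(
                f"{_canonical_notation(self.carbons, self.double_bonds, self.omega_series)}: "
                f"{self.double_bonds} double bonds impossible on a {self.carbons}-carbon chain"
            )
        if self.mass_percent is not None and not 0.0 <= self.mass_percent <= 100.0:
            raise ValidationError(
                f"mass_percent must lie in [0, 100], got {self.mass_percent}"
            )
        if self.common_name is None:
            object.__setattr__(
                self, "common_name", COMMON_NAMES.get(self.notation)
            )

    @property
    def notation(self) -> str:
        """Canonical shorthand, e.g. ``C18:3n-3``."""
        return _canonical_notation(self.carbons, self.double_bonds, self.omega_series)

    @property
    def mass_fraction(self) -> float | None:
        """Mass fraction of 1 (mass % / 100); the Mf of the ADU sum."""
        if self.mass_percent is None:
            return None
        return self.mass_percent / 100.0

    def with_mass_percent(self, mass_percent: float) -> "FattyAcid":
        return replace(self, mass_percent=mass_percent)


def parse_fatty_acid(notation: str) -> FattyAcid:
    """Parse ``C<carbons>:<double_bonds>[n-<series>]`` shorthand.

    Case-insensitive; interior whitespace tolerated.  The returned species
    has no mass percentage attached.

    >>> parse_fatty_acid("C18:3n-6").double_bonds
    3
    """
    if not isinstance(notation, str):
        raise NotationParseError(f"expected a shorthand string, got {notation!r}")
    m = _NOTATION_RE.match(notation)
    if m is None:
        raise NotationParseError(
            f"cannot parse fatty-acid shorthand {notation!r}; "
            "expected the form C<carbons>:<double_bonds>[n-<series>]"
        )
    carbons = int(m.group("carbons"))
    double_bonds = int(m.group("db"))
    omega = m.group("omega")
    return FattyAcid(
        carbons=carbons,
        double_bonds=double_bonds,
        omega_series=int(omega) if omega is not None else None,
    )


def classify(fa: FattyAcid) -> LipidClass:
    """Saturation class from the double-bond count (0 / 1 / >=2)."""
    if fa.double_bonds == 0:
        return LipidClass.SFA
    if fa.double_bonds == 1:
        return LipidClass.MUFA
    return LipidClass.PUFA


@dataclass(frozen=True)
class FameProfile:
    """A condition-labelled FAME profile.

    ``others_percent`` is the unidentified share of the chromatogram.  The
    identified species plus that share must close to 100 % within
    ``sum_tolerance`` (percentage points).  Duplicate notations are rejected
    rather than merged: two rows with the same shorthand in lab data are more
    likely a transcription error than a genuine split peak.
    """

    condition_label: str
    species: tuple[FattyAcid, ...]
    others_percent: float = 0.0
    sum_tolerance: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        seen: set[str] = set()
        for fa in self.species:
            if fa.mass_percent is None:
                raise ValidationError(
                    f"species {fa.notation} in profile {self.condition_label!r} "
                    "has no mass_percent"
                )
            if fa.notation in seen:
                raise ValidationError(
                    f"duplicate notation {fa.notation} in profile "
                    f"{self.condition_label!r}"
                )
            seen.add(fa.notation)
        if self.others_percent < 0:
            raise ValidationError("others_percent must be >= 0")
        total = self.total_percent
        if abs(total - 100.0) > self.sum_tolerance:
            raise ValidationError(
                f"profile {self.condition_label!r} sums to {total:.4f} %, "
                f"outside 100 +/- {self.sum_tolerance}"
            )

    @property
    def total_percent(self) -> float:
        return sum(fa.mass_percent for fa in self.species) + self.others_percent

    def mass_percent_of(self, notation: str) -> float:
        """Stored mass % for a shorthand; 0.0 when the acid is absent."""
        return mass_percent_of(self, notation)

    def mass_percent_by_structure(self, carbons: int, double_bonds: int) -> float:
        """Total mass % over all omega variants of one chain/unsaturation.

        The fuel-property correlations address acids by structure (e.g. the
        C18:3 term of the flash-point formula covers both linolenic isomers).
        """
        return sum(
            fa.mass_percent
            for fa in self.species
            if fa.carbons == carbons and fa.double_bonds == double_bonds
        )


def mass_percent_of(profile: FameProfile, notation: str) -> float:
    """Mass % of one acid in a profile, 0.0 when absent (a "-" table cell)."""
    canonical = parse_fatty_acid(notation).notation
    for fa in profile.species:
        if fa.notation == canonical:
            return fa.mass_percent
    return 0.0


@dataclass(frozen=True)
class ProfileSummary:
    """Class totals and unsaturation statistics of one FAME profile.

    All percentages are mass % of total fatty acids.  ``adu`` is
    dimensionless; ``x_linoleic_plus_linolenic`` is the X of the oxidative
    stability correlation; ``lcsf`` the long-chain saturated factor feeding
    the cold-filter-plugging-point correlation.
    """

    condition_label: str
    sfa_percent: float
    mufa_percent: float
    pufa_percent: float
    adu: float
    linolenic_percent: float
    x_linoleic_plus_linolenic: float
    pufa_ge4db_percent: float
    lcsf: float


def summarize(profile: FameProfile) -> ProfileSummary:
    """Condense a profile into class totals, ADU, X, LCSF and related terms.

    Only identified species contribute; the unidentified "others" share is
    excluded from every term.  "Linolenic" is the structural total of both
    C18:3 isomers (n-3 + n-6); X adds linoleic (C18:2).  The LCSF weights the
    long-chain saturates 0.1/0.5/1/1.5/2 for C16:0/C18:0/C20:0/C22:0/C24:0,
    absent acids contributing zero.
    """
    totals = {cls: 0.0 for cls in LipidClass}
    adu = 0.0
    pufa_ge4db = 0.0
    for fa in profile.species:
        totals[classify(fa)] += fa.mass_percent
        adu += fa.double_bonds * fa.mass_fraction
        if fa.double_bonds >= 4:
            pufa_ge4db += fa.mass_percent

    linolenic = profile.mass_percent_by_structure(18, 3)
    linoleic = profile.mass_percent_by_structure(18, 2)
    lcsf = (
        0.1 * profile.mass_percent_by_structure(16, 0)
        + 0.5 * profile.mass_percent_by_structure(18, 0)
        + 1.0 * profile.mass_percent_by_structure(20, 0)
        + 1.5 * profile.mass_percent_by_structure(22, 0)
        + 2.0 * profile.mass_percent_by_structure(24, 0)
    )
    return ProfileSummary(
        condition_label=profile.condition_label,
        sfa_percent=totals[LipidClass.SFA],
        mufa_percent=totals[LipidClass.MUFA],
        pufa_percent=totals[LipidClass.PUFA],
        adu=adu,
        linolenic_percent=linolenic,
        x_linoleic_plus_linolenic=linoleic + linolenic,
        pufa_ge4db_percent=pufa_ge4db,
        lcsf=lcsf,
    )


def profile_from_mass_percents(
    condition_label: str,
    mass_percents: Mapping[str, float],
    others_percent: float = 0.0,
    sum_tolerance: float = 0.5,
) -> FameProfile:
    """Build a profile from a ``{notation: mass %}`` mapping.

    Entries with zero mass are dropped (a zero row and an absent row are
    equivalent for every downstream computation).
    """
    species = tuple(
        parse_fatty_acid(notation).with_mass_percent(mp)
        for notation, mp in mass_percents.items()
        if mp != 0.0
    )
    return FameProfile(
        condition_label=condition_label,
        species=species,
        others_percent=others_percent,
        sum_tolerance=sum_tolerance,
    )
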