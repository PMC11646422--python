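"""Biochemical assay arithmetic: gravimetric lipids, spectrophotometric
pigments, protein-from-nitrogen, cell geometry and unit conversions.

All formulas are simple closed forms; the value of keeping them here is a
single validated, unit-annotated implementation shared by the analysis
pipeline and the synthetic-data inverter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .exceptions import DomainError, ValidationError

__all__ = [
    "LipidAssay",
    "PigmentAssay",
    "CellDimensions",
    "lipid_content",
    "chlorophyll_a",
    "total_carotenoids",
    "car_chl_ratio",
    "protein_from_nitrogen",
    "cell_volume",
    "salinity_g_per_l_to_molar",
    "NITROGEN_TO_PROTEIN_FACTOR",
    "NACL_MOLAR_MASS",
]

#: Nitrogen-to-protein conversion factor for microalgal biomass.
NITROGEN_TO_PROTEIN_FACTOR = 4.78

#: Molar mass of NaCl, g/mol.
NACL_MOLAR_MASS = 58.44


@dataclass(frozen=True)
class LipidAssay:
    """Gravimetric lipid assay: vial weights and dry biomass input.

    ``w1`` empty-vial weight (g), ``w2`` vial + dried lipid extract (g),
    ``m`` dry algal biomass extracted (g).
    """

    w1: float
    w2: float
    m: float

    def __post_init__(self) -> None:
        if self.w1 <= 0 or self.w2 <= 0:
            raise ValidationError("vial weights must be positive")
        if self.m <= 0:
            raise DomainError("dry biomass weight must be positive")
        if self.w2 < self.w1:
            raise DomainError(
                f"vial+lipid weight ({self.w2} g) below empty-vial weight "
                f"({self.w1} g): negative lipid mass"
            )


@dataclass(frozen=True)
class PigmentAssay:
    """Acetone-extract absorbances and extraction bookkeeping.

    Absorbances at 663/645 nm quantify chlorophyll a, 480/510 nm the total
    carotenoids; ``volume_ml`` is the final extract volume and ``mass_g``
    the algal biomass extracted.
    """

    a663: float
    a645: float
    a510: float
    a480: float
    volume_ml: float
    mass_g: float

    def __post_init__(self) -> None:
        for name in ("a663", "a645", "a510", "a480"):
            if getattr(self, name) < 0:
                raise ValidationError(f"absorbance {name} must be >= 0")
        if self.volume_ml <= 0 or self.mass_g <= 0:
            raise ValidationError("extract volume and biomass must be positive")


@dataclass(frozen=True)
class CellDimensions:
    """Mean cell length and width in micrometres (length >= width)."""

    length_um: float
    width_um: float

    def __post_init__(self) -> None:
        if self.width_um <= 0:
            raise ValidationError("cell width must be positive")
        if self.length_um < self.width_um:
            raise ValidationError("cell length must be >= width")


def lipid_content(assay: LipidAssay) -> float:
    """Total lipid content, % of dry cell weight: (W2 - W1)/M * 100."""
    return (assay.w2 - assay.w1) / assay.m * 100.0


def chlorophyll_a(assay: PigmentAssay) -> float:
    """Chlorophyll a content, mg per g dry biomass.

    (12.7 A663 - 2.69 A645) * V / (1000 * m), the Arnon-style form with the
    absorbance difference fully parenthesised before volume/mass scaling.
    """
    return (12.7 * assay.a663 - 2.69 * assay.a645) * assay.volume_ml / (
        1000.0 * assay.mass_g
    )


def total_carotenoids(assay: PigmentAssay) -> float:
    """Total carotenoid content, mg per g dry biomass.

    (7.6 A480 - 1.49 A510) * V / (1000 * m), parenthesised as for
    chlorophyll a.
    """
    return (7.6 * assay.a480 - 1.49 * assay.a510) * assay.volume_ml / (
        1000.0 * assay.mass_g
    )


def car_chl_ratio(car: float, chl: float) -> float:
    """Carotenoid-to-chlorophyll-a ratio, a carotenogenesis indicator."""
    if chl <= 0:
        raise DomainError(f"ratio undefined for chlorophyll a <= 0 (got {chl})")
    return car / chl


def protein_from_nitrogen(
    n_percent: float, factor: float = NITROGEN_TO_PROTEIN_FACTOR
) -> float:
    """Crude protein (% DCW) from elemental nitrogen (% DCW).

    Warns when the product exceeds 100 % — an impossible composition that
    indicates a bad nitrogen reading or factor.
    """
    if not 0.0 <= n_percent <= 100.0:
        raise DomainError(f"nitrogen content must lie in [0, 100] %, got {n_percent}")
    protein = n_percent * factor
    if protein > 100.0:
        warnings.warn(
            f"protein estimate {protein:.2f} % DCW exceeds 100 %: "
            "impossible composition",
            stacklevel=2,
        )
    return protein


def cell_volume(dims: CellDimensions) -> float:
    """Cell volume in um^3, modelling the cell as a prolate spheroid.

    V = (pi/6) * L * W^2 — an assumption, chosen because Dunaliella cells
    are wall-less ellipsoids/ovoids; reduces to the sphere for L = W.
    """
    return math.pi / 6.0 * dims.length_um * dims.width_um**2


def salinity_g_per_l_to_molar(
    g_per_l: float, molar_mass: float = NACL_MOLAR_MASS
) -> float:
    """Convert a gravimetric salinity (g/L) to molarity (mol/L)."""
    if g_per_l < 0:
        raise DomainError("salinity must be >= 0")
    return g_per_l / molar_mass
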