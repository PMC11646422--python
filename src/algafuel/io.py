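"""File formats, packaged reference tables, rounding and run manifests.

CSV dialects are deliberately plain: comma-separated, UTF-8, one header
row.  In FAME tables an empty cell or any dash variant ("-", the figure
dash, en/em dashes) marks an absent acid; the reserved notation ``OTHERS``
carries the unidentified share of the chromatogram.
"""

from __future__ import annotations

import datetime as _dt
import decimal
import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .exceptions import ValidationError
from .fame import OTHERS_NOTATION, FameProfile, profile_from_mass_percents
from .growth import GrowthCurve

__all__ = [
    "read_fame_profiles",
    "write_fame_profiles",
    "read_growth_curves",
    "write_growth_curves",
    "read_pigment_assays",
    "read_lipid_assays",
    "load_reference_profiles",
    "load_reference_fuel_table",
    "load_reference_class_totals",
    "load_reference_pigments",
    "load_reference_composition",
    "load_reference_cell_dimensions",
    "load_anomaly_whitelist",
    "round_for_report",
    "write_manifest",
]

_ABSENT_CELLS = {"", "-", "‒", "–", "—", "nd", "ND", "n.d."}


def _data_file(name: str):
    return resources.files("algafuel.data").joinpath(name)


# ---------------------------------------------------------------------------
# FAME profiles (long format: condition,notation,mass_percent)
# ---------------------------------------------------------------------------


def read_fame_profiles(source, sum_tolerance: float = 0.5) -> dict[str, FameProfile]:
    """Read long-format FAME CSV into per-condition profiles.

    Expected columns ``condition,notation,mass_percent``; rows whose value
    cell is empty or a dash are treated as absent acids and skipped; the
    reserved notation ``OTHERS`` feeds the profile's unidentified share.
    Conditions keep file order.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False, comment="#")
    required = {"condition", "notation", "mass_percent"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"FAME CSV missing columns: {sorted(missing)}")
    if df.empty:
        raise ValidationError("FAME CSV contains no data rows")

    profiles: dict[str, FameProfile] = {}
    for condition, group in df.groupby("condition", sort=False):
        masses: dict[str, float] = {}
        others = 0.0
        for _, row in group.iterrows():
            cell = row["mass_percent"].strip()
            if cell in _ABSENT_CELLS:
                continue
            value = float(cell)
            notation = row["notation"].strip()
            if notation.upper() == OTHERS_NOTATION:
                others += value
            else:
                if notation in masses:
                    raise ValidationError(
                        f"duplicate notation {notation} for condition {condition!r}"
                    )
                masses[notation] = value
        profiles[condition] = profile_from_mass_percents(
            condition, masses, others_percent=others, sum_tolerance=sum_tolerance
        )
    return profiles


def write_fame_profiles(profiles: Mapping[str, FameProfile], path) -> None:
    rows = []
    for condition, profile in profiles.items():
        for fa in profile.species:
            rows.append((condition, fa.notation, repr(fa.mass_percent)))
        rows.append((condition, OTHERS_NOTATION, repr(profile.others_percent)))
    pd.DataFrame(rows, columns=["condition", "notation", "mass_percent"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Growth curves (condition,replicate,day,cells_per_ml)
# ---------------------------------------------------------------------------


def read_growth_curves(source) -> list[GrowthCurve]:
    """Read a cell-count CSV into one curve per (condition, replicate)."""
    df = pd.read_csv(source, comment="#", float_precision="round_trip")
    required = {"condition", "replicate", "day", "cells_per_ml"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"growth CSV missing columns: {sorted(missing)}")
    if df.empty:
        raise ValidationError("growth CSV contains no data rows")
    curves = []
    for (condition, replicate), group in df.groupby(
        ["condition", "replicate"], sort=False
    ):
        group = group.sort_values("day")
        curves.append(
            GrowthCurve(
                condition_label=str(condition),
                replicate_id=str(replicate),
                observations=tuple(
                    zip(group["day"].astype(float), group["cells_per_ml"].astype(float))
                ),
            )
        )
    return curves


def write_growth_curves(curves, path) -> None:
    rows = [
        (c.condition_label, c.replicate_id, t, repr(n))
        for c in curves
        for t, n in c.observations
    ]
    pd.DataFrame(
        rows, columns=["condition", "replicate", "day", "cells_per_ml"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Assay tables
# ---------------------------------------------------------------------------


def read_pigment_assays(source) -> "pd.DataFrame":
    """Pigment CSV: ``sample,a663,a645,a510,a480,volume_ml,mass_g``."""
    df = pd.read_csv(source, comment="#", float_precision="round_trip")
    required = {"sample", "a663", "a645", "a510", "a480", "volume_ml", "mass_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"pigment CSV missing columns: {sorted(missing)}")
    return df


def read_lipid_assays(source) -> "pd.DataFrame":
    """Lipid CSV: ``sample,w1,w2,m`` (grams)."""
    df = pd.read_csv(source, comment="#", float_precision="round_trip")
    missing = {"sample", "w1", "w2", "m"} - set(df.columns)
    if missing:
        raise ValidationError(f"lipid CSV missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------


def load_reference_profiles() -> dict[str, FameProfile]:
    """The packaged per-salinity FAME reference profiles."""
    with _data_file("table4_fame_profiles.csv").open() as fh:
        return read_fame_profiles(fh)


def load_reference_fuel_table() -> dict[tuple[str, str], str]:
    """Published fuel-property values as printed strings keyed by
    (property, condition); string form preserves each cell's precision."""
    with _data_file("table5_fuel_properties.csv").open() as fh:
        df = pd.read_csv(fh, dtype=str, keep_default_na=False)
    return {
        (row["property"], row["condition"]): row["printed"]
        for _, row in df.iterrows()
    }


def load_reference_class_totals() -> "pd.DataFrame":
    with _data_file("table4_class_totals.csv").open() as fh:
        return pd.read_csv(fh)


def load_reference_pigments() -> "pd.DataFrame":
    with _data_file("table2_pigments.csv").open() as fh:
        return pd.read_csv(fh)


def load_reference_composition() -> "pd.DataFrame":
    with _data_file("table3_composition.csv").open() as fh:
        return pd.read_csv(fh)


def load_reference_cell_dimensions() -> "pd.DataFrame":
    with _data_file("table1_cell_dimensions.csv").open() as fh:
        return pd.read_csv(fh)


def load_anomaly_whitelist() -> set[tuple[str, str]]:
    """(property, condition) cells excluded from exact reproduction."""
    with _data_file("reproduce_anomalies.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    return {(row["property"], row["condition"]) for _, row in df.iterrows()}


# ---------------------------------------------------------------------------
# Rounding and manifests
# ---------------------------------------------------------------------------


def round_for_report(value: float, decimals: int) -> str:
    """Half-up decimal string for reports; internal math is never rounded.

    Half-up (2.675 -> "2.68"), ties away from zero, unlike float banker's
    rounding.
    """
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    quantum = decimal.Decimal(1).scaleb(-decimals)
    d = decimal.Decimal(repr(float(value))).quantize(
        quantum, rounding=decimal.ROUND_HALF_UP
    )
    return format(d, "f")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir,
    command: str,
    inputs=(),
    seed: int | None = None,
    config_path=None,
    extra: Mapping | None = None,
) -> Path:
    """Write the run manifest JSON every CLI invocation emits."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": str(config_path) if config_path else None,
        "inputs": [
            {"path": str(p), "sha256": _sha256(p)} for p in inputs if Path(p).exists()
        ],
        "seed": seed,
        "package_version": __version__,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
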