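"""Trait-table ingestion and validation.

The expected layout is one row per species with columns ``species``,
``leaf_length_cm``, ``d_pet_um``, ``d_twig_um``, ``wood_density_g_cm3``,
``height_m``, ``leaf_type`` and ``site``.  Common aliases (case
insensitive, e.g. ``Species``, ``LeafLength``, ``WD``, ``H``) are
accepted and logged.  Rows with non-positive continuous traits are
flagged, excluded and logged rather than silently propagated into the
log10 transforms downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .allometry import TRAIT_COLUMNS

logger = logging.getLogger(__name__)

__all__ = ["SchemaError", "ValidationReport", "read_trait_table", "write_trait_table"]

REQUIRED = ("species",) + TRAIT_COLUMNS
OPTIONAL = ("leaf_type", "site")

_ALIASES = {
    "species": {"species", "taxon", "sp", "species_name"},
    "leaf_length_cm": {"leaf_length_cm", "leaf_length", "leaflength", "l", "l_cm"},
    "d_pet_um": {"d_pet_um", "d_pet", "dpet", "petiole_vessel_diameter", "d_petiole_um"},
    "d_twig_um": {"d_twig_um", "d_twig", "dtwig", "twig_vessel_diameter"},
    "wood_density_g_cm3": {"wood_density_g_cm3", "wood_density", "wd", "wd_g_cm3"},
    "height_m": {"height_m", "height", "h", "plant_height_m"},
    "leaf_type": {"leaf_type", "leaftype", "type"},
    "site": {"site", "locality", "location"},
}


class SchemaError(ValueError):
    """The CSV is missing required columns."""


@dataclass
class ValidationReport:
    """Row-level issues found while reading a trait table."""

    n_read: int = 0
    n_kept: int = 0
    renamed: dict = field(default_factory=dict)
    dropped: list = field(default_factory=list)  # (species, reason)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"read {self.n_read} rows, kept {self.n_kept}"]
        for sp, reason in self.dropped:
            lines.append(f"  dropped {sp}: {reason}")
        return "\n".join(lines)


def _canonicalize(columns) -> dict:
    mapping = {}
    for col in columns:
        key = str(col).strip().lower().replace(" ", "_").replace("(", "").replace(")", "")
        for canonical, aliases in _ALIASES.items():
            if key in aliases:
                mapping[col] = canonical
                break
    return mapping


def read_trait_table(path, return_report: bool = False):
    """Read and validate a species trait table from CSV.

    Returns the validated DataFrame, or ``(df, ValidationReport)`` when
    ``return_report`` is true.  Raises :class:`SchemaError` if required
    columns (after alias resolution) are absent.
    """
    raw = pd.read_csv(path)
    mapping = _canonicalize(raw.columns)
    renamed = {k: v for k, v in mapping.items() if k != v}
    if renamed:
        logger.info("renamed columns: %s", renamed)
    df = raw.rename(columns=mapping)
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing required columns {missing}; expected {list(REQUIRED)} "
            f"(optional: {list(OPTIONAL)}); found {list(raw.columns)}"
        )
    report = ValidationReport(n_read=len(df), renamed=renamed)

    keep = pd.Series(True, index=df.index)
    for col in TRAIT_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    dup = df["species"].duplicated(keep=False)
    for idx in df.index[dup & df["species"].duplicated()]:
        keep[idx] = False
        report.dropped.append((df.loc[idx, "species"], "duplicate species"))
    for idx, row in df.iterrows():
        if not keep[idx]:
            continue
        bad = [c for c in TRAIT_COLUMNS if pd.notna(row[c]) and row[c] <= 0]
        if bad:
            keep[idx] = False
            report.dropped.append((row["species"], f"non-positive {', '.join(bad)}"))
    out = df[keep].reset_index(drop=True)
    report.n_kept = len(out)
    for sp, reason in report.dropped:
        logger.warning("excluded %s: %s", sp, reason)
    if return_report:
        return out, report
    return out


def write_trait_table(table: pd.DataFrame, path) -> None:
    """Write a trait table as CSV (no index column)."""
    table.to_csv(path, index=False)
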