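"""Gas-exchange table reading/writing and schema validation.

The canonical on-disk format is a UTF-8 CSV with one row per measurement
point, grouped into curves by ``curve_id`` (a Li-6400-style export
flattened to fixed, unit-suffixed column names).  A small alias converter
maps common instrument column names (e.g. "Photo" -> AN) onto the schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .c3 import ACiCurve

logger = logging.getLogger(__name__)

__all__ = [
    "SCHEMA_COLUMNS",
    "REQUIRED_COLUMNS",
    "COLUMN_ALIASES",
    "SchemaError",
    "ValidationReport",
    "read_gas_exchange",
    "write_gas_exchange",
    "curves_to_table",
    "convert_aliases",
]

SCHEMA_COLUMNS = [
    "curve_id",
    "species",
    "growth_T_C",
    "irrigation",
    "meas_T_C",
    "Ca_umol_mol",
    "Ci_umol_mol",
    "AN_umol_m2_s",
    "gs_mol_m2_s",
    "PPFD",
    "Tleaf_C",
    "Fs",
    "Fm_prime",
    "ETR_umol_m2_s",
    "Patm_kPa",
    "Rdark_umol_m2_s",
]

REQUIRED_COLUMNS = [
    "curve_id",
    "species",
    "growth_T_C",
    "irrigation",
    "meas_T_C",
    "Ca_umol_mol",
    "Ci_umol_mol",
    "AN_umol_m2_s",
    "gs_mol_m2_s",
    "Tleaf_C",
]

#: Common instrument export names mapped onto the schema.
COLUMN_ALIASES = {
    "Photo": "AN_umol_m2_s",
    "Cond": "gs_mol_m2_s",
    "Ci": "Ci_umol_mol",
    "CO2S": "Ca_umol_mol",
    "CO2R": "Ca_umol_mol",
    "PARi": "PPFD",
    "Tleaf": "Tleaf_C",
    "Press": "Patm_kPa",
    "Fs": "Fs",
    "Fm'": "Fm_prime",
}

_NUMERIC = [
    c
    for c in SCHEMA_COLUMNS
    if c not in ("curve_id", "species", "irrigation")
]


class SchemaError(ValueError):
    """The file does not conform to the gas-exchange schema."""


@dataclass
class ValidationReport:
    n_rows: int = 0
    n_curves: int = 0
    dropped_rows: list[tuple[int, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.dropped_rows and not self.warnings


def convert_aliases(df: pd.DataFrame, mapping: dict[str, str] | None = None) -> pd.DataFrame:
    """Rename instrument-export columns onto the schema (explicit mapping wins)."""
    return df.rename(columns={**COLUMN_ALIASES, **(mapping or {})})


def read_gas_exchange(path: str | Path) -> tuple[list[ACiCurve], ValidationReport]:
    """Read a schema-conformant CSV into curves grouped by ``curve_id``.

    Rows with non-numeric cells in numeric columns are dropped with a
    line-numbered warning; an empty file returns an empty list.  Missing
    required columns raise :class:`SchemaError` listing the columns.
    """
    report = ValidationReport()
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        report.warnings.append("empty file")
        logger.warning("gas-exchange file %s is empty", path)
        return [], report
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    present_numeric = [c for c in _NUMERIC if c in df.columns]
    converted = df.copy()
    for c in present_numeric:
        converted[c] = pd.to_numeric(df[c], errors="coerce")
    required_numeric = [c for c in present_numeric if c in REQUIRED_COLUMNS]
    bad = converted[required_numeric].isna().any(axis=1)
    for idx in converted.index[bad]:
        # +2: header line and 1-based numbering
        report.dropped_rows.append((int(idx) + 2, "non-numeric value in numeric column"))
        logger.warning("dropping line %d: non-numeric value", int(idx) + 2)
    converted = converted[~bad]
    report.n_rows = len(converted)

    curves = []
    for cid, grp in converted.groupby("curve_id", sort=False):
        curves.append(
            ACiCurve(
                Ca=grp["Ca_umol_mol"].to_numpy(),
                Ci=grp["Ci_umol_mol"].to_numpy(),
                AN=grp["AN_umol_m2_s"].to_numpy(),
                gs=grp["gs_mol_m2_s"].to_numpy(),
                Tleaf=grp["Tleaf_C"].to_numpy(),
                ETR=grp["ETR_umol_m2_s"].to_numpy() if "ETR_umol_m2_s" in grp and grp["ETR_umol_m2_s"].notna().all() else None,
                PPFD=grp["PPFD"].to_numpy() if "PPFD" in grp else None,
                Fs=grp["Fs"].to_numpy() if "Fs" in grp and grp["Fs"].notna().all() else None,
                Fm_prime=grp["Fm_prime"].to_numpy() if "Fm_prime" in grp and grp["Fm_prime"].notna().all() else None,
                species=str(grp["species"].iloc[0]),
                growth_T=float(grp["growth_T_C"].iloc[0]),
                irrigation=str(grp["irrigation"].iloc[0]),
                meas_T=float(grp["meas_T_C"].iloc[0]),
                Rdark=float(grp["Rdark_umol_m2_s"].iloc[0]) if "Rdark_umol_m2_s" in grp else 0.0,
                Patm_kPa=float(grp["Patm_kPa"].iloc[0]) if "Patm_kPa" in grp else 101.325,
                curve_id=str(cid),
            )
        )
    report.n_curves = len(curves)
    return curves, report


def curves_to_table(curves: list[ACiCurve]) -> pd.DataFrame:
    """Flatten curves into the schema DataFrame."""
    frames = []
    for c in curves:
        n = len(c)
        frames.append(
            pd.DataFrame(
                {
                    "curve_id": [c.curve_id] * n,
                    "species": [c.species] * n,
                    "growth_T_C": [c.growth_T] * n,
                    "irrigation": [c.irrigation] * n,
                    "meas_T_C": [c.meas_T] * n,
                    "Ca_umol_mol": c.Ca,
                    "Ci_umol_mol": c.Ci,
                    "AN_umol_m2_s": c.AN,
                    "gs_mol_m2_s": c.gs,
                    "PPFD": c.PPFD if c.PPFD is not None else np.nan,
                    "Tleaf_C": c.Tleaf,
                    "Fs": c.Fs if c.Fs is not None else np.nan,
                    "Fm_prime": c.Fm_prime if c.Fm_prime is not None else np.nan,
                    "ETR_umol_m2_s": c.ETR if c.ETR is not None else np.nan,
                    "Patm_kPa": [c.Patm_kPa] * n,
                    "Rdark_umol_m2_s": [c.Rdark] * n,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=SCHEMA_COLUMNS)
    return pd.concat(frames, ignore_index=True)[SCHEMA_COLUMNS]


def write_gas_exchange(curves: list[ACiCurve], path: str | Path) -> None:
    """Write curves to the canonical CSV (UTF-8, decimal point)."""
    curves_to_table(curves).to_csv(path, index=False)
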