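"""Delimited-text readers and writers for quality and ligand tables.

The quality-table dialect is a UTF-8 CSV (tab selectable) with the
missing-value token ``NA`` and the required header columns listed in
:data:`QUALITY_COLUMNS`. Unknown columns are preserved as annotations.
Row-level validation failures are collected with line numbers; valid
rows are always retained. Writers are deterministic: stable column
order and ``repr``-exact float formatting, so a write-read round trip
reproduces the records bit for bit.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .records import EntryQualityRecord, LigandFitRecord

__all__ = [
    "QualityTableDialect",
    "RowError",
    "QUALITY_COLUMNS",
    "read_quality_table",
    "write_quality_table",
    "read_ligand_table",
    "write_ligand_table",
]

QUALITY_COLUMNS = (
    "entry_id",
    "resolution",
    "rfree_depositor",
    "rfree_dcc",
    "rsrz_outlier_pct",
    "clashscore",
    "rama_outlier_pct",
    "rotamer_outlier_pct",
    "has_structure_factors",
    "free_set_designated",
    "deposition_date",
)

LIGAND_COLUMNS = ("entry_id", "ligand_code", "rsr", "rscc")


@dataclass(frozen=True)
class QualityTableDialect:
    delimiter: str = ","
    na_token: str = "NA"
    columns: tuple[str, ...] = QUALITY_COLUMNS


@dataclass(frozen=True)
class RowError:
    line: int
    entry_id: str
    message: str


def _opt_float(cell, na: str) -> Optional[float]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == na or cell == "":
        return None
    return float(cell)


def _bool(cell) -> bool:
    s = str(cell).strip().lower()
    if s in ("true", "1", "yes", "y"):
        return True
    if s in ("false", "0", "no", "n"):
        return False
    raise ValueError(f"not a boolean: {cell!r}")


def read_quality_table(
    path: str | Path, dialect: QualityTableDialect = QualityTableDialect()
) -> tuple[list[EntryQualityRecord], list[RowError]]:
    """Read a quality table; returns (valid records, row errors).

    A missing required column is a hard error naming it; invalid rows are
    reported with their 1-based line number and skipped.
    """
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in dialect.columns if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in dialect.columns]
    na = dialect.na_token
    records: list[EntryQualityRecord] = []
    errors: list[RowError] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        entry = str(row["entry_id"]).strip().lower()
        try:
            date_cell = row["deposition_date"]
            date = (
                _dt.date.fromisoformat(date_cell)
                if date_cell not in ("", na)
                else None
            )
            annotations = tuple(
                f"{c}={row[c]}" for c in extra if row[c] not in ("", na)
            )
            records.append(EntryQualityRecord(
                entry_id=entry,
                resolution=_opt_float(row["resolution"], na),
                rfree_depositor=_opt_float(row["rfree_depositor"], na),
                rfree_dcc=_opt_float(row["rfree_dcc"], na),
                rsrz_outlier_pct=_opt_float(row["rsrz_outlier_pct"], na),
                clashscore=float(row["clashscore"]),
                rama_outlier_pct=float(row["rama_outlier_pct"]),
                rotamer_outlier_pct=float(row["rotamer_outlier_pct"]),
                has_structure_factors=_bool(row["has_structure_factors"]),
                free_set_designated=_bool(row["free_set_designated"]),
                deposition_date=date,
                annotations=annotations,
            ))
        except (ValueError, TypeError) as exc:
            errors.append(RowError(line=line, entry_id=entry, message=str(exc)))
    return records, errors


def _fmt(value, na: str) -> str:
    if value is None:
        return na
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_quality_table(
    records: Sequence[EntryQualityRecord],
    path: str | Path,
    dialect: QualityTableDialect = QualityTableDialect(),
) -> None:
    sep = dialect.delimiter
    na = dialect.na_token
    lines = [sep.join(dialect.columns)]
    for r in records:
        date = r.deposition_date.isoformat() if r.deposition_date else na
        cells = [
            r.entry_id,
            _fmt(r.resolution, na),
            _fmt(r.rfree_depositor, na),
            _fmt(r.rfree_dcc, na),
            _fmt(r.rsrz_outlier_pct, na),
            _fmt(float(r.clashscore), na),
            _fmt(float(r.rama_outlier_pct), na),
            _fmt(float(r.rotamer_outlier_pct), na),
            _fmt(r.has_structure_factors, na),
            _fmt(r.free_set_designated, na),
            date,
        ]
        lines.append(sep.join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_ligand_table(path: str | Path) -> list[LigandFitRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in LIGAND_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    return [
        LigandFitRecord(
            entry_id=row["entry_id"],
            ligand_code=row["ligand_code"],
            rsr=float(row["rsr"]),
            rscc=float(row["rscc"]),
        )
        for _, row in df.iterrows()
    ]


def write_ligand_table(ligands: Sequence[LigandFitRecord], path: str | Path) -> None:
    lines = [",".join(LIGAND_COLUMNS)]
    for lig in ligands:
        lines.append(f"{lig.entry_id},{lig.ligand_code},{lig.rsr!r},{lig.rscc!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
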