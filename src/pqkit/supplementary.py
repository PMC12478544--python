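"""Recomputations over the survey's supplementary per-entry spreadsheet.

The PKA quality survey distributes its per-entry data as a supplementary
Excel spreadsheet (one row per deposit, with PQ1, resolution, R_free in
its depositor/DCC/re-refined variants, geometry metrics and flags). That
file is not redistributable with this package; users who download it can
point these functions at it to recompute the survey's headline numbers:

* the count of entries with PQ1 < 0.5;
* the count of entries with structure factors available;
* median R_free on the original (DCC) and re-refined sides;
* the median DCC-minus-re-refined R_free difference for entries
  deposited after January 2010.

Column names in supplementary spreadsheets are not standardized, so a
fuzzy header matcher maps them onto the canonical roles; pass an
explicit ``columns`` mapping to override it.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = ["load_supplementary_table", "recompute_headline_numbers"]

_ROLE_PATTERNS: dict[str, list[str]] = {
    "pq1": [r"^pq1\b", r"\bpq1\b"],
    "rfree_dcc": [r"dcc.*r.?free", r"r.?free.*dcc"],
    "rfree_redo": [r"(redo|rffin).*", r"r.?free.*redo"],
    "has_structure_factors": [r"structure.?factor", r"\bsf\b"],
    "deposition_date": [r"deposit.*date", r"release.*date", r"\bdate\b", r"\byear\b"],
}


def _match_columns(header: list[str]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for role, patterns in _ROLE_PATTERNS.items():
        for pat in patterns:
            hit = next(
                (c for c in header if re.search(pat, str(c), flags=re.IGNORECASE)), None
            )
            if hit is not None:
                mapping[role] = hit
                break
    return mapping


def load_supplementary_table(
    path: str | Path, columns: Optional[Mapping[str, str]] = None
) -> pd.DataFrame:
    """Load the per-entry sheet and normalize the recognized columns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"supplementary spreadsheet not found at {path}; it is an external "
            "download and is not shipped with this package"
        )
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    mapping = dict(columns) if columns else _match_columns(list(df.columns))
    return df.rename(columns={v: k for k, v in mapping.items()})


def recompute_headline_numbers(df: pd.DataFrame) -> dict[str, float]:
    """Headline counts and medians from a normalized per-entry table."""
    out: dict[str, float] = {}
    if "pq1" in df:
        pq1 = pd.to_numeric(df["pq1"], errors="coerce").dropna()
        out["n_pq1_below_half"] = int((pq1 < 0.5).sum())
    if "has_structure_factors" in df:
        sf = df["has_structure_factors"]
        truthy = sf.astype(str).str.strip().str.lower().isin(
            ("true", "1", "yes", "y")
        ) | (pd.to_numeric(sf, errors="coerce") == 1)
        out["n_with_structure_factors"] = int(truthy.sum())
    rfree_dcc = (
        pd.to_numeric(df["rfree_dcc"], errors="coerce") if "rfree_dcc" in df else None
    )
    rfree_redo = (
        pd.to_numeric(df["rfree_redo"], errors="coerce") if "rfree_redo" in df else None
    )
    if rfree_dcc is not None:
        out["median_rfree_original"] = float(np.median(rfree_dcc.dropna()))
    if rfree_redo is not None:
        out["median_rfree_rerefined"] = float(np.median(rfree_redo.dropna()))
    if rfree_dcc is not None and rfree_redo is not None:
        diff = (rfree_dcc - rfree_redo).dropna()
        if "deposition_date" in df:
            dates = pd.to_datetime(df["deposition_date"], errors="coerce")
            recent = dates >= pd.Timestamp("2010-01-01")
            diff = (rfree_dcc - rfree_redo)[recent].dropna()
        out["median_delta_rfree_dcc_minus_redo"] = float(np.median(diff))
    return out
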