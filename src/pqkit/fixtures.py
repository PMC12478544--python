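"""Curated PKA-deposit classification lists and worked re-refinement cases.

The published quality survey of cAMP-dependent protein kinase (PKA)
catalytic-domain crystal structures classifies its deposits into named
categories and discusses a handful of entries in numeric detail. Those
ID lists and worked values are transcribed here verbatim so the
categorization and paired-delta machinery can be exercised against known
desk-scale ground truth without any download.

Provenance notes carried with the data:

* the survey states 33 deposits lack diffraction data, while its
  structure-factor bookkeeping elsewhere implies 325 - 289 = 36; both
  counts are kept, unreconciled, with labels;
* the assorted-problems list is transcribed as printed (it lists
  ``3n9l`` although the running text discusses ``3l9l``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional

from .records import EntryQualityRecord, PairedEntry

__all__ = [
    "CuratedFixtures",
    "WorkedCase",
    "load_curated_fixtures",
    "fixture_quality_records",
    "fixture_worked_pairs",
]

_TOP10_NOT_IMPROVED = (
    "5n3l", "5n3o", "6spm", "5n1h", "5n1g", "6spu", "5n3n", "5n3t", "4c36", "5n3q",
)
_IMPROVED = (
    "6y89", "7e12", "4dfz", "3ag9", "4yxs", "2qcs", "3kkv", "4ae6", "1q62", "3ovv",
)
_WORSENED_GE_0P02 = (
    "5n3p", "5n3h", "6sox", "6sq1", "6zn0", "6z44", "5o5m", "6eh0", "5n3r", "5ok3",
)
_NO_STRUCTURE_FACTORS = (
    "2uzu", "2uzw", "2oh0", "2f7e", "2uzt", "2f7x", "2ojf", "2uzv", "2f7z",
    "1cmk", "1bx6", "1szm", "1stc", "1rek", "1rej", "1jbp", "1jlu", "1xha",
    "1cdk", "1svh", "1re8", "1xh6", "1sve", "1xh7", "2cpk", "1smh", "1svg",
    "1xh4", "1xh5", "1xh8", "1veb", "2c1a", "2c1b",
)
_FREE_SET_NOT_DESIGNATED = (
    "1ctp", "3idc", "2qvs", "3o7l", "1ydr", "1yds", "2jdt", "2uvz",
)
_ASSORTED_PROBLEMS = ("3pvb", "3e8c", "3nx8", "3l9m", "3n9l", "3l9n", "4nts")
_MOLPROBITY_ERRORS = ("1cdk", "3kkv", "4c36", "4c37", "4c38", "5uzk", "6qj7")


@dataclass(frozen=True)
class WorkedCase:
    """One deposit discussed with explicit numbers in the survey text."""

    entry_id: str
    resolution: Optional[float] = None
    rfree_depositor: Optional[float] = None
    rfree_dcc: Optional[float] = None
    rfree_redo: Optional[float] = None
    waters_original: Optional[int] = None
    waters_rerefined: Optional[int] = None
    note: str = ""


_WORKED_CASES: tuple[WorkedCase, ...] = (
    WorkedCase("6gzm", resolution=1.59, rfree_dcc=0.26, rfree_redo=0.3988,
               waters_original=833, waters_rerefined=49,
               note="re-refinement removed ~800 waters and raised R_free sharply"),
    WorkedCase("3e8c", resolution=2.2, rfree_depositor=0.290, rfree_dcc=0.286,
               rfree_redo=0.240,
               note="substantial R_free improvement; unjustified waters removed"),
    WorkedCase("3nx8", resolution=2.0, rfree_depositor=0.288, rfree_dcc=0.220,
               rfree_redo=0.210,
               note="large depositor/DCC discrepancy, possible free-set misidentification"),
    WorkedCase("3l9m", rfree_depositor=0.270, rfree_dcc=0.240, rfree_redo=0.205,
               note="very large improvement on re-refinement"),
    WorkedCase("3pvb", resolution=3.3, rfree_depositor=0.290, rfree_dcc=0.340,
               rfree_redo=0.326,
               note="holoenzyme with unexplained depositor/DCC discrepancy"),
    WorkedCase("5n3p", resolution=1.58, rfree_depositor=0.181, rfree_redo=0.205,
               note="top-quality entry worsened by re-refinement"),
)


@dataclass(frozen=True)
class CuratedFixtures:
    """Verbatim category ID lists, worked cases, and stated counts."""

    top10_not_improved: tuple[str, ...]
    improved: tuple[str, ...]
    worsened_ge_0p02: tuple[str, ...]
    no_structure_factors: tuple[str, ...]
    free_set_not_designated: tuple[str, ...]
    assorted_problems: tuple[str, ...]
    molprobity_errors: tuple[str, ...]
    worked_cases: tuple[WorkedCase, ...]
    stated_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        pdb_code = re.compile(r"^[0-9][a-z0-9]{3}$")
        for name in ("top10_not_improved", "improved", "worsened_ge_0p02",
                     "no_structure_factors", "free_set_not_designated",
                     "assorted_problems", "molprobity_errors"):
            for code in getattr(self, name):
                if not pdb_code.match(code):
                    raise ValueError(f"invalid PDB code {code!r} in {name}")


def load_curated_fixtures() -> CuratedFixtures:
    """The packaged fixture lists with provenance-labelled counts."""
    return CuratedFixtures(
        top10_not_improved=_TOP10_NOT_IMPROVED,
        improved=_IMPROVED,
        worsened_ge_0p02=_WORSENED_GE_0P02,
        no_structure_factors=_NO_STRUCTURE_FACTORS,
        free_set_not_designated=_FREE_SET_NOT_DESIGNATED,
        assorted_problems=_ASSORTED_PROBLEMS,
        molprobity_errors=_MOLPROBITY_ERRORS,
        worked_cases=_WORKED_CASES,
        stated_counts={
            # survey results text: deposits without diffraction data
            "no_diffraction_data_stated": 33,
            # survey results text: SF deposits without designated free set
            "free_set_not_designated_stated": 8,
            # survey methods bookkeeping: crystal structures and SF coverage
            "crystal_structures_total": 325,
            "with_structure_factors": 289,
            "without_structure_factors_implied": 325 - 289,  # unreconciled vs 33
            # survey results text: entries with PQ1 below 0.5
            "pq1_below_half": 125,
        },
    )


# placeholder geometry used when building flag-only categorization tables;
# values sit at the survey's cohort medians so records validate
_PLACEHOLDER_GEOMETRY = {"clashscore": 3.01, "rama_outlier_pct": 0.0, "rotamer_outlier_pct": 1.41}


def fixture_quality_records() -> list[EntryQualityRecord]:
    """Flag-only records for the categorization fixture table.

    Builds one record per curated entry ID with the availability flags the
    category lists imply; geometry metrics are synthetic placeholders
    (categorization never reads them).
    """
    fx = load_curated_fixtures()
    records: dict[str, EntryQualityRecord] = {}
    for code in fx.no_structure_factors:
        records[code] = EntryQualityRecord(
            entry_id=code, has_structure_factors=False, free_set_designated=False,
            **_PLACEHOLDER_GEOMETRY,
        )
    for code in fx.free_set_not_designated:
        records[code] = EntryQualityRecord(
            entry_id=code, has_structure_factors=True, free_set_designated=False,
            **_PLACEHOLDER_GEOMETRY,
        )
    for group in (fx.top10_not_improved, fx.improved, fx.worsened_ge_0p02):
        for code in group:
            records.setdefault(code, EntryQualityRecord(
                entry_id=code, has_structure_factors=True, free_set_designated=True,
                **_PLACEHOLDER_GEOMETRY,
            ))
    for code in fx.assorted_problems:
        base = records.get(code)
        if base is None:
            records[code] = EntryQualityRecord(
                entry_id=code, has_structure_factors=True, free_set_designated=True,
                annotations=("assorted_problems",), **_PLACEHOLDER_GEOMETRY,
            )
    return [records[k] for k in sorted(records)]


def fixture_worked_pairs() -> list[PairedEntry]:
    """Original/re-refined pairs for the worked cases with known R_free."""
    pairs = []
    for case in _WORKED_CASES:
        if case.rfree_redo is None:
            continue
        original = EntryQualityRecord(
            entry_id=case.entry_id,
            resolution=case.resolution,
            rfree_depositor=case.rfree_depositor,
            rfree_dcc=case.rfree_dcc,
            **_PLACEHOLDER_GEOMETRY,
        )
        rerefined = EntryQualityRecord(
            entry_id=case.entry_id,
            resolution=case.resolution,
            rfree_dcc=case.rfree_redo,
            **_PLACEHOLDER_GEOMETRY,
        )
        pairs.append(PairedEntry(entry_id=case.entry_id, original=original,
                                 rerefined=rerefined))
    return pairs
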