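"""Ligand fit quality scoring from real-space metrics.

A modelled small molecule is scored against a reference population of
ligands by combining two oriented percentile ranks: RSR (real-space R
factor, lower is better) and RSCC (real-space correlation coefficient,
higher is better). The equal-weight mean of the two percentiles yields a
fraction in [0, 1] -- 0 for the worst-fitting and 1 for the best-fitting
ligand relative to the reference. This mirrors the "ligand structure
quality assessment" sliders shown for PDB entries; the exact published
combination rule is proprietary to that pipeline, so the symmetric
two-percentile mean is adopted here as a documented approximation.

Solvent and ion components are not meaningful "ligands of interest" and
are excluded by a configurable component-code list before scoring.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .quality import percentile_rank
from .records import LigandFitRecord

__all__ = [
    "DEFAULT_EXCLUDED_COMPONENTS",
    "filter_ligands",
    "ligand_quality_score",
    "score_ligand_table",
]

# waters, common buffer/cryo additives and monoatomic ions
DEFAULT_EXCLUDED_COMPONENTS: frozenset[str] = frozenset({
    "HOH", "WAT", "DOD",
    "NA", "K", "LI", "CS", "CL", "BR", "IOD", "F",
    "MG", "CA", "ZN", "MN", "FE", "FE2", "NI", "CU", "CO", "CD", "HG",
    "SO4", "PO4", "NO3", "CO3", "NH4", "ACT", "FMT",
    "GOL", "EDO", "PEG", "PG4", "MPD", "TRS", "DMS", "BME",
})


def filter_ligands(
    ligands: Iterable[LigandFitRecord],
    excluded: frozenset[str] = DEFAULT_EXCLUDED_COMPONENTS,
) -> list[LigandFitRecord]:
    """Drop solvent/ion components so only ligands of interest are scored."""
    return [lig for lig in ligands if lig.ligand_code not in excluded]


def ligand_quality_score(
    ligand: LigandFitRecord, reference: Sequence[LigandFitRecord]
) -> float:
    """Fractional fit quality of one ligand against a reference population.

    Mean of the RSR percentile (lower RSR is better) and the RSCC
    percentile (higher RSCC is better), both mid-rank conventions, so the
    score is non-increasing in RSR and non-decreasing in RSCC.
    """
    if len(reference) == 0:
        raise ValueError("empty ligand reference population")
    rsr_ref = np.sort([r.rsr for r in reference])
    rscc_ref = np.sort([r.rscc for r in reference])
    p_rsr = percentile_rank(ligand.rsr, rsr_ref, "lower")
    p_rscc = percentile_rank(ligand.rscc, rscc_ref, "higher")
    return 0.5 * (p_rsr + p_rscc)


def score_ligand_table(
    ligands: Sequence[LigandFitRecord],
    reference: Sequence[LigandFitRecord] | None = None,
    excluded: frozenset[str] = DEFAULT_EXCLUDED_COMPONENTS,
) -> list[tuple[LigandFitRecord, float]]:
    """Score each ligand of interest; by default the cohort itself is the
    reference population (the scope of the reference is a caller decision)."""
    of_interest = filter_ligands(ligands, excluded)
    ref = filter_ligands(reference, excluded) if reference is not None else of_interest
    return [(lig, ligand_quality_score(lig, ref)) for lig in of_interest]
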