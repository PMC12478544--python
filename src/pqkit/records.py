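"""Core domain types for structure-quality assessment.

An :class:`EntryQualityRecord` carries the validation metrics routinely
reported for a crystal structure deposit: the cross-validation residual
R_free (as reported by the depositor and as independently recalculated by
DCC), the percentage of RSRZ (real-space R-value Z-score) outlier residues,
and the three MolProbity-style geometry metrics (clashscore, Ramachandran
outlier %, rotamer outlier %), together with availability flags for the
deposited diffraction data.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "EntryQualityRecord",
    "PQ1Result",
    "PairedEntry",
    "BoxplotSummary",
    "CategoryReport",
    "LigandFitRecord",
]


def _check_pct(name: str, value: Optional[float]) -> None:
    if value is not None and not 0.0 <= value <= 100.0:
        raise ValueError(f"{name} must lie in [0, 100], got {value!r}")


@dataclass(frozen=True)
class EntryQualityRecord:
    """Validation metrics and data-availability flags for one deposit.

    Percentage fields are on the 0-100 scale; R_free values are fractions in
    [0, 1]; resolution is in Angstrom. Entries deposited without structure
    factors cannot carry DCC-recalculated R_free or %RSRZ outliers (those
    require the diffraction data), which the constructor enforces.
    """

    entry_id: str
    clashscore: float
    rama_outlier_pct: float
    rotamer_outlier_pct: float
    resolution: Optional[float] = None
    rfree_depositor: Optional[float] = None
    rfree_dcc: Optional[float] = None
    rsrz_outlier_pct: Optional[float] = None
    has_structure_factors: bool = True
    free_set_designated: bool = True
    deposition_date: Optional[_dt.date] = None
    annotations: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "entry_id", str(self.entry_id).lower())
        if self.clashscore is None or self.clashscore < 0:
            raise ValueError(f"clashscore must be >= 0, got {self.clashscore!r}")
        _check_pct("rama_outlier_pct", self.rama_outlier_pct)
        _check_pct("rotamer_outlier_pct", self.rotamer_outlier_pct)
        if self.rama_outlier_pct is None or self.rotamer_outlier_pct is None:
            raise ValueError("geometry outlier percentages are required")
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError(f"resolution must be > 0, got {self.resolution!r}")
        for name in ("rfree_depositor", "rfree_dcc"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.rsrz_outlier_pct is not None and self.rsrz_outlier_pct < 0:
            raise ValueError("rsrz_outlier_pct must be >= 0")
        if not self.has_structure_factors:
            if self.rfree_dcc is not None or self.rsrz_outlier_pct is not None:
                raise ValueError(
                    "entries without structure factors cannot carry DCC R_free "
                    "or %RSRZ outliers"
                )

    @property
    def rfree(self) -> Optional[float]:
        """R_free with DCC-recalculated value taking priority over the
        depositor-reported one (DCC is the independent benchmark)."""
        return self.rfree_dcc if self.rfree_dcc is not None else self.rfree_depositor


@dataclass(frozen=True)
class PQ1Result:
    """Component percentiles and the final PQ1 score for one entry.

    ``mean_percentile`` is the arithmetic mean of the component percentiles
    that are present; ``pq1`` is its percentile rank within the reference
    population's mean-percentile distribution. ``estimated_geometry_only``
    marks entries scored from geometry alone (no diffraction data, so
    neither an R_free nor a %RSRZ percentile exists).
    """

    entry_id: str
    p_geometry: float
    mean_percentile: float
    pq1: float
    p_rfree: Optional[float] = None
    p_rsrz: Optional[float] = None
    estimated_geometry_only: bool = False

    def __post_init__(self) -> None:
        for name in ("p_geometry", "mean_percentile", "pq1", "p_rfree", "p_rsrz"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0 and math.isfinite(v)):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        components = [p for p in (self.p_rfree, self.p_rsrz, self.p_geometry) if p is not None]
        mean = sum(components) / len(components)
        if abs(mean - self.mean_percentile) > 1e-9:
            raise ValueError("mean_percentile must equal the mean of present components")
        if self.estimated_geometry_only != (self.p_rfree is None and self.p_rsrz is None):
            raise ValueError(
                "estimated_geometry_only must be set exactly when both the "
                "R_free and %RSRZ percentiles are absent"
            )


def _delta(a: Optional[float], b: Optional[float]) -> Optional[float]:
    if a is None or b is None:
        return None
    return b - a


@dataclass(frozen=True)
class PairedEntry:
    """One deposit paired with its automated re-refinement.

    Deltas are stored as re-refined minus original; for R_free the
    DCC-recalculated value is preferred on each side. A negative
    ``delta_rfree`` therefore means the re-refinement improved the fit to
    the diffraction data.
    """

    entry_id: str
    original: EntryQualityRecord
    rerefined: EntryQualityRecord

    def __post_init__(self) -> None:
        if self.original.entry_id != self.rerefined.entry_id:
            raise ValueError(
                f"entry_id mismatch: {self.original.entry_id!r} vs "
                f"{self.rerefined.entry_id!r}"
            )
        object.__setattr__(self, "entry_id", self.original.entry_id)

    @property
    def delta_rfree(self) -> Optional[float]:
        return _delta(self.original.rfree, self.rerefined.rfree)

    @property
    def delta_clashscore(self) -> Optional[float]:
        return _delta(self.original.clashscore, self.rerefined.clashscore)

    @property
    def delta_rama_pct(self) -> Optional[float]:
        return _delta(self.original.rama_outlier_pct, self.rerefined.rama_outlier_pct)

    @property
    def delta_rotamer_pct(self) -> Optional[float]:
        return _delta(self.original.rotamer_outlier_pct, self.rerefined.rotamer_outlier_pct)


@dataclass(frozen=True)
class BoxplotSummary:
    """Tukey box-and-whisker statistics of a labelled sample.

    Quartiles use linear interpolation between order statistics; whiskers
    sit at the most extreme observations within 1.5 x IQR of the hinges;
    everything beyond is listed in ``outliers``.
    """

    q1: float
    median: float
    q3: float
    lower_whisker: float
    upper_whisker: float
    outliers: tuple[tuple[str, float], ...]
    n: int

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    def __post_init__(self) -> None:
        if not self.q1 <= self.median <= self.q3:
            raise ValueError("quartiles out of order")
        lo = self.q1 - 1.5 * self.iqr
        hi = self.q3 + 1.5 * self.iqr
        for entry_id, v in self.outliers:
            if lo <= v <= hi:
                raise ValueError(f"outlier {entry_id}={v} lies inside the whisker span")


@dataclass(frozen=True)
class CategoryReport:
    """Entry-ID lists per quality category, in stable (sorted) order."""

    no_structure_factors: tuple[str, ...]
    free_set_not_designated: tuple[str, ...]
    improved: tuple[str, ...]
    worsened_ge_threshold: tuple[str, ...]
    top_not_improved: tuple[str, ...]
    assorted_problems: tuple[str, ...]
    delta_threshold: float = 0.02
    # the symmetric +/- threshold rule for improved/worsened is this
    # package's operationalization; flagged here so report consumers see it
    threshold_rule: str = "symmetric |delta_rfree| >= threshold (package convention)"

    def __post_init__(self) -> None:
        paired = set(self.improved) | set(self.worsened_ge_threshold) | set(self.top_not_improved)
        overlap = set(self.no_structure_factors) & paired
        if overlap:
            raise ValueError(
                f"entries without structure factors cannot be paired: {sorted(overlap)}"
            )


@dataclass(frozen=True)
class LigandFitRecord:
    """Real-space fit metrics for one modelled ligand.

    RSR (real-space R factor, lower is better) and RSCC (real-space
    correlation coefficient in [-1, 1], higher is better) quantify how well
    the ligand's atoms explain the local electron density.
    """

    entry_id: str
    ligand_code: str
    rsr: float
    rscc: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "entry_id", str(self.entry_id).lower())
        object.__setattr__(self, "ligand_code", str(self.ligand_code).upper())
        if not 1 <= len(self.ligand_code) <= 5:
            raise ValueError(f"ligand_code must be 1-5 characters, got {self.ligand_code!r}")
        if self.rsr < 0 or not math.isfinite(self.rsr):
            raise ValueError(f"rsr must be a finite value >= 0, got {self.rsr!r}")
        if not -1.0 <= self.rscc <= 1.0:
            raise ValueError(f"rscc must lie in [-1, 1], got {self.rscc!r}")
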