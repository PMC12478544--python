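"""PQ1 composite quality scoring against a reference population.

PQ1 condenses a crystal structure's validation record into a single number
in [0, 1]. Three component percentiles are computed against a reference
population of X-ray entries: the percentile of R_free (lower is better),
of the %RSRZ outlier fraction (lower is better), and of a geometry
component (lower is better) -- the first principal component of the
z-standardized triple (Ramachandran outlier %, rotamer outlier %,
clashscore). The mean of the available component percentiles is then
itself percentile-ranked against the population's mean-percentile
distribution, giving the final score:

    PQ1(entry) = rank( (P_Rfree + P_%RSRZ + P_geometry) / 3 )

with 0 the worst and 1 the best entry relative to the reference. Entries
deposited without diffraction data have neither R_free nor %RSRZ
percentiles; their PQ1 is estimated from the geometry component alone and
flagged as such.

Conventions (documented package choices):

* percentile rank is the mid-rank fraction ``(#strictly-worse + 0.5 *
  #ties) / n`` -- symmetric and bounded in [0, 1];
* the geometry PCA is fit on z-standardized metrics (clashscore and the
  two percentage metrics have incommensurate scales);
* the PC1 sign is fixed by requiring a non-negative clashscore loading,
  making larger projections mean worse geometry;
* scoring an entry that belongs to the reference uses the reference
  as-is (no leave-one-out);
* the mean-percentile re-ranking array is frozen at fit time -- scoring
  never mutates the population.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .records import EntryQualityRecord, PQ1Result

__all__ = [
    "ReferencePopulation",
    "BatchScores",
    "percentile_rank",
    "fit_reference",
    "geometry_score",
    "compute_pq1",
    "batch_pq1",
]

Orientation = Literal["lower", "higher"]

_GEOMETRY_FIELDS = ("rama_outlier_pct", "rotamer_outlier_pct", "clashscore")


class DegeneratePopulationError(ValueError):
    """A geometry metric has zero variance across the reference records."""


def percentile_rank(value: float, reference: np.ndarray, orientation: Orientation) -> float:
    """Mid-rank percentile of ``value`` within a sorted reference array.

    Returns ``(#strictly worse + 0.5 * #tied) / n`` where "worse" is
    resolved by ``orientation``: for ``"lower"`` (lower is better, e.g.
    R_free) worse means larger; for ``"higher"`` (e.g. a correlation
    coefficient) worse means smaller. Output is always in [0, 1]: 1.0 for
    a value better than the whole reference, 0.0 for one worse than all
    of it.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.size == 0:
        raise ValueError("empty reference population")
    if not np.isfinite(value):
        raise ValueError(f"non-finite value: {value!r}")
    lo = int(np.searchsorted(reference, value, side="left"))
    hi = int(np.searchsorted(reference, value, side="right"))
    ties = hi - lo
    if orientation == "lower":
        worse = reference.size - hi
    elif orientation == "higher":
        worse = lo
    else:
        raise ValueError(f"orientation must be 'lower' or 'higher', got {orientation!r}")
    return (worse + 0.5 * ties) / reference.size


@dataclass(frozen=True)
class ReferencePopulation:
    """Frozen percentile tables and geometry-PCA constants of a fit.

    All reference arrays are sorted ascending. ``geometry_mean`` /
    ``geometry_sd`` standardize the (rama %, rotamer %, clashscore)
    triple; ``pca_loadings`` is the unit first eigenvector of its
    correlation structure, oriented so larger projections are worse.
    """

    rfree_reference: np.ndarray
    rsrz_reference: np.ndarray
    geometry_reference: np.ndarray
    mean_percentile_reference: np.ndarray
    geometry_mean: np.ndarray
    geometry_sd: np.ndarray
    pca_loadings: np.ndarray
    n_records: int
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("rfree_reference", "rsrz_reference", "geometry_reference",
                     "mean_percentile_reference"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if np.any(np.diff(arr) < 0):
                raise ValueError(f"{name} must be sorted ascending")
        for name in ("geometry_mean", "geometry_sd", "pca_loadings"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.geometry_sd <= 0):
            raise ValueError("geometry standard deviations must be > 0")
        if abs(float(np.linalg.norm(self.pca_loadings)) - 1.0) > 1e-9:
            raise ValueError("pca_loadings must have unit norm")

    def to_json(self) -> str:
        payload = {
            "rfree_reference": self.rfree_reference.tolist(),
            "rsrz_reference": self.rsrz_reference.tolist(),
            "geometry_reference": self.geometry_reference.tolist(),
            "mean_percentile_reference": self.mean_percentile_reference.tolist(),
            "geometry_mean": self.geometry_mean.tolist(),
            "geometry_sd": self.geometry_sd.tolist(),
            "pca_loadings": self.pca_loadings.tolist(),
            "n_records": self.n_records,
            "label": self.label,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ReferencePopulation":
        d = json.loads(text)
        return cls(
            rfree_reference=np.array(d["rfree_reference"], dtype=float),
            rsrz_reference=np.array(d["rsrz_reference"], dtype=float),
            geometry_reference=np.array(d["geometry_reference"], dtype=float),
            mean_percentile_reference=np.array(d["mean_percentile_reference"], dtype=float),
            geometry_mean=np.array(d["geometry_mean"], dtype=float),
            geometry_sd=np.array(d["geometry_sd"], dtype=float),
            pca_loadings=np.array(d["pca_loadings"], dtype=float),
            n_records=int(d["n_records"]),
            label=d.get("label", ""),
        )


def _geometry_matrix(records: Sequence[EntryQualityRecord]) -> np.ndarray:
    return np.array(
        [[r.rama_outlier_pct, r.rotamer_outlier_pct, r.clashscore] for r in records],
        dtype=float,
    )


def fit_reference(records: Iterable[EntryQualityRecord], label: str = "") -> ReferencePopulation:
    """Fit percentile tables and the geometry PC1 on a reference set.

    Requires at least 3 records (all carry the full geometry triple by
    construction) and nonzero variance in each geometry column. R_free and
    %RSRZ reference arrays are built from the records where the metric is
    present; the geometry projection and the final mean-percentile
    re-ranking array cover every record.
    """
    records = list(records)
    if len(records) < 3:
        raise ValueError(f"need at least 3 records to fit a reference, got {len(records)}")
    geom = _geometry_matrix(records)
    mean = geom.mean(axis=0)
    sd = geom.std(axis=0, ddof=1)
    for j, name in enumerate(_GEOMETRY_FIELDS):
        if sd[j] <= 0:
            raise DegeneratePopulationError(
                f"geometry metric {name!r} has zero variance across the reference"
            )
    z = (geom - mean) / sd

    pca = PCA(n_components=1)
    pca.fit(z)
    loadings = pca.components_[0]
    loadings = loadings / np.linalg.norm(loadings)
    # orient so that a larger clashscore worsens (raises) the projection
    if loadings[2] < 0:
        loadings = -loadings

    projections = z @ loadings
    rfree = np.sort([r.rfree for r in records if r.rfree is not None])
    rsrz = np.sort([r.rsrz_outlier_pct for r in records if r.rsrz_outlier_pct is not None])
    geometry_ref = np.sort(projections)

    partial = ReferencePopulation(
        rfree_reference=np.asarray(rfree, dtype=float),
        rsrz_reference=np.asarray(rsrz, dtype=float),
        geometry_reference=geometry_ref,
        mean_percentile_reference=np.array([0.0]),  # placeholder, replaced below
        geometry_mean=mean,
        geometry_sd=sd,
        pca_loadings=loadings,
        n_records=len(records),
        label=label,
    )
    means = [_mean_percentile(r, partial) for r in records]
    return ReferencePopulation(
        rfree_reference=partial.rfree_reference,
        rsrz_reference=partial.rsrz_reference,
        geometry_reference=partial.geometry_reference,
        mean_percentile_reference=np.sort(means),
        geometry_mean=mean,
        geometry_sd=sd,
        pca_loadings=loadings,
        n_records=len(records),
        label=label,
    )


def geometry_score(record: EntryQualityRecord, population: ReferencePopulation) -> float:
    """Project a record's standardized geometry triple on the population PC1.

    Larger values mean worse geometry (the loading sign convention fixes
    this); a record sitting at the population mean of all three metrics
    scores exactly 0.
    """
    for name in _GEOMETRY_FIELDS:
        if getattr(record, name) is None:
            raise ValueError(f"geometry metric {name!r} missing on {record.entry_id}")
    triple = np.array(
        [record.rama_outlier_pct, record.rotamer_outlier_pct, record.clashscore], dtype=float
    )
    z = (triple - population.geometry_mean) / population.geometry_sd
    return float(z @ population.pca_loadings)


def _components(
    record: EntryQualityRecord, population: ReferencePopulation
) -> tuple[Optional[float], Optional[float], float]:
    p_rfree = None
    if record.rfree is not None and population.rfree_reference.size > 0:
        p_rfree = percentile_rank(record.rfree, population.rfree_reference, "lower")
    p_rsrz = None
    if record.rsrz_outlier_pct is not None and population.rsrz_reference.size > 0:
        p_rsrz = percentile_rank(record.rsrz_outlier_pct, population.rsrz_reference, "lower")
    p_geom = percentile_rank(
        geometry_score(record, population), population.geometry_reference, "lower"
    )
    return p_rfree, p_rsrz, p_geom


def _mean_percentile(record: EntryQualityRecord, population: ReferencePopulation) -> float:
    p_rfree, p_rsrz, p_geom = _components(record, population)
    parts = [p for p in (p_rfree, p_rsrz, p_geom) if p is not None]
    return float(np.mean(parts))


def compute_pq1(record: EntryQualityRecord, population: ReferencePopulation) -> PQ1Result:
    """Score one entry: component percentiles, their mean, and PQ1.

    The mean of the present component percentiles is ranked
    (higher-is-better) against the population's frozen mean-percentile
    array. When R_free and %RSRZ are both unavailable the score is
    estimated from geometry alone and flagged.
    """
    p_rfree, p_rsrz, p_geom = _components(record, population)
    parts = [p for p in (p_rfree, p_rsrz, p_geom) if p is not None]
    mean = float(np.mean(parts))
    pq1 = percentile_rank(mean, population.mean_percentile_reference, "higher")
    return PQ1Result(
        entry_id=record.entry_id,
        p_rfree=p_rfree,
        p_rsrz=p_rsrz,
        p_geometry=p_geom,
        mean_percentile=mean,
        pq1=pq1,
        estimated_geometry_only=(p_rfree is None and p_rsrz is None),
    )


@dataclass(frozen=True)
class BatchScores:
    """Scores for a cohort plus a decile histogram of the PQ1 values."""

    results: tuple[PQ1Result, ...]
    errors: tuple[tuple[str, str], ...]  # (entry_id, message) for failed rows
    histogram_fractions: tuple[float, ...]  # 10 equal bins on [0, 1]
    n_below_half: int
    n_at_or_above_half: int

    def to_dict(self) -> dict:
        return {
            "n_scored": len(self.results),
            "n_errors": len(self.errors),
            "histogram_fractions": list(self.histogram_fractions),
            "n_below_half": self.n_below_half,
            "n_at_or_above_half": self.n_at_or_above_half,
        }


def batch_pq1(
    records: Iterable[EntryQualityRecord], population: ReferencePopulation
) -> BatchScores:
    """Score a cohort and summarize the PQ1 distribution.

    Per-record failures are collected as flagged rows rather than aborting
    the batch. The histogram uses 10 equal bins on [0, 1] (right-closed
    last bin) and is reported as fractions of the scored records.
    """
    results: list[PQ1Result] = []
    errors: list[tuple[str, str]] = []
    for record in records:
        try:
            results.append(compute_pq1(record, population))
        except Exception as exc:  # noqa: BLE001 - flagged row, batch continues
            errors.append((record.entry_id, str(exc)))
    values = np.array([r.pq1 for r in results], dtype=float)
    if values.size:
        counts, _ = np.histogram(values, bins=10, range=(0.0, 1.0))
        fractions = tuple((counts / values.size).tolist())
        below = int(np.sum(values < 0.5))
    else:
        fractions = tuple([0.0] * 10)
        below = 0
    return BatchScores(
        results=tuple(results),
        errors=tuple(errors),
        histogram_fractions=fractions,
        n_below_half=below,
        n_at_or_above_half=len(results) - below,
    )
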