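"""Paired original-vs-re-refined cohort statistics and categorization.

Automated re-refinement pipelines (PDB-REDO style) produce, for each
deposit with structure factors, a second model whose validation metrics
can be compared with the original's. This module computes per-entry
deltas, Tukey boxplot summaries of delta distributions, cohort-level
mean/median tables, and a categorization of entries into quality classes:
deposits without structure factors, deposits whose free-reflection set
was not designated, entries improved or worsened by re-refinement beyond
a threshold on delta R_free, and top-quality entries the re-refinement
could not improve.

Delta sign convention: deltas are stored as re-refined minus original
throughout; reporting layers that want the opposite orientation (original
minus re-refined, as some violin-plot presentations use) negate at the
interface via :func:`reported_rfree_differences`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .quality import ReferencePopulation, compute_pq1
from .records import BoxplotSummary, CategoryReport, EntryQualityRecord, PairedEntry

__all__ = [
    "paired_delta",
    "boxplot_summary",
    "summarize_cohort",
    "categorize_entries",
    "reported_rfree_differences",
    "MetricSummary",
    "CohortSummary",
]


def paired_delta(original: EntryQualityRecord, rerefined: EntryQualityRecord) -> PairedEntry:
    """Pair one deposit with its re-refined counterpart.

    The two records must describe the same entry; deltas (re-refined minus
    original) are exposed per metric wherever both sides carry it.
    """
    return PairedEntry(entry_id=original.entry_id, original=original, rerefined=rerefined)


def boxplot_summary(values: Iterable[tuple[str, float]]) -> BoxplotSummary:
    """Tukey five-number summary with 1.5 x IQR whiskers and outlier list.

    Quartiles use linear interpolation between order statistics; whiskers
    sit at the most extreme observations still within 1.5 x IQR of the
    hinges, so every value is either inside the whisker span or listed as
    an outlier.
    """
    labelled = list(values)
    if not labelled:
        raise ValueError("empty input")
    arr = np.array([v for _, v in labelled], dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    outliers = tuple(
        (entry_id, float(v)) for entry_id, v in labelled if v < lo_fence or v > hi_fence
    )
    return BoxplotSummary(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        lower_whisker=float(inside.min()),
        upper_whisker=float(inside.max()),
        outliers=outliers,
        n=len(labelled),
    )


def reported_rfree_differences(pairs: Sequence[PairedEntry]) -> list[tuple[str, float]]:
    """R_free differences oriented as original minus re-refined.

    This is the presentation convention of re-refinement violin plots
    (positive = re-refinement lowered R_free); internally deltas are
    stored re-refined minus original, so this negates at the interface.
    """
    return [(p.entry_id, -p.delta_rfree) for p in pairs if p.delta_rfree is not None]


@dataclass(frozen=True)
class MetricSummary:
    mean: float
    median: float
    n: int


@dataclass(frozen=True)
class CohortSummary:
    """Per-metric mean/median for the original and re-refined sides."""

    original: Mapping[str, MetricSummary]
    rerefined: Mapping[str, MetricSummary]

    def to_dict(self) -> dict:
        return {
            side: {
                m: {"mean": s.mean, "median": s.median, "n": s.n}
                for m, s in getattr(self, side).items()
            }
            for side in ("original", "rerefined")
        }


# rfree uses the DCC-over-depositor priority; the depositor-reported value
# is also summarized separately so either convention can be tabulated
_SUMMARY_METRICS = {
    "rfree": lambda r: r.rfree,
    "rfree_depositor": lambda r: r.rfree_depositor,
    "clashscore": lambda r: r.clashscore,
    "rama_outlier_pct": lambda r: r.rama_outlier_pct,
    "rotamer_outlier_pct": lambda r: r.rotamer_outlier_pct,
}


def summarize_cohort(pairs: Sequence[PairedEntry]) -> CohortSummary:
    """Mean and linear-interpolation median per metric and side.

    A metric missing on one side of a pair is simply excluded from that
    metric's summary (per-metric n is reported), matching how paired
    validation tables with incomplete coverage are aggregated.
    """
    if not pairs:
        raise ValueError("empty cohort")
    out: dict[str, dict[str, MetricSummary]] = {"original": {}, "rerefined": {}}
    for side in ("original", "rerefined"):
        for metric, getter in _SUMMARY_METRICS.items():
            vals = [getter(getattr(p, side)) for p in pairs]
            vals = np.array([v for v in vals if v is not None], dtype=float)
            if vals.size:
                out[side][metric] = MetricSummary(
                    mean=float(vals.mean()), median=float(np.median(vals)), n=int(vals.size)
                )
    return CohortSummary(original=out["original"], rerefined=out["rerefined"])


def categorize_entries(
    records: Sequence[EntryQualityRecord],
    pairs: Sequence[PairedEntry] = (),
    delta_threshold: float = 0.02,
    population: Optional[ReferencePopulation] = None,
) -> CategoryReport:
    """Classify deposits into quality categories (stable under reordering).

    * ``no_structure_factors`` -- deposits lacking diffraction data;
    * ``free_set_not_designated`` -- structure-factor deposits whose free
      reflections were not identified by the depositor;
    * ``worsened_ge_threshold`` / ``improved`` -- pairs with
      delta R_free >= +threshold / <= -threshold (default 0.02);
    * ``top_not_improved`` -- pairs in the top decile of original PQ1
      whose R_free did not decrease (requires a fitted ``population``);
    * ``assorted_problems`` -- pass-through of records carrying
      annotations.
    """
    if delta_threshold <= 0:
        raise ValueError("delta_threshold must be > 0")
    no_sf = sorted({r.entry_id for r in records if not r.has_structure_factors})
    free_not = sorted(
        {r.entry_id for r in records if r.has_structure_factors and not r.free_set_designated}
    )
    worsened = sorted(
        {p.entry_id for p in pairs if p.delta_rfree is not None and p.delta_rfree >= delta_threshold}
    )
    improved = sorted(
        {p.entry_id for p in pairs if p.delta_rfree is not None and p.delta_rfree <= -delta_threshold}
    )
    top_not_improved: list[str] = []
    if population is not None and pairs:
        scored = [(p, compute_pq1(p.original, population).pq1) for p in pairs]
        cut = float(np.percentile([s for _, s in scored], 90))
        top_not_improved = sorted(
            {
                p.entry_id
                for p, s in scored
                if s >= cut and p.delta_rfree is not None and p.delta_rfree >= 0
            }
        )
    assorted = sorted({r.entry_id for r in records if r.annotations})
    return CategoryReport(
        no_structure_factors=tuple(no_sf),
        free_set_not_designated=tuple(free_not),
        improved=tuple(improved),
        worsened_ge_threshold=tuple(worsened),
        top_not_improved=tuple(top_not_improved),
        assorted_problems=tuple(assorted),
        delta_threshold=delta_threshold,
    )
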