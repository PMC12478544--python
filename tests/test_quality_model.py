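"""PQ1 scoring: percentile ranks, geometry PCA, and the composite score."""

import json
import math

import numpy as np
import pytest

from pqkit import (
    EntryQualityRecord,
    ReferencePopulation,
    batch_pq1,
    compute_pq1,
    fit_reference,
    geometry_score,
    percentile_rank,
)
from pqkit.quality import DegeneratePopulationError

from conftest import brute_force_pc1, brute_force_percentile, make_record


class TestPercentileRank:
    @pytest.mark.parametrize(
        "value,reference,orientation,expected",
        [
            (0.10, [0.20, 0.22, 0.25, 0.30], "lower", 1.0),   # best of all
            (0.50, [0.20, 0.22, 0.25, 0.30], "lower", 0.0),   # worst of all
            (0.24, [0.20, 0.22, 0.25, 0.30], "lower", 0.5),   # two strictly worse
            (0.95, [0.5, 0.7, 0.9], "higher", 1.0),
            (0.22, [0.20, 0.22, 0.25, 0.30], "lower", (2 + 0.5) / 4),  # one tie
        ],
    )
    def test_counting_examples(self, value, reference, orientation, expected):
        ref = np.sort(reference)
        assert percentile_rank(value, ref, orientation) == pytest.approx(expected)

    def test_rejects_empty_reference_and_nonfinite_value(self):
        with pytest.raises(ValueError):
            percentile_rank(0.2, np.array([]), "lower")
        with pytest.raises(ValueError):
            percentile_rank(float("nan"), np.array([0.1]), "lower")

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(1, 201)
            ref = np.sort(np.round(rng.normal(size=n), 2))  # rounding forces ties
            value = float(np.round(rng.normal(), 2))
            for orientation in ("lower", "higher"):
                assert percentile_rank(value, ref, orientation) == brute_force_percentile(
                    value, ref, orientation
                )

    def test_self_ranking_mean_is_half(self):
        rng = np.random.default_rng(3)
        values = np.sort(rng.normal(size=37))  # continuous draws: tie-free
        ranks = [percentile_rank(v, values, "lower") for v in values]
        assert np.mean(ranks) == pytest.approx(0.5, abs=1 / (2 * len(values)))


class TestFitReference:
    def test_requires_three_records(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_reference([make_record("9aaa"), make_record("9aab")])

    def test_zero_variance_column_rejected_by_name(self):
        records = [
            make_record(f"9aa{i}", clash=5.0, rama=0.1 * i, rota=1.0 + i) for i in range(5)
        ]
        with pytest.raises(DegeneratePopulationError, match="clashscore"):
            fit_reference(records)

    def test_pc1_tracks_dominant_clashscore_axis(self):
        # variance overwhelmingly in clashscore after standardization is
        # impossible; instead correlate the other two tightly with clash so
        # PC1 has a strictly positive clashscore loading and orders by clash
        rng = np.random.default_rng(5)
        records = []
        for i in range(50):
            c = float(rng.uniform(1, 20))
            records.append(make_record(f"9b{i:02d}", clash=c, rama=0.05 * c, rota=0.3 * c))
        pop = fit_reference(records)
        assert pop.pca_loadings[2] > 0
        scores = [geometry_score(r, pop) for r in records]
        order = np.argsort([r.clashscore for r in records])
        assert np.all(np.diff(np.array(scores)[order]) > 0)

    def test_loadings_match_brute_force_eigendecomposition(self):
        rng = np.random.default_rng(11)
        cov = np.array([[1.0, 0.6, 0.3], [0.6, 2.0, 0.5], [0.3, 0.5, 1.5]])
        raw = np.abs(rng.multivariate_normal([1, 3, 6], cov, size=100))
        records = [
            make_record(f"9c{i:02d}", rama=row[0], rota=row[1], clash=row[2])
            for i, row in enumerate(raw)
        ]
        pop = fit_reference(records)
        z = (raw - raw.mean(axis=0)) / raw.std(axis=0, ddof=1)
        expected = brute_force_pc1(z)
        if expected[2] < 0:
            expected = -expected
        assert np.allclose(pop.pca_loadings, expected, atol=1e-8)

    def test_reference_arrays_sorted_and_loadings_unit(self, fitted_population):
        pop = fitted_population
        for arr in (pop.rfree_reference, pop.rsrz_reference, pop.geometry_reference,
                    pop.mean_percentile_reference):
            assert np.all(np.diff(arr) >= 0)
        assert np.linalg.norm(pop.pca_loadings) == pytest.approx(1.0, abs=1e-12)


class TestGeometryScore:
    def test_population_mean_projects_to_zero(self, fitted_population):
        pop = fitted_population
        record = make_record(
            "9fff",
            rama=pop.geometry_mean[0],
            rota=pop.geometry_mean[1],
            clash=pop.geometry_mean[2],
        )
        assert geometry_score(record, pop) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_recomputation(self, synthetic_records, fitted_population):
        pop = fitted_population
        for r in synthetic_records[:25]:
            z = [
                (r.rama_outlier_pct - pop.geometry_mean[0]) / pop.geometry_sd[0],
                (r.rotamer_outlier_pct - pop.geometry_mean[1]) / pop.geometry_sd[1],
                (r.clashscore - pop.geometry_mean[2]) / pop.geometry_sd[2],
            ]
            expected = sum(zi * li for zi, li in zip(z, pop.pca_loadings))
            assert geometry_score(r, pop) == pytest.approx(expected, abs=1e-12)

    def test_larger_clashscore_scores_worse(self, fitted_population):
        a = make_record("9aaa", clash=2.0)
        b = make_record("9aab", clash=30.0)
        assert geometry_score(b, fitted_population) > geometry_score(a, fitted_population)


def enumerate_pq1(records):
    """Exhaustive hand-style recomputation of the composite score for every
    member of a small population: count-based percentiles per component,
    average, then count-based re-rank of the averages."""
    geo = np.array([[r.rama_outlier_pct, r.rotamer_outlier_pct, r.clashscore] for r in records])
    z = (geo - geo.mean(axis=0)) / geo.std(axis=0, ddof=1)
    v = brute_force_pc1(z)
    if v[2] < 0:
        v = -v
    proj = z @ v
    rfrees = [r.rfree for r in records]
    rsrzs = [r.rsrz_outlier_pct for r in records]
    means = []
    for i, r in enumerate(records):
        parts = [
            brute_force_percentile(r.rfree, rfrees, "lower"),
            brute_force_percentile(r.rsrz_outlier_pct, rsrzs, "lower"),
            brute_force_percentile(proj[i], list(proj), "lower"),
        ]
        means.append(sum(parts) / 3)
    return [brute_force_percentile(m, means, "higher") for m in means]


class TestComputePQ1:
    @pytest.fixture()
    def hand_population(self):
        return [
            make_record("9h00", rfree=0.18, rsrz=0.5, clash=2.0, rama=0.0, rota=0.5),
            make_record("9h01", rfree=0.21, rsrz=1.5, clash=4.0, rama=0.2, rota=1.5),
            make_record("9h02", rfree=0.24, rsrz=3.0, clash=7.0, rama=0.5, rota=3.0),
            make_record("9h03", rfree=0.28, rsrz=6.0, clash=12.0, rama=1.5, rota=6.0),
            make_record("9h04", rfree=0.33, rsrz=9.0, clash=25.0, rama=4.0, rota=11.0),
        ]

    def test_dominant_record_scores_one(self, fitted_population, synthetic_records):
        best = make_record("9bst", rfree=0.01, rsrz=0.0, clash=0.0, rama=0.0, rota=0.0)
        assert compute_pq1(best, fitted_population).pq1 == 1.0

    def test_matches_exhaustive_enumeration(self, hand_population):
        pop = fit_reference(hand_population)
        expected = enumerate_pq1(hand_population)
        for record, exp in zip(hand_population, expected):
            result = compute_pq1(record, pop)
            assert result.pq1 == pytest.approx(exp, abs=1e-12)
            assert result.mean_percentile == pytest.approx(
                np.mean([result.p_rfree, result.p_rsrz, result.p_geometry]), abs=1e-12
            )

    def test_geometry_only_estimation_flagged(self, fitted_population):
        legacy = make_record(
            "9old", rfree=None, rfree_depositor=None, rsrz=None,
            has_structure_factors=False, free_set_designated=False,
        )
        result = compute_pq1(legacy, fitted_population)
        assert result.estimated_geometry_only
        assert result.p_rfree is None and result.p_rsrz is None
        assert result.mean_percentile == result.p_geometry

    def test_single_missing_component_averages_present_ones(self, fitted_population):
        partial = make_record("9par", rsrz=None, has_structure_factors=True)
        result = compute_pq1(partial, fitted_population)
        assert not result.estimated_geometry_only
        assert result.p_rsrz is None
        assert result.mean_percentile == pytest.approx(
            (result.p_rfree + result.p_geometry) / 2
        )

    def test_lowering_rfree_never_lowers_pq1(self, fitted_population):
        rfrees = np.linspace(0.40, 0.10, 31)
        scores = [
            compute_pq1(make_record("9mon", rfree=float(rf)), fitted_population).pq1
            for rf in rfrees
        ]
        assert np.all(np.diff(scores) >= 0)

    def test_scores_bounded(self, synthetic_records, fitted_population):
        for r in synthetic_records:
            res = compute_pq1(r, fitted_population)
            assert 0.0 <= res.pq1 <= 1.0


class TestBatchPQ1:
    def test_identical_records_collapse_to_one_bin(self, fitted_population):
        records = [make_record(f"9d{i:02d}") for i in range(8)]
        batch = batch_pq1(records, fitted_population)
        assert len(set(r.pq1 for r in batch.results)) == 1
        assert max(batch.histogram_fractions) == pytest.approx(1.0)
        assert sum(batch.histogram_fractions) == pytest.approx(1.0)

    def test_empty_input(self, fitted_population):
        batch = batch_pq1([], fitted_population)
        assert batch.results == ()
        assert batch.histogram_fractions == tuple([0.0] * 10)
        assert batch.n_below_half == 0 == batch.n_at_or_above_half

    def test_better_half_cohort_skews_high(self, synthetic_records, fitted_population):
        scored = sorted(
            synthetic_records, key=lambda r: compute_pq1(r, fitted_population).pq1
        )
        better_half = scored[len(scored) // 2:]
        batch = batch_pq1(better_half, fitted_population)
        assert batch.n_below_half < batch.n_at_or_above_half

    def test_per_record_failures_are_flagged_not_fatal(self, fitted_population):
        class Broken:
            entry_id = "9bad"
            rama_outlier_pct = None
            rotamer_outlier_pct = 1.0
            clashscore = 1.0
            rfree = None
            rsrz_outlier_pct = None

        batch = batch_pq1([make_record("9ok0"), Broken()], fitted_population)
        assert len(batch.results) == 1
        assert batch.errors[0][0] == "9bad"
        assert "rama" in batch.errors[0][1]


class TestSerialization:
    def test_json_round_trip(self, fitted_population):
        text = fitted_population.to_json()
        restored = ReferencePopulation.from_json(text)
        for name in ("rfree_reference", "rsrz_reference", "geometry_reference",
                     "mean_percentile_reference", "geometry_mean", "geometry_sd",
                     "pca_loadings"):
            assert np.array_equal(getattr(restored, name), getattr(fitted_population, name))
        assert restored.n_records == fitted_population.n_records
        record = make_record("9rtt")
        assert compute_pq1(record, restored) == compute_pq1(record, fitted_population)

    def test_rejects_unsorted_reference(self):
        with pytest.raises(ValueError, match="sorted"):
            ReferencePopulation(
                rfree_reference=np.array([0.3, 0.2]),
                rsrz_reference=np.array([1.0]),
                geometry_reference=np.array([0.0]),
                mean_percentile_reference=np.array([0.5]),
                geometry_mean=np.zeros(3),
                geometry_sd=np.ones(3),
                pca_loadings=np.array([0.0, 0.0, 1.0]),
                n_records=2,
            )
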