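"""Unit tests for assemblage analytics, each checked against an
independent brute-force oracle on small fixtures."""

import itertools

import numpy as np
import pandas as pd
import pytest

import rabi
from rabi import AnalyticsWarning, OccurrenceMatrix, SpeciesScore, ValidationError
from conftest import random_matrix


def exact_accumulation(presence: np.ndarray):
    """Mean/SD accumulation curve by enumerating every site ordering."""
    n = presence.shape[0]
    curves = []
    for perm in itertools.permutations(range(n)):
        cumulative = np.cumsum(presence[list(perm)], axis=0) > 0
        curves.append(cumulative.sum(axis=1))
    curves = np.array(curves)
    return curves.mean(axis=0), curves.std(axis=0)


class TestEcozoneSummaries:
    def test_toy_fixture_counts(self, toy_matrix):
        summaries = {s.ecozone: s for s in rabi.ecozone_summaries(toy_matrix)}
        z1 = summaries["Z1"]
        assert (z1.n_sites, z1.total_species, z1.unique_species) == (2, 3, 1)
        assert z1.unique_pct == rabi.round_half_up(100 / 3, 1)
        assert z1.most_common_species == ("s1",)  # two records, s2/s5 one each
        assert summaries["Z3"].unique_species == 1
        total = summaries["total"]
        assert total.total_species == 6
        assert total.most_common_species == ("s1", "s3")  # three records each
        assert total.unique_species is None
        assert total.mean_species_per_site == pytest.approx(11 / 5)

    def test_species_in_two_zones_unique_in_neither(self, toy_matrix):
        # s1 occurs in Z1 and Z2: both zones' unique sets exclude it
        summaries = {s.ecozone: s for s in rabi.ecozone_summaries(toy_matrix)}
        assert summaries["Z1"].unique_species == 1  # only s2
        assert summaries["Z2"].unique_species == 1  # only s6

    def test_matches_set_algebra_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            matrix = random_matrix(rng, int(rng.integers(2, 7)), int(rng.integers(2, 9)))
            per_zone = {
                ez: {
                    sp
                    for site in matrix.sites_in(ez)
                    for sp in matrix.species_at(site)
                }
                for ez in matrix.ecozones
            }
            for s in rabi.ecozone_summaries(matrix):
                if s.ecozone == "total":
                    assert s.total_species == len(set().union(*per_zone.values()))
                    continue
                expected_unique = per_zone[s.ecozone] - {
                    sp
                    for ez, spp in per_zone.items()
                    if ez != s.ecozone
                    for sp in spp
                }
                assert s.total_species == len(per_zone[s.ecozone])
                assert s.unique_species == len(expected_unique)

    def test_unique_sum_bounded_by_regional_richness(self, toy_matrix):
        summaries = rabi.ecozone_summaries(toy_matrix)
        total = next(s for s in summaries if s.ecozone == "total")
        unique_sum = sum(
            s.unique_species for s in summaries if s.ecozone != "total"
        )
        assert unique_sum <= total.total_species

    def test_declared_empty_ecozone_warns_and_reports_zeros(self, toy_matrix):
        with pytest.warns(AnalyticsWarning, match="no sites"):
            summaries = rabi.ecozone_summaries(toy_matrix, ecozones=["Z1", "Z2", "Z3", "Z4"])
        z4 = next(s for s in summaries if s.ecozone == "Z4")
        assert (z4.n_sites, z4.total_species, z4.unique_species) == (0, 0, 0)


class TestSharedSpeciesMatrix:
    def test_toy_fixture(self, toy_matrix):
        shared = rabi.shared_species_matrix(toy_matrix)
        counts = shared.counts
        assert (counts.values == counts.values.T).all()
        assert list(np.diag(counts)) == [3, 4, 2]
        assert counts.loc["Z1", "Z2"] == 2 and counts.loc["Z1", "Z3"] == 0
        assert shared.row_pct.loc["Z1", "Z2"] == pytest.approx(200 / 3)
        assert shared.row_pct.loc["Z2", "Z1"] == pytest.approx(50.0)
        assert (np.diag(shared.row_pct) == 100.0).all()

    def test_counts_bounded_by_pairwise_min_richness(self):
        rng = np.random.default_rng(3)
        matrix = random_matrix(rng, 6, 10)
        shared = rabi.shared_species_matrix(matrix)
        diag = np.diag(shared.counts)
        bound = np.minimum.outer(diag, diag)
        assert (shared.counts.values <= bound).all()

    def test_zone_without_species_gives_nan_row(self):
        frame = pd.DataFrame(
            [[1, 1], [0, 0]], index=["a", "b"], columns=["s1", "s2"]
        )
        matrix = OccurrenceMatrix(frame, {"a": "Z1", "b": "Z2"})
        with pytest.warns(AnalyticsWarning, match="zero species"):
            shared = rabi.shared_species_matrix(matrix)
        assert shared.row_pct.loc["Z2"].isna().all()
        assert not shared.row_pct.loc["Z1"].isna().any()

    def test_requires_two_ecozones(self):
        frame = pd.DataFrame([[1]], index=["a"], columns=["s"])
        matrix = OccurrenceMatrix(frame, {"a": "Z1"})
        with pytest.raises(ValidationError, match="at least 2 ecozones"):
            rabi.shared_species_matrix(matrix)


class TestCompositionChisq:
    def test_df_formula_on_toy_matrix(self, toy_matrix):
        result = rabi.composition_chisq(toy_matrix)
        assert result.df == (6 - 1) * (3 - 1)

    def test_statistic_matches_direct_formula(self):
        table = pd.DataFrame([[10, 20], [30, 40], [50, 60]])
        observed = table.to_numpy(dtype=float)
        expected = (
            observed.sum(axis=1, keepdims=True)
            * observed.sum(axis=0, keepdims=True)
            / observed.sum()
        )
        by_hand = ((observed - expected) ** 2 / expected).sum()
        result = rabi.composition_chisq(table)
        assert result.statistic == pytest.approx(by_hand)
        assert result.df == 2

    def test_proportional_rows_give_zero_statistic(self):
        table = pd.DataFrame([[10, 20], [20, 40], [5, 10]])
        result = rabi.composition_chisq(table)
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_empty_rows_and_columns_dropped_with_warning(self):
        table = pd.DataFrame([[10, 20, 0], [0, 0, 0], [30, 40, 0]])
        with pytest.warns(AnalyticsWarning, match="dropping 1 empty row"):
            result = rabi.composition_chisq(table)
        assert result.df == 1

    def test_binary_cells_option(self, toy_matrix):
        result = rabi.composition_chisq(toy_matrix, cells="binary")
        assert result.df == (6 - 1) * (3 - 1)

    def test_low_expected_counts_warn(self):
        table = pd.DataFrame([[1, 2], [2, 1]])
        with pytest.warns(AnalyticsWarning, match="below 5"):
            rabi.composition_chisq(table)


def _scores(values):
    return [
        SpeciesScore(f"sp{i}", d, t, s) for i, (d, t, s) in enumerate(values)
    ]


class TestSubindexCorrelations:
    def test_identical_vectors_give_unit_correlation(self):
        scores = _scores([(1, 1, 0), (2, 2, 0), (4, 4, 1), (8, 8, 2)])
        corr = rabi.subindex_correlations(scores)
        assert corr[("dbs", "tbs")] == pytest.approx(1.0)

    def test_inverted_linear_ranking_gives_minus_one(self):
        scores = _scores([(1, 8, 0), (2, 7, 0), (3, 6, 0), (4, 5, 0)])
        corr = rabi.subindex_correlations(scores)
        assert corr[("dbs", "tbs")] == pytest.approx(-1.0)

    def test_matches_closed_form_pearson(self):
        rng = np.random.default_rng(11)
        values = [
            (int(rng.integers(0, 9)), int(rng.integers(0, 9)), int(rng.integers(0, 5)))
            for _ in range(30)
        ]
        corr = rabi.subindex_correlations(_scores(values))
        arr = np.array(values, dtype=float)
        cols = {"dbs": arr[:, 0], "tbs": arr[:, 1], "sbs": arr[:, 2]}
        for (a, b), r in corr.items():
            x, y = cols[a], cols[b]
            xd, yd = x - x.mean(), y - y.mean()
            by_hand = (xd * yd).sum() / np.sqrt((xd**2).sum() * (yd**2).sum())
            assert r == pytest.approx(by_hand)

    def test_zero_variance_pair_reported_undefined(self):
        scores = _scores([(1, 0, 0), (2, 0, 1), (4, 0, 2)])
        with pytest.warns(AnalyticsWarning, match="zero variance"):
            corr = rabi.subindex_correlations(scores)
        assert corr[("dbs", "tbs")] is None
        assert corr[("dbs", "sbs")] is not None

    def test_spearman_option(self):
        scores = _scores([(1, 1, 0), (2, 2, 0), (4, 4, 1), (8, 8, 2)])
        corr = rabi.subindex_correlations(scores, method="spearman")
        assert corr[("dbs", "tbs")] == pytest.approx(1.0)

    def test_requires_three_species(self):
        with pytest.raises(ValidationError, match="at least 3"):
            rabi.subindex_correlations(_scores([(1, 0, 0), (2, 0, 0)]))


class TestSIDistribution:
    def test_histogram_counts(self):
        scores = _scores([(1, 0, 0)] * 9 + [(2, 0, 0)] * 10 + [(4, 2, 4)] * 13)
        dist = rabi.si_distribution(scores)
        assert dist.counts.loc[1] == 9
        assert dist.counts.loc[2] == 10
        assert dist.counts.loc[10] == 13
        assert dist.counts.sum() == 32
        assert list(dist.counts.index) == list(range(1, 21))

    def test_single_species_median(self):
        dist = rabi.si_distribution(_scores([(2, 2, 2)]))
        assert dist.median == 6.0

    def test_median_matches_sorting_oracle(self):
        rng = np.random.default_rng(5)
        for n in (4, 5, 10, 13):
            values = [
                (int(rng.choice([1, 2, 4, 8])), int(rng.choice([0, 1, 2, 4, 8])),
                 int(rng.choice([0, 1, 2, 4])))
                for _ in range(n)
            ]
            dist = rabi.si_distribution(_scores(values))
            sis = sorted(d + t + s for d, t, s in values)
            if n % 2:
                expected = sis[n // 2]
            else:  # even count: arithmetic mean of the two middle values
                expected = (sis[n // 2 - 1] + sis[n // 2]) / 2
            assert dist.median == expected


def _assessment(site, ecozone, rabi_value, n_species=1):
    return rabi.SiteAssessment(
        site_id=site,
        ecozone=ecozone,
        species_present=tuple(f"x{i}" for i in range(n_species)),
        per_species_si=(1,) * n_species,
        rabi=rabi_value,
        priority_bin=rabi.priority_bin_label(rabi_value),
        high_priority=rabi_value > 20,
    )


class TestRabiSummary:
    def test_even_group_median_is_midpoint(self):
        values = [11, 14, 17, 47, 12, 20]
        assessments = [_assessment(f"s{i}", "EZ1", v) for i, v in enumerate(values)]
        summary = rabi.rabi_summary_by_ecozone(assessments)
        assert summary.loc["EZ1", "median"] == (14 + 17) / 2
        assert summary.loc["EZ1", "min"] == 11
        assert summary.loc["EZ1", "max"] == 47
        assert summary.loc["EZ1", "n_sites"] == 6

    def test_single_site_group(self):
        summary = rabi.rabi_summary_by_ecozone([_assessment("s", "EZ2", 9)])
        row = summary.loc["EZ2"]
        assert row["min"] == row["max"] == row["median"] == 9

    def test_matches_sorting_oracle(self):
        rng = np.random.default_rng(9)
        assessments = [
            _assessment(f"s{i}", f"EZ{int(rng.integers(1, 4))}", int(rng.integers(0, 64)))
            for i in range(25)
        ]
        summary = rabi.rabi_summary_by_ecozone(assessments)
        for ez in summary.index:
            group = sorted(a.rabi for a in assessments if a.ecozone == ez)
            n = len(group)
            expected = (
                group[n // 2] if n % 2 else (group[n // 2 - 1] + group[n // 2]) / 2
            )
            assert summary.loc[ez, "median"] == expected


class TestPriorityBins:
    def test_threshold_is_strict(self):
        report = rabi.priority_bins(
            [_assessment("a", "EZ1", 21), _assessment("b", "EZ1", 20)]
        )
        flags = dict(zip(report.ranked["site"], report.ranked["high_priority"]))
        assert flags == {"a": True, "b": False}

    def test_empty_input_gives_empty_report(self):
        report = rabi.priority_bins([])
        assert report.ranked.empty
        assert report.bin_counts.empty

    def test_bin_counts(self):
        values = [0, 5, 10, 11, 20, 21, 63]
        report = rabi.priority_bins(
            [_assessment(f"s{i}", "EZ1", v) for i, v in enumerate(values)]
        )
        assert report.bin_counts["0"] == 1
        assert report.bin_counts["1-10"] == 2
        assert report.bin_counts["11-20"] == 2
        assert report.bin_counts["21-30"] == 1
        assert report.bin_counts["61-70"] == 1
        assert report.bin_counts["31-40"] == 0

    def test_ranking_matches_brute_force_comparator(self):
        rng = np.random.default_rng(13)
        assessments = [
            _assessment(
                f"s{i:02d}", "EZ1", int(rng.integers(0, 30)), int(rng.integers(1, 6))
            )
            for i in range(10)
        ]
        report = rabi.priority_bins(assessments)
        expected = sorted(
            assessments, key=lambda a: (-a.rabi, -a.n_species, a.site_id)
        )
        assert list(report.ranked["site"]) == [a.site_id for a in expected]


class TestAccumulationCurve:
    def test_full_union_is_exact_for_any_seed(self, toy_matrix):
        for seed in (0, 1, 99):
            curve = rabi.accumulation_curve(toy_matrix, n_runs=20, seed=seed)
            assert curve.mean_richness[-1] == 6
            assert curve.sd_richness[-1] == 0

    def test_mean_curve_monotone(self, toy_matrix):
        curve = rabi.accumulation_curve(toy_matrix, n_runs=50, seed=4)
        assert (np.diff(curve.mean_richness) >= 0).all()

    def test_reproducible_under_fixed_seed(self, toy_matrix):
        a = rabi.accumulation_curve(toy_matrix, n_runs=30, seed=8)
        b = rabi.accumulation_curve(toy_matrix, n_runs=30, seed=8)
        assert np.array_equal(a.mean_richness, b.mean_richness)
        assert np.array_equal(a.sd_richness, b.sd_richness)

    def test_monte_carlo_matches_exhaustive_ordering_oracle(self):
        presence = np.array(
            [[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 0, 1]], dtype=bool
        )
        frame = pd.DataFrame(
            presence, index=["x", "y", "z"], columns=list("abcd")
        )
        matrix = OccurrenceMatrix(frame, {"x": "Z1", "y": "Z1", "z": "Z2"})
        exact_mean, _ = exact_accumulation(presence)
        curve = rabi.accumulation_curve(matrix, n_runs=1000, seed=0)
        se = curve.sd_richness / np.sqrt(curve.n_runs)
        assert (np.abs(curve.mean_richness - exact_mean) <= 3 * se + 1e-9).all()

    def test_first_site_mean_matches_average_richness(self, toy_matrix):
        curve = rabi.accumulation_curve(toy_matrix, n_runs=2000, seed=6)
        expected = toy_matrix.site_richness().mean()
        se = curve.sd_richness[0] / np.sqrt(curve.n_runs)
        assert abs(curve.mean_richness[0] - expected) <= 3 * se

    def test_rejects_zero_runs(self, toy_matrix):
        with pytest.raises(ValidationError, match="n_runs"):
            rabi.accumulation_curve(toy_matrix, n_runs=0)


class TestRounding:
    @pytest.mark.parametrize(
        "value, expected",
        [(40.625, 40.6), (21.875, 21.9), (38.8888, 38.9), (0.05, 0.1), (8.25, 8.3)],
    )
    def test_half_up_to_one_decimal(self, value, expected):
        assert rabi.round_half_up(value, 1) == expected
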