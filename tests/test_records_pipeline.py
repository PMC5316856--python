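"""Standardization rules and rate computation on first-record tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from alien_accrual import records_pipeline as rp

from conftest import make_db


class TestResolveYear:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("1873", 1873),
            ("<1980", 1980),  # open range resolves to its end year
            ("1950-1950", 1950),
        ],
    )
    def test_deterministic_cases(self, raw, expected, rng):
        assert rp.resolve_year(raw, rng) == expected

    def test_wide_range_dropped(self, rng):
        assert rp.resolve_year("1800-1850", rng) is None
        # width exactly 20 years is still resolvable
        assert rp.resolve_year("1900-1920", rng) is not None

    def test_range_resolves_inside(self, rng):
        for _ in range(50):
            y = rp.resolve_year("1940-1949", rng)
            assert 1940 <= y <= 1949

    def test_range_resolution_is_uniform(self, rng):
        draws = [rp.resolve_year("1940-1949", rng) for _ in range(10_000)]
        counts = np.bincount(np.array(draws) - 1940, minlength=10)
        assert stats.chisquare(counts).pvalue > 0.01

    @pytest.mark.parametrize("raw", ["1950-1940", "abc", "", "19??"])
    def test_malformed_rejected(self, raw, rng):
        with pytest.raises(rp.ValidationError):
            rp.resolve_year(raw, rng)


class TestDeduplicate:
    def test_priority_beats_year(self):
        db = make_db(
            [
                ("sp1", "rA", "EU", "t", "1900", "established", "s2", 2),
                ("sp1", "rA", "EU", "t", "1910", "established", "s1", 1),
            ]
        )
        out = rp.deduplicate(rp.resolve_years(db, 0))
        assert len(out) == 1
        assert out.records.loc[0, "year"] == 1910
        assert out.records.loc[0, "source_priority"] == 1

    def test_year_first_order_is_switchable(self):
        db = make_db(
            [
                ("sp1", "rA", "EU", "t", "1900", "established", "s2", 2),
                ("sp1", "rA", "EU", "t", "1910", "established", "s1", 1),
            ]
        )
        out = rp.deduplicate(rp.resolve_years(db, 0), prefer_priority=False)
        assert out.records.loc[0, "year"] == 1900

    def test_earliest_year_breaks_priority_ties(self):
        db = make_db(
            [
                ("sp1", "rA", "EU", "t", "1905", "established", "s1", 1),
                ("sp1", "rA", "EU", "t", "1900", "established", "s1", 1),
            ]
        )
        out = rp.deduplicate(rp.resolve_years(db, 0))
        assert out.records.loc[0, "year"] == 1900

    def test_idempotent(self, messy_db):
        once = rp.deduplicate(rp.resolve_years(messy_db, 7))
        twice = rp.deduplicate(once)
        pd.testing.assert_frame_equal(once.records, twice.records)

    def test_one_row_per_species_region(self, messy_db):
        out = rp.deduplicate(rp.resolve_years(messy_db, 7))
        assert not out.records.duplicated(["species_id", "region_id"]).any()


class TestFilter:
    def test_span_boundaries(self, messy_db):
        resolved = rp.resolve_years(messy_db, 0)
        out = rp.filter_records(resolved, min_year=1500, max_year=2000)
        years = out.records["year"]
        assert years.min() >= 1500 and years.max() <= 2000
        # the 1499 record and the 2003 casual are both gone
        assert "sp4" not in set(out.records["species_id"])
        assert "sp5" not in set(out.records["species_id"])

    def test_casuals_removed_only_when_flagged(self, messy_db):
        resolved = rp.resolve_years(messy_db, 0)
        keep = rp.filter_records(
            resolved, max_year=2014, established_only=False
        )
        assert "sp5" in set(keep.records["species_id"])

    def test_reversed_span_rejected(self, messy_db):
        with pytest.raises(ValueError):
            rp.filter_records(rp.resolve_years(messy_db, 0), min_year=2000, max_year=1500)


class TestContinentalFirstRecords:
    def test_min_year_within_continent(self):
        db = make_db(
            [
                ("sp1", "France", "EU", "t", "1900", "established", "s1", 1),
                ("sp1", "Spain", "EU", "t", "1850", "established", "s1", 1),
                ("sp1", "USA", "NA", "t", "1920", "established", "s1", 1),
            ]
        )
        out = rp.continental_first_records(rp.resolve_years(db, 0))
        got = dict(zip(out.records["continent_id"], out.records["year"]))
        assert got == {"EU": 1850, "NA": 1920}
        assert set(out.records["region_id"]) == {"EU", "NA"}

    def test_matches_groupby_min_oracle(self, synth_config):
        from alien_accrual import synth_data as sd

        db, _ = sd.generate_records(synth_config)
        resolved = rp.deduplicate(rp.resolve_years(db, 3))
        out = rp.continental_first_records(resolved)
        oracle = (
            resolved.records.groupby(["species_id", "continent_id"])["year"]
            .min()
            .reset_index()
        )
        merged = out.records.merge(
            oracle, on=["species_id", "continent_id"], suffixes=("", "_oracle")
        )
        assert len(merged) == len(out) == len(oracle)
        assert (merged["year"] == merged["year_oracle"]).all()

    def test_output_never_larger_than_input(self, synth_config):
        from alien_accrual import synth_data as sd

        db, _ = sd.generate_records(synth_config)
        resolved = rp.deduplicate(rp.resolve_years(db, 3))
        assert len(rp.continental_first_records(resolved)) <= len(resolved)


class TestRates:
    def test_hand_counted_bins(self):
        db = make_db(
            [
                ("s1", "r", "c", "t", "1801", "established", "s", 1),
                ("s2", "r", "c", "t", "1804", "established", "s", 1),
                ("s3", "r", "c", "t", "1805", "established", "s", 1),
            ]
        )
        series = rp.first_record_rates(
            rp.resolve_years(db, 0), bin_width=5, span=(1800, 1814)
        )
        assert list(series.counts) == [2, 1, 0]
        assert list(series.bin_start_years) == [1800, 1805, 1810]

    def test_empty_database_gives_zero_counts(self):
        db = make_db([])
        series = rp.first_record_rates(
            rp.resolve_years(db, 0), bin_width=1, span=(1500, 1509)
        )
        assert series.counts.sum() == 0 and len(series) == 10

    def test_counts_conserved(self, synth_config):
        from alien_accrual import synth_data as sd

        db, _ = sd.generate_records(synth_config)
        clean = rp.filter_records(
            rp.deduplicate(rp.resolve_years(db, 3)), max_year=2014
        )
        series = rp.first_record_rates(clean, bin_width=1, span=(1500, 2014))
        assert series.counts.sum() == len(clean)

    def test_partial_last_bin_flagged(self):
        db = make_db([("s1", "r", "c", "t", "2012", "established", "s", 1)])
        series = rp.first_record_rates(
            rp.resolve_years(db, 0), bin_width=5, span=(1500, 2012)
        )
        assert series.last_bin_partial  # [2010, 2015) sticks past 2012
        assert series.counts.sum() == 1
        full = rp.first_record_rates(
            rp.resolve_years(db, 0), bin_width=5, span=(1500, 2014)
        )
        assert not full.last_bin_partial  # 1500-2014 is exactly 103 bins

    def test_bad_bin_width(self, messy_db):
        with pytest.raises(ValueError):
            rp.first_record_rates(rp.resolve_years(messy_db, 0), bin_width=0)


class TestSmoothingAndCumulative:
    def test_constant_series_unchanged(self):
        s = rp.RateSeries(np.arange(1500, 1600), 1, np.full(100, 7.0))
        assert np.array_equal(rp.running_median(s, 25), np.full(100, 7.0))

    def test_single_spike_suppressed(self):
        counts = np.zeros(51)
        counts[25] = 100
        s = rp.RateSeries(1500 + 5 * np.arange(51), 5, counts)
        assert rp.running_median(s, 25)[25] == 0.0  # 5-bin window, 1 nonzero

    def test_matches_bruteforce_windowed_median(self, rng):
        counts = rng.integers(0, 50, size=80)
        s = rp.RateSeries(np.arange(1500, 1580), 1, counts)
        got = rp.running_median(s, 25)
        half = 12
        for i in range(80):
            h = min(half, i, 79 - i)
            assert got[i] == np.median(counts[i - h : i + h + 1])

    def test_window_must_divide(self):
        s = rp.RateSeries(1500 + 5 * np.arange(10), 5, np.zeros(10))
        with pytest.raises(ValueError):
            rp.running_median(s, 12)

    def test_cumulative_prefix_sums(self):
        s = rp.RateSeries(np.arange(1500, 1503), 1, [1, 0, 2])
        assert list(rp.cumulative_counts(s)) == [1, 1, 3]

    def test_cumulative_inverts_to_counts(self, rng):
        counts = rng.integers(0, 9, size=30)
        s = rp.RateSeries(np.arange(1500, 1530), 1, counts)
        cum = rp.cumulative_counts(s)
        assert np.array_equal(np.diff(np.concatenate([[0], cum])), counts)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    counts=st.lists(st.integers(0, 100), min_size=1, max_size=60),
    factor=st.integers(1, 6),
)
def test_rebinning_preserves_totals(counts, factor):
    s = rp.RateSeries(np.arange(1500, 1500 + len(counts)), 1, counts)
    coarse = rp.rebin(s, factor)
    assert coarse.counts.sum() == s.counts.sum()
    assert np.all(coarse.counts >= 0)


class TestAggregatedCounts:
    def test_round_trip(self, tmp_path):
        s = {
            "plants": rp.RateSeries(np.arange(1900, 1910), 1, np.arange(10), "plants"),
            "fishes": rp.RateSeries(np.arange(1950, 1955), 1, [1, 2, 0, 4, 5], "fishes"),
        }
        path = tmp_path / "counts.tsv"
        rp.write_aggregated_counts(s, path)
        back = rp.ingest_aggregated_counts(path)
        for lab in s:
            assert np.array_equal(back[lab].counts, np.asarray(s[lab].counts, float))
            assert np.array_equal(back[lab].bin_start_years, s[lab].bin_start_years)

    def test_five_year_series_round_trip_keeps_bin_width(self, tmp_path):
        s = rp.RateSeries(1800 + 5 * np.arange(8), 5, [0, 3, 0, 7, 1, 0, 0, 2], "m")
        path = tmp_path / "five.tsv"
        rp.write_aggregated_counts({"m": s}, path)
        back = rp.ingest_aggregated_counts(path)["m"]
        assert back.bin_width == 5
        np.testing.assert_array_equal(back.counts, s.counts)
        np.testing.assert_array_equal(back.bin_start_years, s.bin_start_years)

    def test_rebinned_annual_sums_five_year_windows(self, tmp_path):
        counts = np.arange(20)
        s = rp.RateSeries(np.arange(1900, 1920), 1, counts, "x")
        coarse = rp.rebin(s, 5)
        assert list(coarse.counts) == [10, 35, 60, 85]

    def test_malformed_row_reported(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("year\tlabel\tcount\n1900\tplants\t-3\n")
        with pytest.raises(rp.ValidationError):
            rp.ingest_aggregated_counts(path)


class TestHeadlineStats:
    def test_summary_statistics_on_known_series(self):
        years = np.arange(1991, 2001)
        counts = np.array([10, 10, 10, 10, 10, 50, 20, 20, 20, 10])
        s = rp.RateSeries(years, 1, counts)
        assert rp.total_records(s) == 170
        assert rp.total_between(s, 1996, 2000) == 120
        assert rp.share_between(s, 1996, 2000) == pytest.approx(100 * 120 / 170)
        assert rp.mean_annual_rate(s, 1991, 1995) == pytest.approx(10.0)
        assert rp.peak_bin(s) == (1996, 50)

    def test_mean_rate_requires_annual_bins(self):
        s = rp.RateSeries([1900, 1905], 5, [1, 2])
        with pytest.raises(ValueError):
            rp.mean_annual_rate(s, 1900, 1909)


class TestRecordDatabaseValidation:
    def test_region_in_two_continents_rejected(self):
        with pytest.raises(rp.ValidationError):
            make_db(
                [
                    ("s1", "rA", "EU", "t", "1900", "established", "s", 1),
                    ("s2", "rA", "NA", "t", "1901", "established", "s", 1),
                ]
            )
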