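"""Standardization and rate computation for alien-species first records.

A *first record* is the earliest documented year an established alien
species was recorded in a region; one species can contribute first
records in several regions.  Raw compilations carry year ranges
("1940-1949", "<1980"), duplicate entries from multiple sources, and
casual (non-established) occurrences.  This module implements the
standardization rules and turns the cleaned records into binned
first-record rate series, continental first records, running-median
smooths and cumulative counts.

Standardization rules
---------------------
* a closed year range of width <= 20 years is resolved to a uniformly
  random year inside it (avoiding artificial peaks at, e.g., midpoints);
  wider ranges are dropped;
* an open range "<Y" resolves to Y;
* duplicates of the same (species, region) keep the record from the
  best-quality source (lowest priority rank), then the earliest year;
* casual records are excluded from analysis, and the analysis span is
  restricted (by default 1500-2000; the upper cut avoids the
  detection/reporting lag that makes recent counts incomplete).

File formats are plain tab-separated text (see :func:`read_records` and
:func:`ingest_aggregated_counts`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "RecordDatabase",
    "RateSeries",
    "RECORD_COLUMNS",
    "parse_year_value",
    "resolve_year",
    "resolve_years",
    "deduplicate",
    "filter_records",
    "continental_first_records",
    "first_record_rates",
    "running_median",
    "cumulative_counts",
    "rebin",
    "read_records",
    "write_records",
    "ingest_aggregated_counts",
    "write_aggregated_counts",
    "total_records",
    "total_between",
    "share_between",
    "mean_annual_rate",
    "peak_bin",
]

#: maximum width (in years, last minus first) of a resolvable closed range
MAX_RANGE_WIDTH = 20

RECORD_COLUMNS = [
    "species_id",
    "region_id",
    "continent_id",
    "taxon_group",
    "year_raw",
    "status",
    "source_id",
    "source_priority",
]

_RANGE_RE = re.compile(r"^(\d+)-(\d+)$")
_OPEN_RE = re.compile(r"^<(\d+)$")
_SINGLE_RE = re.compile(r"^(\d+)$")


class ValidationError(ValueError):
    """Malformed record data."""


@dataclass
class RecordDatabase:
    """A table of raw first-record observations.

    ``records`` carries one row per (species, region, source)
    observation with the columns in :data:`RECORD_COLUMNS`; after
    :func:`resolve_years` an integer ``year`` column is present as well.
    Each region must belong to exactly one continent.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in RECORD_COLUMNS[:4] if c not in self.records.columns]
        if missing:
            raise ValidationError(f"records table missing columns {missing}")
        mapping = self.records.groupby("region_id")["continent_id"].nunique()
        overlapping = mapping[mapping > 1]
        if len(overlapping):
            raise ValidationError(
                "regions mapped to more than one continent: "
                f"{list(overlapping.index)}"
            )

    @property
    def region_to_continent(self) -> dict[str, str]:
        return dict(
            self.records.drop_duplicates("region_id")[
                ["region_id", "continent_id"]
            ].itertuples(index=False)
        )

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class RateSeries:
    """Binned first-record counts over contiguous half-open year bins.

    Bin ``i`` covers ``[bin_start_years[i], bin_start_years[i] +
    bin_width)`` and is labelled by its start year.  ``last_bin_partial``
    flags a final bin that extends past the requested span end.
    """

    bin_start_years: np.ndarray
    bin_width: int
    counts: np.ndarray
    label: str = ""
    last_bin_partial: bool = False

    def __post_init__(self) -> None:
        self.bin_start_years = np.asarray(self.bin_start_years, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if len(self.bin_start_years) != len(self.counts):
            raise ValueError("bin starts and counts differ in length")
        if len(self.bin_start_years) > 1:
            step = np.diff(self.bin_start_years)
            if not np.all(step == self.bin_width):
                raise ValueError("bins must be contiguous and non-overlapping")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.bin_start_years, "label": self.label, "count": self.counts}
        )


# ---------------------------------------------------------------------------
# year resolution
# ---------------------------------------------------------------------------


def parse_year_value(raw: str):
    """Parse a raw year field.

    Returns ``("single", y)``, ``("range", y1, y2)`` or ``("open", y)``.
    """
    raw = str(raw).strip()
    m = _SINGLE_RE.match(raw)
    if m:
        return ("single", int(m.group(1)))
    m = _OPEN_RE.match(raw)
    if m:
        return ("open", int(m.group(1)))
    m = _RANGE_RE.match(raw)
    if m:
        y1, y2 = int(m.group(1)), int(m.group(2))
        if y1 > y2:
            raise ValidationError(f"reversed year range '{raw}'")
        return ("range", y1, y2)
    raise ValidationError(f"unparseable year value '{raw}'")


def resolve_year(year_raw: str, rng: np.random.Generator):
    """Resolve one raw year field to an integer year, or None if dropped.

    A single year passes through; "<Y" resolves to Y; a closed range of
    width <= 20 years resolves to a uniform random year inside it
    (inclusive), and wider ranges are dropped.
    """
    parsed = parse_year_value(year_raw)
    if parsed[0] == "single":
        return parsed[1]
    if parsed[0] == "open":
        return parsed[1]
    _, y1, y2 = parsed
    if y2 - y1 > MAX_RANGE_WIDTH:
        return None
    return int(rng.integers(y1, y2 + 1))


def resolve_years(db: RecordDatabase, seed: int) -> RecordDatabase:
    """Resolve every record's year; drop records with over-wide ranges.

    The random selection within ranges is driven by a single seeded
    generator so the whole pipeline is reproducible.
    """
    rng = np.random.default_rng(seed)
    years = []
    keep = []
    for raw in db.records["year_raw"]:
        y = resolve_year(raw, rng)
        keep.append(y is not None)
        years.append(y if y is not None else -1)
    out = db.records.loc[keep].copy()
    out["year"] = np.asarray(years)[keep]
    return RecordDatabase(out.reset_index(drop=True))


# ---------------------------------------------------------------------------
# deduplication / filtering / aggregation
# ---------------------------------------------------------------------------


def _require_resolved(db: RecordDatabase) -> None:
    if "year" not in db.records.columns:
        raise ValidationError("years must be resolved first (resolve_years)")


def deduplicate(db: RecordDatabase, *, prefer_priority: bool = True) -> RecordDatabase:
    """Keep one record per (species, region).

    With ``prefer_priority`` (default) the record from the best source
    (lowest ``source_priority``) wins and ties fall to the earliest
    year; the alternative order prefers the earliest year first.
    Deterministic and idempotent.
    """
    _require_resolved(db)
    order = ["source_priority", "year"] if prefer_priority else ["year", "source_priority"]
    out = (
        db.records.sort_values(order + ["source_id"], kind="mergesort")
        .groupby(["species_id", "region_id"], as_index=False, sort=True)
        .first()
    )
    return RecordDatabase(out[list(db.records.columns)].reset_index(drop=True))


def filter_records(
    db: RecordDatabase,
    *,
    min_year: int = 1500,
    max_year: int = 2000,
    established_only: bool = True,
) -> RecordDatabase:
    """Restrict to the analysis span and (optionally) established species.

    Both bounds are inclusive.  ``max_year`` is configurable so display
    series can run to 2014 while trend analysis stops at 2000.
    """
    if min_year > max_year:
        raise ValueError("min_year must not exceed max_year")
    _require_resolved(db)
    mask = (db.records["year"] >= min_year) & (db.records["year"] <= max_year)
    if established_only:
        mask &= db.records["status"] == "established"
    return RecordDatabase(db.records.loc[mask].reset_index(drop=True))


def continental_first_records(db: RecordDatabase) -> RecordDatabase:
    """Collapse regional first records to continental first records.

    For each (species, continent) keeps the earliest resolved year over
    that species' regional records; this excludes within-continent
    secondary spread.  The region field is replaced by the continent.
    """
    _require_resolved(db)
    if db.records["continent_id"].isna().any():
        raise ValidationError("records with missing continent")
    out = (
        db.records.sort_values(["year", "source_priority", "source_id"], kind="mergesort")
        .groupby(["species_id", "continent_id"], as_index=False, sort=True)
        .first()
    )
    out["region_id"] = out["continent_id"]
    return RecordDatabase(out[list(db.records.columns)].reset_index(drop=True))


def first_record_rates(
    db: RecordDatabase,
    *,
    bin_width: int = 1,
    span: tuple[int, int] = (1500, 2014),
    label: str = "",
) -> RateSeries:
    """Count first records per half-open year bin over ``span``.

    Bins start at ``span[0]`` and cover every year up to and including
    ``span[1]``; a final bin reaching past the span end is retained and
    flagged partial.  Empty bins have count 0.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    _require_resolved(db)
    start, end = span
    if start > end:
        raise ValueError("span start after span end")
    n_bins = int(np.ceil((end - start + 1) / bin_width))
    starts = start + bin_width * np.arange(n_bins)
    years = db.records["year"].to_numpy()
    in_span = (years >= start) & (years <= end)
    idx = ((years[in_span] - start) // bin_width).astype(np.int64)
    counts = np.bincount(idx, minlength=n_bins)
    return RateSeries(
        bin_start_years=starts,
        bin_width=bin_width,
        counts=counts,
        label=label,
        last_bin_partial=(starts[-1] + bin_width - 1 > end),
    )


def running_median(series: RateSeries, window_years: int = 25) -> np.ndarray:
    """Centred running median over a window of ``window_years``.

    The window must be a positive multiple of the bin width.  At the
    series edges the window shrinks symmetrically to the available bins,
    so the output has the same length as the input.
    """
    if window_years <= 0 or window_years % series.bin_width != 0:
        raise ValueError(
            "window_years must be a positive multiple of bin_width "
            f"({series.bin_width}), got {window_years}"
        )
    w = window_years // series.bin_width
    half = (w - 1) // 2
    counts = series.counts
    n = len(counts)
    out = np.empty(n, dtype=float)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = np.median(counts[i - h : i + h + 1])
    return out


def cumulative_counts(series: RateSeries) -> np.ndarray:
    """Prefix sums of the binned counts (cumulative species records)."""
    return np.cumsum(series.counts)


def rebin(series: RateSeries, new_width: int) -> RateSeries:
    """Re-bin to a coarser width (a multiple of the current width).

    Counts are summed within each new bin; the total is preserved.
    """
    if new_width % series.bin_width != 0 or new_width <= 0:
        raise ValueError("new_width must be a positive multiple of bin_width")
    factor = new_width // series.bin_width
    n_new = int(np.ceil(len(series) / factor))
    padded = np.zeros(n_new * factor)
    padded[: len(series)] = series.counts
    counts = padded.reshape(n_new, factor).sum(axis=1)
    starts = series.bin_start_years[0] + new_width * np.arange(n_new)
    partial = series.last_bin_partial or (len(series) % factor != 0)
    return RateSeries(
        bin_start_years=starts,
        bin_width=new_width,
        counts=counts,
        label=series.label,
        last_bin_partial=partial,
    )


# ---------------------------------------------------------------------------
# i/o
# ---------------------------------------------------------------------------


def read_records(path) -> RecordDatabase:
    """Read a tab-separated first-record table.

    Expected header: ``species_id region_id continent_id taxon_group
    year_raw status source_id source_priority`` (year_raw like ``1873``,
    ``1940-1949`` or ``<1980``).
    """
    df = pd.read_csv(path, sep="\t", dtype={"year_raw": str})
    return RecordDatabase(df)


def write_records(db: RecordDatabase, path) -> None:
    db.records.to_csv(path, sep="\t", index=False)


def ingest_aggregated_counts(path) -> dict[str, RateSeries]:
    """Read pre-aggregated binned first-record counts.

    The file is tab-separated ``year  label  count`` with one row per
    non-empty bin, labelled by its start year (annual counts, the
    deposited-accession layout, are the common case).  The bin width is
    inferred per label as the greatest common divisor of the year gaps
    (1 for annual data, 5 for five-year series); bins missing from the
    file get count 0 inside each label's observed span.
    """
    df = pd.read_csv(path, sep="\t")
    expected = {"year", "label", "count"}
    if not expected.issubset(df.columns):
        raise ValidationError(
            f"aggregated-counts file needs columns {sorted(expected)}"
        )
    bad = df.index[
        df["year"].isna()
        | df["count"].isna()
        | (pd.to_numeric(df["count"], errors="coerce") < 0)
    ]
    if len(bad):
        raise ValidationError(f"malformed aggregated-count row {bad[0] + 2}")
    out: dict[str, RateSeries] = {}
    for lab, grp in df.groupby("label"):
        grp = grp.sort_values("year")
        years = grp["year"].astype(int).to_numpy()
        if len(np.unique(years)) != len(years):
            raise ValidationError(f"duplicate year for label '{lab}'")
        diffs = np.diff(years)
        width = int(np.gcd.reduce(diffs)) if len(diffs) else 1
        lo, hi = years.min(), years.max()
        starts = np.arange(lo, hi + 1, width)
        counts = np.zeros(len(starts))
        counts[(years - lo) // width] = grp["count"].to_numpy()
        out[str(lab)] = RateSeries(
            bin_start_years=starts,
            bin_width=width,
            counts=counts,
            label=str(lab),
        )
    return out


def write_aggregated_counts(series: dict[str, RateSeries] | list[RateSeries], path) -> None:
    """Write annual RateSeries to the ``year  label  count`` layout."""
    if isinstance(series, dict):
        series = list(series.values())
    frames = [s.to_frame() for s in series]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# headline summary statistics on an annual series
# ---------------------------------------------------------------------------


def total_records(series: RateSeries) -> float:
    """Total first records over the whole series."""
    return float(series.counts.sum())


def total_between(series: RateSeries, start: int, end: int) -> float:
    """Total first records with bin start in [start, end] inclusive."""
    mask = (series.bin_start_years >= start) & (series.bin_start_years <= end)
    return float(series.counts[mask].sum())


def share_between(series: RateSeries, start: int, end: int) -> float:
    """Percentage of all first records falling in [start, end]."""
    tot = total_records(series)
    if tot == 0:
        return float("nan")
    return 100.0 * total_between(series, start, end) / tot


def mean_annual_rate(series: RateSeries, start: int, end: int) -> float:
    """Mean first records per year over [start, end] inclusive.

    Requires an annual series (bin width 1).
    """
    if series.bin_width != 1:
        raise ValueError("mean annual rate needs an annual series")
    return total_between(series, start, end) / (end - start + 1)


def peak_bin(series: RateSeries) -> tuple[int, float]:
    """(bin start year, count) of the bin with the most first records."""
    i = int(np.argmax(series.counts))
    return int(series.bin_start_years[i]), float(series.counts[i])
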