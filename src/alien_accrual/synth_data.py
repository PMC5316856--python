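"""Synthetic first-record databases and driver series with known truth.

Downstream stages (standardization, trend selection, trade coupling,
simulation) are exercised against generated data whose generating
process is known exactly.  Each synthetic taxon draws its first-record
years from one of the five trend families treated as an unnormalized
intensity over the year span (inverse-CDF sampling on the discretized
per-year intensity), and the generator can inject the messiness of real
compilations: year ranges, casual records, and duplicate entries from a
second, lower-quality source.

Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .records_pipeline import RECORD_COLUMNS, RecordDatabase
from .trend_models import FAMILIES, evaluate_family

__all__ = [
    "ConfigError",
    "TaxonSpec",
    "SynthConfig",
    "TruthTable",
    "TradeSeries",
    "generate_records",
    "generate_trade_series",
    "generate_cpi_series",
    "generate_botanic_garden_series",
    "sample_years",
]

#: fraction of ranged records emitted as an open "<Y" range
OPEN_RANGE_SHARE = 0.2

#: closed-range widths (total years spanned) drawn uniformly
RANGE_WIDTHS = np.arange(2, 21)


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass
class TaxonSpec:
    """One synthetic taxon: its trend family, parameters and size."""

    name: str
    family: str
    params: tuple
    n_records: int

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown trend family '{self.family}'")
        if self.n_records < 0:
            raise ConfigError("n_records must be >= 0")


@dataclass
class SynthConfig:
    """Configuration for a synthetic first-record database."""

    taxa: list[TaxonSpec]
    regions: list[tuple[str, str]]  # (region_id, continent_id)
    year_span: tuple[int, int] = (1500, 2014)
    frac_ranged: float = 0.0
    frac_casual: float = 0.0
    frac_duplicate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_ranged", "frac_casual", "frac_duplicate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.year_span[0] >= self.year_span[1]:
            raise ConfigError("year_span start must precede end")
        if not self.regions:
            raise ConfigError("at least one region is required")


@dataclass
class TruthTable:
    """Generating process per taxon: family, parameters, expected counts."""

    entries: dict[str, dict] = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        serializable = {
            taxon: {
                "family": e["family"],
                "params": [float(p) for p in e["params"]],
                "n_records": int(e["n_records"]),
                "years": [int(y) for y in e["years"]],
                "expected_counts": [float(c) for c in e["expected_counts"]],
            }
            for taxon, e in self.entries.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(serializable, fh, sort_keys=True)


@dataclass
class TradeSeries:
    """Annual import values (current US$) for one country, with optional CPI."""

    country_id: str
    years: np.ndarray
    import_value: np.ndarray
    cpi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.import_value = np.asarray(self.import_value, dtype=float)
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(self.import_value <= 0):
            raise ValueError("import values must be positive")
        if self.cpi is not None:
            self.cpi = np.asarray(self.cpi, dtype=float)
            if len(self.cpi) != len(self.years):
                raise ValueError("cpi length must match years")


def sample_years(
    family: str,
    params,
    year_span: tuple[int, int],
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample first-record years from a trend family used as an intensity.

    The family is evaluated per year over the span (time measured from
    the year before the span start so x >= 1), clipped at zero,
    normalized, and sampled by inverse CDF.
    """
    start, end = year_span
    years = np.arange(start, end + 1)
    x = years - (start - 1)
    intensity = np.clip(evaluate_family(family, params, x), 0.0, None)
    mass = intensity.sum()
    if not np.isfinite(mass) or mass <= 0:
        raise ConfigError(
            f"family '{family}' with params {tuple(params)} has no positive "
            "mass over the year span"
        )
    cdf = np.cumsum(intensity / mass)
    cdf[-1] = 1.0
    idx = np.searchsorted(cdf, rng.random(n), side="right")
    return years[idx]


def _emit_range(year: int, span: tuple[int, int], rng: np.random.Generator) -> str:
    """Convert a true year into a raw ranged value containing it."""
    if rng.random() < OPEN_RANGE_SHARE:
        return f"<{year}"
    width = int(rng.choice(RANGE_WIDTHS))
    offset = int(rng.integers(0, width))
    y1 = max(year - offset, span[0])
    y2 = min(y1 + width - 1, span[1])
    y1 = min(y1, year)
    y2 = max(y2, year)
    return f"{y1}-{y2}"


def generate_records(config: SynthConfig) -> tuple[RecordDatabase, TruthTable]:
    """Generate a synthetic first-record database plus its truth table.

    Each taxon contributes exactly ``n_records`` base records with
    unique species, regions assigned uniformly, all from a priority-1
    source.  A ``frac_ranged`` share is re-expressed as year ranges, a
    ``frac_casual`` share is flagged casual, and a ``frac_duplicate``
    share is re-emitted under a second priority-2 source with the year
    shifted by 0-2 years — so deduplication must recover exactly the
    base (species, region) set.
    """
    rng = np.random.default_rng(config.seed)
    regions = np.array([r for r, _ in config.regions])
    continent_of = dict(config.regions)

    rows: list[dict] = []
    truth = TruthTable()
    start, end = config.year_span
    years_axis = np.arange(start, end + 1)
    for taxon in config.taxa:
        years = sample_years(
            taxon.family, taxon.params, config.year_span, taxon.n_records, rng
        )
        x = years_axis - (start - 1)
        intensity = np.clip(
            evaluate_family(taxon.family, taxon.params, x), 0.0, None
        )
        truth.entries[taxon.name] = {
            "family": taxon.family,
            "params": tuple(taxon.params),
            "n_records": taxon.n_records,
            "years": years_axis,
            "expected_counts": taxon.n_records * intensity / intensity.sum(),
        }
        reg_idx = rng.integers(0, len(regions), size=taxon.n_records)
        ranged = rng.random(taxon.n_records) < config.frac_ranged
        casual = rng.random(taxon.n_records) < config.frac_casual
        for i in range(taxon.n_records):
            year = int(years[i])
            region = str(regions[reg_idx[i]])
            raw = (
                _emit_range(year, config.year_span, rng)
                if ranged[i]
                else str(year)
            )
            rows.append(
                {
                    "species_id": f"{taxon.name}_sp{i:06d}",
                    "region_id": region,
                    "continent_id": continent_of[region],
                    "taxon_group": taxon.name,
                    "year_raw": raw,
                    "status": "casual" if casual[i] else "established",
                    "source_id": "src_primary",
                    "source_priority": 1,
                    "_true_year": year,
                }
            )

    n_base = len(rows)
    n_dup = int(round(config.frac_duplicate * n_base))
    if n_dup:
        dup_idx = rng.choice(n_base, size=n_dup, replace=False)
        offsets = rng.integers(0, 3, size=n_dup)
        for j, i in enumerate(dup_idx):
            base = rows[int(i)]
            dup_year = min(base["_true_year"] + int(offsets[j]), end)
            dup = dict(base)
            dup.update(
                year_raw=str(dup_year),
                source_id="src_secondary",
                source_priority=2,
            )
            rows.append(dup)

    df = pd.DataFrame(rows, columns=RECORD_COLUMNS + ["_true_year"])
    df = df.drop(columns="_true_year")
    return RecordDatabase(df), truth


def generate_trade_series(
    n_years: int,
    growth_rate: float,
    noise_sd: float,
    seed: int,
    *,
    start_year: int = 1870,
    base_value: float = 1e9,
    country_id: str = "GLOBAL",
) -> TradeSeries:
    """Exponentially growing annual import values with log-normal noise.

    ``value(t) = base * (1 + growth_rate)^t * exp(eps_t)`` with
    ``eps_t ~ N(0, noise_sd^2)``; with zero noise consecutive values
    satisfy ``value(t+1)/value(t) = 1 + growth_rate`` exactly.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if growth_rate <= -1:
        raise ValueError("growth_rate must exceed -1")
    log_final = np.log(base_value) + (n_years - 1) * np.log1p(growth_rate)
    if log_final > 700:
        raise OverflowError("growth_rate too large: import values overflow")
    rng = np.random.default_rng(seed)
    t = np.arange(n_years)
    log_values = np.log(base_value) + t * np.log1p(growth_rate)
    if noise_sd > 0:
        log_values = log_values + rng.normal(0.0, noise_sd, size=n_years)
    return TradeSeries(
        country_id=country_id,
        years=start_year + t,
        import_value=np.exp(log_values),
    )


def generate_cpi_series(
    n_years: int,
    inflation_rate: float,
    *,
    start_year: int = 1870,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic CPI index, 1.0 in the first year, compounding yearly."""
    t = np.arange(n_years)
    return start_year + t, np.power(1.0 + inflation_rate, t)


def generate_botanic_garden_series(
    n_years: int,
    total_gardens: int,
    growth_rate: float,
    *,
    start_year: int = 1500,
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative count of botanic-garden foundations, growing exponentially.

    Foundation intensity grows at ``growth_rate`` per year; the
    cumulative series is scaled to reach ``total_gardens`` at the end.
    Used as an introduction-pressure driver for plant-like scenarios.
    """
    t = np.arange(n_years)
    intensity = np.exp(growth_rate * t)
    cum = np.cumsum(intensity)
    cum = total_gardens * cum / cum[-1]
    return start_year + t, cum
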