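#!/usr/bin/env python
"""Generate the synthetic study data: first-record database + drivers.

Builds a global-scale synthetic compilation of first records (three
taxa with sigmoidal, exponential and hump-shaped generating trends,
plus the messiness of real compilations: year ranges, casual records,
duplicate sources), an exponentially growing import-value series with
CPI, and a botanic-garden foundation series.  Everything downstream
(02-06) reads from results/data/.

Run from the repository root:  python analysis/01_synthesize_data.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from alien_accrual import records_pipeline as rp
from alien_accrual import synth_data as sd

SEED = 20170214
OUT = Path("results/data")

CONFIG = sd.SynthConfig(
    taxa=[
        # vascular-plant-like: steep 19th-century rise, high plateau
        sd.TaxonSpec("plants", "sigmoidal", (120.0, 8.0, 360.0), 6000),
        # stowaway-invertebrate-like: accelerating with trade
        sd.TaxonSpec("insects", "exponential", (0.05, 0.016), 5000),
        # mammal/fish-like: mid-20th-century hump then decline
        sd.TaxonSpec("mammals", "weibull", (3000.0, 3.0, 520.0), 1200),
    ],
    regions=[(f"region_{i:03d}", f"continent_{i % 6}") for i in range(40)],
    year_span=(1500, 2014),
    frac_ranged=0.13,  # roughly the share of non-single-year entries
    frac_casual=0.17,
    frac_duplicate=0.2,
    seed=SEED,
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    db, truth = sd.generate_records(CONFIG)
    rp.write_records(db, OUT / "records.tsv")
    truth.to_yaml(OUT / "truth.yaml")

    trade = sd.generate_trade_series(
        131, growth_rate=0.05, noise_sd=0.15, seed=SEED + 1, start_year=1870
    )
    _, cpi = sd.generate_cpi_series(131, 0.025, start_year=1870)
    pd.DataFrame(
        {
            "country_id": trade.country_id,
            "year": trade.years,
            "import_usd": trade.import_value,
            "cpi": cpi,
        }
    ).to_csv(OUT / "trade.tsv", sep="\t", index=False)

    bg_years, bg_cum = sd.generate_botanic_garden_series(515, 1633, 0.012)
    pd.DataFrame({"year": bg_years, "cumulative_gardens": bg_cum}).to_csv(
        OUT / "botanic_gardens.tsv", sep="\t", index=False
    )

    n_base = sum(t.n_records for t in CONFIG.taxa)
    print(f"wrote {len(db)} raw rows ({n_base} base records) to {OUT}/records.tsv")
    print(f"trade series 1870-2000, {trade.import_value[-1]:.3g} US$ in final year")
    print("taxa and generating trends:")
    for t in CONFIG.taxa:
        print(f"  {t.name:8s} {t.family:12s} {t.n_records} records")


if __name__ == "__main__":
    main()
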