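#!/usr/bin/env python
"""Select the best temporal trend family per taxon by AIC.

Fits the five candidate families (linear, exponential, saturating,
sigmoidal, hump-shaped Weibull) to each taxon's 5-year first-record
rate series and to the global annual series, and reports the smallest-
AIC winner with its Delta-AIC table.  Also runs the family-recovery
calibration study quantifying how reliably the procedure identifies a
known generating family at 10%-of-peak noise.

Run after 02:  python analysis/03_trend_model_selection.py
"""

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from alien_accrual import records_pipeline as rp
from alien_accrual import studies
from alien_accrual import trend_models as tm

SEED = 20170216
OUT = Path("results/trends")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    series = rp.ingest_aggregated_counts("results/rates/taxa_5yr.tsv")
    series["all_annual"] = rp.ingest_aggregated_counts(
        "results/rates/annual_analysis.tsv"
    )["all"]

    truth = yaml.safe_load(Path("results/data/truth.yaml").read_text())
    report = {}
    print("AIC model selection (origin year 1499, 10 restarts):")
    for lab, s in sorted(series.items()):
        sel = tm.select_model(s, origin_year=1499, n_restarts=10, rng=rng)
        report[lab] = sel.to_dict()
        theta = ", ".join(f"{v:.4g}" for v in sel.fits[sel.winner].theta)
        gen = truth.get(lab, {}).get("family", "-")
        print(f"  {lab:12s} -> {sel.winner:12s} (generating: {gen}; theta = {theta})")
    with open(OUT / "selection.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=True)
    print(
        "note: a hump whose peak sits near the end of the window (mammals)\n"
        "is hard to tell from saturation at this sample size; the dedicated\n"
        "hump-recovery study below places the peak mid-series"
    )

    rec = studies.family_recovery_study(seed=SEED, n_replicates=100)
    pd.Series(rec).to_csv(OUT / "family_recovery.tsv", sep="\t", header=False)
    print("\nfamily recovery at 10%-of-peak noise (100 replicates each):")
    for fam, frac in rec.items():
        print(f"  {fam:12s} {frac:.2f}")
    print(
        "note: the saturating family is capped by its near-nesting Hill "
        "rival; see docs/methods.md"
    )


if __name__ == "__main__":
    main()
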