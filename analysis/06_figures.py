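#!/usr/bin/env python
"""Figures: rate series with running medians, trade curves, simulations.

Renders the analysis outputs as four figures under results/figures/:
per-taxon first-record rates with 25-year running medians, continental
rates, Michaelis--Menten curves over the (import value, rate) pairs,
and island richness trajectories by mainland community size.

Run after 02-05:  python analysis/06_figures.py
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from alien_accrual import records_pipeline as rp

OUT = Path("results/figures")


def rate_panels(path_counts, path_smooth, out_name, title):
    series = rp.ingest_aggregated_counts(path_counts)
    smooth = rp.ingest_aggregated_counts(path_smooth) if path_smooth else {}
    n = len(series)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 3), squeeze=False)
    for ax, (lab, s) in zip(axes.flat, sorted(series.items())):
        ax.plot(s.bin_start_years, s.counts, "o", ms=3, color="steelblue")
        if lab in smooth:
            sm = smooth[lab]
            ax.plot(sm.bin_start_years, sm.counts, "-", color="crimson", lw=2)
        ax.set_title(lab)
        ax.set_xlabel("year")
    axes.flat[0].set_ylabel("first records per bin")
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(OUT / out_name, dpi=120)
    plt.close(fig)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rate_panels(
        "results/rates/taxa_5yr.tsv",
        "results/rates/taxa_5yr_runmed25.tsv",
        "rates_by_taxon.png",
        "First-record rates per 5 years with 25-year running median",
    )
    rate_panels(
        "results/rates/continental_5yr.tsv",
        None,
        "rates_by_continent.png",
        "Continental first-record rates per 5 years",
    )

    fig, ax = plt.subplots(figsize=(5, 4))
    for path in sorted(Path("results/trade").glob("pairs_*.tsv")):
        df = pd.read_csv(path, sep="\t").sort_values("M")
        lab = path.stem.removeprefix("pairs_")
        pts = ax.plot(df["M"], df["R"], "o", ms=3, alpha=0.5, label=lab)
        ax.plot(df["M"], df["fitted"], "-", color=pts[0].get_color())
    ax.set_xscale("log")
    ax.set_xlabel("annual import value (US$)")
    ax.set_ylabel("first-record rate")
    ax.legend(fontsize=7)
    ax.set_title("Michaelis-Menten fits")
    fig.tight_layout()
    fig.savefig(OUT / "trade_vs_rates.png", dpi=120)
    plt.close(fig)

    df = pd.read_csv("results/simulation/richness_trajectories.tsv", sep="\t")
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = plt.cm.coolwarm_r
    sizes = sorted(df["m_species"].unique())
    for i, m in enumerate(sizes):
        col = colors(i / max(len(sizes) - 1, 1))
        for a, style in ((0, "-"), (10, "--")):
            sub = df[(df["m_species"] == m) & (df["allee"] == a)]
            ax.plot(sub["step"], sub["mean_richness"], style, color=col,
                    label=f"M={m}" if a == 0 else None)
    ax.set_xlabel("simulation step")
    ax.set_ylabel("mean island richness")
    ax.set_title("Neutral colonization (dashed: Allee a=10, T=1000)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(OUT / "island_accumulation.png", dpi=120)
    plt.close(fig)
    print(f"wrote 4 figures to {OUT}/")


if __name__ == "__main__":
    main()
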