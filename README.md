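# alien-accrual

Tools for analysing the accumulation of established alien species from
*first records* — the earliest documented year an alien species was
recorded in a region.  Built for invasion ecologists and
biostatisticians working with compiled first-record databases, the
package covers the full chain from raw, messy compilations to fitted
temporal trends and mechanistic simulation:

- **Record standardization** — resolve year ranges (`1940-1949`,
  `<1980`), drop over-wide ranges, deduplicate (species, region)
  entries by source quality, exclude casual occurrences, restrict the
  analysis span (default 1500–2000).
- **Rate series** — first records per 1- or 5-year bin, 25-year running
  medians, cumulative counts, continental first records (earliest
  record per species per continent, excluding within-continent spread).
- **Trend-model selection** — fit five candidate families of the rate
  `y` against time `x`, and pick the winner by smallest AIC
  (`n·ln(SSE/n) + 2(k+1)`):
  linear `y = a + bx`; exponential `y = a·e^{bx}`; saturating
  `y = a(1 − e^{−bx})`; sigmoidal `y = a·x^b/(x^b + c^b)`; and a
  hump-shaped scaled Weibull density to detect rates that rise then
  decline.
- **Trade coupling** — the saturating Michaelis–Menten relationship
  `R = R_max·M/(K + M)` between annual import values `M` and
  first-record rates `R`, with Pearson-correlation goodness of fit and
  optional CPI deflation.
- **Neutral colonization simulator** — a mainland community of `M`
  species with log-normal propagule abundances feeds an island: per
  step one propagule arrives with probability `P(t)` (species chosen by
  abundance), and establishes immediately or, with an Allee threshold
  `a`, only once more than `a` conspecific propagules arrive within a
  window of `T` steps.  Schedules of any shape (constant, linear,
  exponential, trade- or botanic-garden-driven) are standardized to a
  common propagule budget `Σ P(t)`.  A closed-form expected-richness
  oracle `E[S(t)] = Σ_i(1 − Π_{s≤t}(1 − P(s)p_i))` backs the simulator
  in tests.
- **Synthetic data with known truth** — first-record databases sampled
  from chosen trend families, with configurable fractions of ranged
  years, casuals and duplicate sources, plus exponentially growing
  import-value, CPI and botanic-garden series.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
synthetic global database (12,200 base records, three taxa emulating
plant-like, stowaway-insect-like and mammal-like dynamics):

```sh
python analysis/01_synthesize_data.py      # records + trade/CPI/garden series
python analysis/02_first_record_rates.py   # standardization + rate series
python analysis/03_trend_model_selection.py
python analysis/04_trade_coupling.py
python analysis/05_colonization_simulation.py
python analysis/06_figures.py
```

Selected output (seeds fixed in the scripts):

```
AIC model selection (origin year 1499, 10 restarts):
  all_annual   -> sigmoidal    (generating: -; theta = 978.2, 3.965, 911.5)
  insects      -> exponential  (generating: exponential; theta = 0.1039, 0.01565)
  mammals      -> saturating   (generating: weibull; theta = 23.4, 0.003209)
  plants       -> sigmoidal    (generating: sigmoidal; theta = 168.2, 7.433, 360)
```

The plant-like taxon recovers its generating sigmoid almost exactly
(true shape 8.0, half-saturation year 1859 = x 360), and the insect
taxon its exponential.  The mammal-like hump peaks so late in the
1800–1999 window that, at 1,200 records, its decline is within noise
and the more parsimonious saturating family wins — a detectability
limit discussed in `docs/methods.md`.

```
Michaelis-Menten fits against import values (non-deflated):
  all      Rmax=      66.3  K=  3.28e+09  r=0.766
  insects  Rmax=       214  K=   2.8e+10  r=0.932
  mammals  Rmax=      17.7  K=  1.08e+08  r=0.108
deflation robustness: r = 0.766 (nominal) vs 0.856 (CPI-deflated)
```

The stowaway-like taxon tracks import values tightly (r = 0.93), the
intentionally-introduced-like taxon does not (r = 0.11) — the contrast
the trade-coupling analysis is designed to expose.

```
accumulation on the island (20000 steps, budget 5000 propagules, 20 replicates):
  M_species  a=0 final a=10 final
        100      100.0       45.9
       1000      873.0        6.3
     100000     4696.2        0.0
```

Small mainland pools saturate the island within the run; large pools do
not, and an Allee threshold (a = 10 within T = 1,000 steps) delays
establishment most where the pool is large and each species' propagule
stream is thin.

A config-driven end-to-end run of the same stages is available as
`alien-accrual run --config configs/default.yaml`; every run writes a
manifest (config, derived stage seeds, package version) sufficient to
reproduce its outputs bit for bit.

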