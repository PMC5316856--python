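# Full-pipeline configuration for `alien-accrual run --config ...`.
# One global seed drives everything; per-stage child seeds are derived
# deterministically so disabling a stage never perturbs the others.
seed: 1
out_dir: results/run
stages: [synth, rates, fit, trade, simulate]

synth:
  taxa:
    - {name: plants,  family: sigmoidal,   params: [120.0, 8.0, 360.0],   n_records: 6000}
    - {name: insects, family: exponential, params: [0.05, 0.016],         n_records: 5000}
    - {name: mammals, family: weibull,     params: [3000.0, 3.0, 520.0],  n_records: 1200}
  regions: 40          # or an explicit list of [region_id, continent_id]
  n_continents: 6
  year_span: [1500, 2014]
  frac_ranged: 0.13    # share of records emitted as year ranges
  frac_casual: 0.17    # share flagged casual (excluded from analysis)
  frac_duplicate: 0.2  # share re-emitted under a second, lower-quality source
  trade: {n_years: 131, growth_rate: 0.05, noise_sd: 0.15, start_year: 1870}

records:
  span: [1500, 2014]       # display span
  max_analysis_year: 2000  # trend/trade analysis cut-off
  bin_width_taxa: 5

fit:
  origin_year: 1499        # x = year - origin; keeps x >= 1 from 1500 on
  n_restarts: 10

trade:
  deflate: false           # non-deflated import values by default

simulate:
  species: 1000
  meanlog: 2.0
  sdlog: 1.0
  shape: exponential
  steps: 20000
  budget: 5000
  allee: 0                 # 0 = basic model; >0 enables the Allee threshold
  window: 1000
  replicates: 20
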