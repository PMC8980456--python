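# Missing-data factorial: 4 x 2 x 2 x 2 x 4 x 2 = 256 parameter combinations
# (occasion-level MCAR at 20% or 50%), multiple imputation with 100
# imputations x 5 chained iterations before each analysis.
n_total: [20, 30, 60, 100]
a_level: [0.0, 2.0]
a_trend: [0.0, 0.2]
b_path: [0.0, 0.59]
rho: [0.0, 0.1, 0.5, 0.9]
missing_prop: [0.2, 0.5]
methods: [OLS, NW, FGLS, AR1]
n_reps: 1000
ci_draws: 10000
alpha: 0.05
seed: 1
mi:
  m: 100
  iterations: 5
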