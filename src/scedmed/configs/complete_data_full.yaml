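# Complete-data factorial: 4 x 2 x 2 x 2 x 4 = 128 parameter combinations,
# each analyzed by all four estimators.
n_total: [20, 30, 60, 100]
a_level: [0.0, 2.0]
a_trend: [0.0, 0.2]
b_path: [0.0, 0.59]
rho: [0.0, 0.1, 0.5, 0.9]
missing_prop: [0.0]
methods: [OLS, NW, FGLS, AR1]
n_reps: 1000
ci_draws: 10000
alpha: 0.05
seed: 1
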