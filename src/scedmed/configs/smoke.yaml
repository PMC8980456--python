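# Minimal smoke-test grid: one condition, 10 replications.
n_total: [20]
a_level: [2.0]
a_trend: [0.2]
b_path: [0.59]
rho: [0.0]
missing_prop: [0.0]
methods: [OLS]
n_reps: 10
ci_draws: 10000
alpha: 0.05
seed: 1
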