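# Synthetic growth experiment in the fitted breast-cancer case-study regime:
# four weekly waning doses, 5.8-day half-life, 8-hour cell cycle.
fc_ratio: 1.033
fm_ratio: 1.289
r_m: 1.1e-6
eff_c: 0.052
eff_m: 0.0
N: 200
horizon_days: 35.0
sample_interval_days: 3.5
n_doses: 4
dose_interval_days: 7.0
half_life_days: 5.8
noise_sigma: 0.05
seed: 1
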