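# Default calibration of the adaptive-response simulator (version 1).
#
# Produced by scripts/calibrate.py: a documented coordinate grid search that
# tunes the free mechanistic constants until the simulator + analysis
# pipeline jointly reproduce the published single-cell summary statistics
# (activation-delay statistics, basal copy-number statistics, survival
# fractions, gated subpopulation sizes and mutant-frequency ratios).
# These values are data, not code: edit via the YAML, not the source.

basal_means: {ada: 1.0, alkb: 0.25, alka: 2.6, aidb: 0.05}
dilution_rate: 0.0075

k_m: 0.0143
trigger_shape: 4.2
trigger_dose_exponent: 1.35
c321a_switch_rate: 0.5

induced_levels: {ada: 300.0, alkb: 100.0, alka: 250.0, aidb: 0.0}
tau_rise: 25.0
tau_lag: 8.0

fluct_reversion: 0.012
fluct_sd: 0.25

alpha_alka: 0.5
alpha_alkb: 0.5
alpha_mug: 1.0
mug_dose_exponent: 3.0
beta_off: 0.0
beta_on: 0.4

fork_rate: 0.02
mug_fork_rate: 0.00021
fork_resolution_off: 5.0e-4
fork_resolution_on: 0.3
hazard_scale: 2.2e-4
susceptibility_sd: 0.5
fate_probs: {lysed: 0.5, arrested: 0.3, escaped: 0.2}
lysed_intact_loss: 1.0
arrest_recovery: 0.35

r_0: 4.0e-3
r_mug: 2.0e-4
r_tox: 6.67e-5
mismatch_u_exponent: 0.5
p_fix: 0.01
p_rif: 0.1

fluor_scale: 1.0
fluor_background: 50.0
fluor_noise_sd: 2.0
maturation_delay: 0.0
frame_interval: 3.0
facs_log_sd: 0.10
constitutive_level: 200.0

count_limit: 8
spontaneous_active: {ada: 0.0, alkb: 0.0, alka: 0.05, aidb: 0.0}
spontaneous_level: 25.0

damage_grid_dt: 1.0
induced_repair_scale: 1.0
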