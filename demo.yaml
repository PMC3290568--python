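# Demo pipeline configuration: all inputs generated synthetically.
# Run with: standscan run --config demo.yaml
out_dir: results/demo
seed: 1
stages: [synth, stats, nulltest, ld, ihs, age, envcorr, dnds]

# synthetic locus
n: 40
L: 100000
theta_per_bp: 0.0008
rho_per_bp: 0.0004
conv_ratio_f: 2.0
tract_mean: 500.0

# neutrality test
null_model: constant
null_reps: 500

# planted sweep (drives the ihs and age stages)
sweep_frequency: 0.6
sweep_age_generations: 400.0
sweep_morgans_per_bp: 1.0e-7
max_cluster_gap: 20000

# calibration constants
generation_time_years: 25.0
split_time_years: 5.4e+6
mu_per_marker: 2.5e-8

# environmental-correlation scenario
env_populations: 50
env_countries: 21
env_effect_tau: 0.4
env_noise_sd: 0.05

# codon-selection scenario
codons: 300
tree_scale: 0.05
omega_true: 0.2
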