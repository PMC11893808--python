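# Synthetic incubation experiment at a small, quick-to-run scale.
# All parameters shown with their scientific meaning; omitted keys keep
# package defaults (full study design: GIA+RSA habitats, DOM/POM-HW/POM-NaOH
# pools, light+dark over 0-24 days, duplicate measurements, 6 blanks).
seed: 1
output_dir: cryodom_out

truth:
  n_formulae: 300          # CHNOSP formulae planted across both habitats
  noise_cv: 0.05           # multiplicative intensity noise between replicates
  mz_error_ppm_sd: 0.1     # Gaussian mass error (ppm)
  dropout_fraction: 0.02   # formulae missing from one replicate of one sample

engine:
  tolerance_ppm: 0.5       # assignment window around the neutral mass
  mdl_factor: 2.0          # peaks kept above mdl_factor x noise level
  noise_level: 1.0         # constant noise floor of the simulated spectra
  min_series_links: 1      # homologous-series partners required

rule:
  tolerance_rel: 0.10      # allowed backstep vs the running extremum
  min_net_change_rel: 0.20 # net change required to call a trend

ordination_restarts: 50
signal_threshold: 0.45
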