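# Demo configuration for `vectorenm run --config examples/demo.yml`.
# Mirrors RunConfig.demo(): a small synthetic world that exercises every
# pipeline stage in a few seconds.
output_dir: vectorenm_demo
seed: 1
nrows: 50
ncols: 50
cellsize: 0.2
xll: -100.0
yll: 10.0
n_layers: 7
correlation: 0.3
smooth_sigma: 3.0
n_gcm: 5
gcm_noise_sd: 0.3
n_occurrences: 250
n_regions: 3
thin_km: 22.0
thin_restarts: 10
split_fraction: 0.5
buffer_km: 200.0
r_max: 0.80
min_set_size: 2
candidate_sets:
  - [bio1, bio4, bio12, bio14, rh]
  - [bio1, bio4, bio6]
  - [bio6, bio15]
class_subsets: [lq]
rms: [1.0]
knots: 9
E: 0.05
alpha: 0.05
proc_iterations: 200
proc_resample: 0.5
n_boot: 5
cutoff_frac: 0.6
mop_reference_fraction: 0.1
mop_sample_cap: 1500
max_background: 10000
breakpoints: [0, 1, 5, 10, 20, 50, 100]
strong_only: true
flag_cutoff: 10.0
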