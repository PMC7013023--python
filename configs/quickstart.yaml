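# Quickstart experiment: the bundled four-system phantom study.
# Run with:  spectrc all --config configs/quickstart.yaml --out results_quickstart
seed: 1
profiles:
  - discovery_nm670_pro
  - symbia_intevo_bold
  - symbia_t16_system1
  - symbia_t16_system2
modes:
  - vendor_specific
  - vendor_neutral
n_repeats: 3
span_h: 74.7
n_projections: 128
reference_projection_time_s: 40.0
sphere_kBq_per_ml: 750.0
background_kBq_per_ml: 75.0
noise: true
calibration: measured
out_dir: results_quickstart
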