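# Demonstration pipeline configuration (defaults shown explicitly).
seed: 1
phantom_slices: 2
phantom_noise_sd: 2.0
phantom_bias_frac: 0.0
phantom_profile: step
exclude_first: true
r2_threshold: 0.66
t2_bounds_ms: [1.0, 1000.0]
depth_method: edt-2d-sagittal
roi_fraction: 0.6
equal_var: true
covariates: [age, sex, bmi]
family_size: 6
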