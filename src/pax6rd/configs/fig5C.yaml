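name: fig5C
variant: D
ic: noisy_homogeneous
rng_seed: 2
noise_amplitude: 0.05
shh_peak: 1.0
shh_form: linear
shh_direction: long
t_end: 500.0
snapshot_interval: 10.0
long_axis: 0.7
short_axis: 0.35
dx: 0.04
explant_shape: capsule
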