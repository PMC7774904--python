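name: fig4H
variant: C
ic: distal_high_prepattern
rng_seed: 1
noise_amplitude: 0.02
prepattern_axis: short
prepattern_profile: linear
t_end: 500.0
snapshot_interval: 10.0
long_axis: 0.7
short_axis: 0.35
dx: 0.04
explant_shape: capsule
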