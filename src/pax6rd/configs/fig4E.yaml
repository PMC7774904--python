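name: fig4E
variant: B
ic: noisy_homogeneous
rng_seed: 1
noise_amplitude: 0.05
t_end: 200.0
snapshot_interval: 4.0
length: 7.44
n_points: 192
boundary: zero_flux
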