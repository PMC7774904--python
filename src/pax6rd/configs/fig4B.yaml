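name: fig4B
variant: A
ic: fixed_pax6_source
rng_seed: 1
t_end: 100.0
snapshot_interval: 2.0
length: 1.2
n_points: 32
boundary: zero_flux
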