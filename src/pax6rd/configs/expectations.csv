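scenario,expected_outcome,max_correlation
fig4B,polarised,
fig4D,polarised,-0.5
fig4E,multipolar,-0.5
fig4H,polarised,
fig5C,polarised,
fig5D,polarised,
fig5E,polarised,
fig5G,polarised,
fig5I,uniform,
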