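# pepself 0.1.0 | seed=1
model	kingdom_average
complete	0.06350300459526334
middle	0.0681980003029844
nonanchor	0.06350300459526334
degenerate	0.06978740594859364
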