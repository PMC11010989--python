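configuration,dc_percent,p0_mpa,t_final_min_c,t_final_max_c
monolayer,15,0.433,46.53,46.59
monolayer,15,0.661,55.13,71.21
monolayer,30,0.433,88.00,88.11
monolayer,30,0.661,74.01,95.71
spheroid,15,0.433,40.55,40.6
spheroid,15,0.661,42.9,55.41
spheroid,30,0.433,57.88,57.96
spheroid,30,0.661,48.01,62.01
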