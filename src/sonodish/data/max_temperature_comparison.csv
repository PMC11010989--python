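configuration,dc_percent,p0_mpa,t_exp_c,t_num_c,error_pct
monolayer,15,0.433,49.0,46.6,5.0
monolayer,15,0.661,72.0,71.2,1.1
monolayer,30,0.433,74.5,88.1,15.0
spheroid,15,0.433,38.0,40.6,6.8
spheroid,30,0.433,54.5,58.0,6.4
spheroid,55,0.433,63.3,63.5,0.3
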