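layer,rho,C,k,c0,alpha_ref,BA,eta
Water,1000,4180,0.615,1520,2.8e-4,3.5,2
DMEM,1023,3800,0.13,1560,,,
Hydrogel,1060,3770,0.53,1560,,,
Cells,1066,3610,0.442,1423,0.57,,0.75
Glass,2500,880,1.1,4500,0.27,6.8,1.32
Petri Dish,1000,1350,0.165,2000,0.27,6.8,1.32
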