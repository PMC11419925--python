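variant,aa181,Tm_obs,Tm_sd
WT,VAL,56.55,0.06
V181A,ALA,61.56,0.04
E40S/V181A,ALA,65.21,0.10
PROSS1,VAL,60.01,0.07
PROSS2,VAL,56.19,0.36
E40S,VAL,58.40,
V158F,VAL,57.74,
A36R,VAL,54.33,
G86S,VAL,52.22,
H39A,VAL,49.43,
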