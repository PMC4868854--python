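# Synthetic example driver table (treatment means from the packaged
# factorial driver model; real per-treatment measurements are not
# distributed with this package).
treatment,ammonification_ng_N_g_h,respiration_mg_C_g_h
CTRL,100,1.3
N,180,1.3
W,90,1.495
NW,162,1.495
CO2,100,1.69
CO2N,180,1.69
CO2W,90,1.9435
CO2NW,162,1.9435
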