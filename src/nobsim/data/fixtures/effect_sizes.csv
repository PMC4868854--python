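# Observed main-effect sizes (% effect = 100*(elevated-ambient)/ambient)
# and split-plot ANOVA p-values for potential nitrite oxidation (PNO) and
# NOB abundances, Jasper Ridge Global Change Experiment, April 2005 and
# April 2006. Interaction rows carry p-values only.
year,response,factor,percent_effect,p_value
2005,PNO,CO2,25,0.06
2005,PNO,W,-16,0.01
2005,PNO,N,-3,0.58
2005,PNO,CO2:W,,0.39
2005,PNO,CO2:N,,0.17
2005,PNO,W:N,,0.29
2005,PNO,CO2:W:N,,0.04
2005,Nitrobacter abundance,CO2,94,0.11
2005,Nitrobacter abundance,W,-40,0.06
2005,Nitrobacter abundance,N,93,0.03
2005,Nitrobacter abundance,CO2:W,,0.62
2005,Nitrobacter abundance,CO2:N,,0.83
2005,Nitrobacter abundance,W:N,,0.14
2005,Nitrobacter abundance,CO2:W:N,,0.63
2005,Nitrospira abundance,CO2,-37,0.06
2005,Nitrospira abundance,W,50,0.06
2005,Nitrospira abundance,N,-3,0.65
2005,Nitrospira abundance,CO2:W,,0.62
2005,Nitrospira abundance,CO2:N,,0.72
2005,Nitrospira abundance,W:N,,0.66
2005,Nitrospira abundance,CO2:W:N,,0.28
2006,PNO,CO2,56,0.005
2006,PNO,W,-17,0.03
2006,PNO,N,-2,0.99
2006,PNO,CO2:W,,0.72
2006,PNO,CO2:N,,0.53
2006,PNO,W:N,,0.37
2006,PNO,CO2:W:N,,0.74
2006,Nitrobacter abundance,CO2,74,0.11
2006,Nitrobacter abundance,W,-35,0.04
2006,Nitrobacter abundance,N,67,0.80
2006,Nitrobacter abundance,CO2:W,,0.92
2006,Nitrobacter abundance,CO2:N,,0.96
2006,Nitrobacter abundance,W:N,,0.34
2006,Nitrobacter abundance,CO2:W:N,,0.10
2006,Nitrospira abundance,CO2,-11,0.82
2006,Nitrospira abundance,W,28,0.24
2006,Nitrospira abundance,N,22,0.03
2006,Nitrospira abundance,CO2:W,,0.94
2006,Nitrospira abundance,CO2:N,,0.82
2006,Nitrospira abundance,W:N,,0.51
2006,Nitrospira abundance,CO2:W:N,,0.37
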