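# Percentage of Nitrobacter-like NOB clone-library sequences assigned to
# the three main nxrA clusters per global-change treatment (mean ± SE;
# letters denote Fisher means-comparison groups). Cluster A is affiliated
# with N. hamburgensis (putatively mixotrophic).
treatment,cluster,percent,se,group
CTRL,A,0.0,0.0,a
CTRL,B,98.0,1.3,a
CTRL,C,0.0,0.0,a
N,A,0.0,0.0,a
N,B,96.0,4.0,a
N,C,0.0,0.0,a
W,A,30.8,11.4,b
W,B,52.6,12.0,bc
W,C,4.2,2.9,a
NW,A,0.0,0.0,a
NW,B,71.1,18.5,ab
NW,C,15.6,11.0,b
CO2,A,0.0,0.0,a
CO2,B,96.7,3.3,a
CO2,C,0.0,0.0,a
CO2N,A,4.2,3.4,a
CO2N,B,82.7,6.6,a
CO2N,C,0.0,0.0,a
CO2W,A,0.9,0.9,a
CO2W,B,98.1,1.0,a
CO2W,C,0.0,0.0,a
CO2NW,A,62.8,14.5,c
CO2NW,B,34.7,14.8,c
CO2NW,C,1.0,1.0,a
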