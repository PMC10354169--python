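parameter,units,agricultural_mean,agricultural_se,forest_mean,forest_se
soc,mg C g-1 dry soil,8.864,0.213,45.641,2.365
mbc,ug C g-1 dry soil,45.15,3.894,294.3,27.64
total_plfa,nmol C g-1 dry soil,145.3,44.77,1975,215.3
respiration,ng C h-1 g-1 dry soil,119.9,2.482,975.2,68.00
growth,ng C h-1 g-1 dry soil,87.98,8.884,569.9,86.7
cue,dimensionless,0.420,0.027,0.364,0.026
label_respiration,ng C h-1 g-1 dry soil,23.11,0.077,101.1,111.6
label_mbc,ng C h-1 g-1 dry soil,58.29,1.471,229.4,33.38
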