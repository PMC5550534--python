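species_id,academic_name,common_name,state,n,mean,sd,conc_min,conc_max,median,p95,portion_mean,portion_sd
m_magellanicus,Macruronus magellanicus,hoki,raw,12,0.105,0.015,0.075,0.13,0.11,0.12,0.175,0.015
m_magellanicus,Macruronus magellanicus,hoki,fried,12,0.109,0.015,0.052,0.139,0.11,0.13,0.15,0.014
g_chalcogrammus,Gadus chalcogrammus,pollock,raw,12,0.018,0.006,0.01,0.028,0.02,0.03,0.166,0.02
g_chalcogrammus,Gadus chalcogrammus,pollock,fried,12,0.023,0.009,0.009,0.033,0.02,0.03,0.147,0.019
g_morhua,Gadus morhua,cod,raw,12,0.049,0.006,0.041,0.06,0.05,0.06,0.189,0.025
g_morhua,Gadus morhua,cod,fried,12,0.06,0.009,0.049,0.072,0.06,0.07,0.173,0.026
p_virens,Pollachius virens,coalfish,raw,12,0.041,0.005,0.027,0.046,0.04,0.05,0.189,0.023
p_virens,Pollachius virens,coalfish,fried,12,0.055,0.019,0.035,0.09,0.05,0.09,0.166,0.021
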