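label,biomass,protein_g_per_L,surface_tension_mN_per_m,clear_zone_cm
50,0.52,2.83,45.05,4.65
75,0.5,2.47,44.04,4.5
100,0.48,3.28,44.15,6.1
125,0.4,3.37,42.89,5.75
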