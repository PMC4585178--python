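label,biomass,protein_g_per_L,surface_tension_mN_per_m,clear_zone_cm
0,0.06,0.0,48.0,0.0
5,0.35,2.62,44.07,5.65
10,0.46,3.88,45.22,3.75
15,0.56,3.83,42.27,4.5
20,0.6,3.97,37.68,4.7
30,0.68,4.01,34.57,0.0
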