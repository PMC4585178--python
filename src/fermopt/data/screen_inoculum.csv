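label,biomass,protein_g_per_L,surface_tension_mN_per_m,clear_zone_cm
4,0.6,2.71,38.25,7.0
6,0.61,2.58,36.3,6.0
8,0.54,2.47,38.65,6.0
10,0.46,2.13,38.98,6.15
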