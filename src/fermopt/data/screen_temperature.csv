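label,biomass,protein_g_per_L,surface_tension_mN_per_m,clear_zone_cm
25,0.72,2.72,45.0,4.25
28,0.62,2.9,34.6,6.5
31,0.65,2.47,41.3,5.75
34,0.55,1.82,47.0,4.25
37,0.55,2.0,51.1,5.0
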