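label,biomass,protein_g_per_L,surface_tension_mN_per_m,clear_zone_cm
blank,0.85,4.23,35.28,5.5
maltose,1.13,5.66,42.44,6.55
lactose,0.86,4.3,32.4,6.48
sucrose,0.35,1.75,39.08,0.0
xylose,1.1,5.49,42.95,7.3
glucose,0.4,2.0,40.98,0.0
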