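label,biomass,protein_g_per_L,surface_tension_mN_per_m,clear_zone_cm
peptone,0.47,3.72,36.43,6.0
beef_extract,0.38,3.19,39.4,5.44
yeast_extract,0.6,3.82,31.0,5.55
soybean_meal,0.47,6.55,31.09,3.0
corn_meal,0.14,0.13,39.44,0.0
(NH4)2SO4,0.05,0.16,34.33,0.0
NH4NO3,0.05,0.14,34.94,0.0
NH4Cl,0.05,0.04,43.14,0.0
NaNO3,0.09,0.42,46.3,0.0
urea,0.1,0.39,32.47,0.0
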