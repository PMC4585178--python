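label,biomass,protein_g_per_L,surface_tension_mN_per_m,clear_zone_cm
blank,0.59,3.71,37.55,6.0
ZnSO4,0.33,2.87,32.55,5.25
Na2HPO4,0.66,3.7,29.18,5.95
CaCl2,0.6,3.81,36.0,5.45
BaCl2,0.6,3.61,41.85,5.4
CuSO4,0.32,2.76,32.43,4.5
MgSO4,0.59,3.47,33.98,4.25
MnSO4,0.62,3.49,34.16,5.55
FeCl3,0.6,3.37,33.17,5.5
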