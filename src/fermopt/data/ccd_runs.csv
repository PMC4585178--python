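run,x1,x2,x3,biomass,protein_g_per_L,surface_tension_mN_per_m,clear_zone_cm,response
1,0,0,0,0.59,4.39,37.81,4.3,0.0268
2,0,0,-1.682,0.35,2.65,49.36,4.5,0.0161
3,1,1,1,0.86,5.29,40.72,5.5,0.0374
4,1,-1,-1,0.29,2.29,45.69,4.0,0.0133
5,-1,1,-1,0.54,4.37,50.51,6.0,0.0304
6,1,1,-1,0.72,5.09,47.57,7.0,0.0409
7,0,-1.682,0,0.16,1.32,48.0,0.0,-0.0134
8,-1,-1,-1,0.28,2.02,48.35,0.0,-0.0103
9,0,0,0,0.6,4.11,41.96,5.0,0.0283
10,-1,1,1,0.85,5.33,38.25,7.0,0.0466
11,1.682,0,0,0.59,4.16,43.38,4.5,0.0251
12,1,-1,1,0.37,2.85,41.47,4.5,0.0199
13,0,0,0,0.62,4.33,42.89,5.5,0.0315
14,0,1.682,0,1.0,6.25,41.36,6.5,0.0467
15,0,0,0,0.59,4.5,38.0,4.5,0.0289
16,0,0,0,0.59,4.5,38.0,4.5,0.0289
17,-1,-1,1,0.36,2.84,43.11,5.0,0.0219
18,0,0,1.682,0.67,4.38,37.85,6.0,0.0368
19,-1.682,0,0,0.59,4.4,40.36,5.0,0.0296
20,0,0,0,0.59,4.5,38.0,4.5,0.0289
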