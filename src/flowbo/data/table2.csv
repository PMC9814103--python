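entry,mixer,equiv,tfoh_mol_pct,temp_c,conc_m,flow_ml_min,residence_min,yield_pct,note
1,comet_x,2.0,1.0,60,0.05,0.05,24,14,
2,comet_x,3.0,0.5,40,0.01,0.2,6,35,
3,beta_type,1.0,2.0,60,0.01,0.1,13.5,11,
4,beta_type,3.0,0.5,20,0.1,0.1,13.5,52,
5,t_shaped,1.0,2.0,40,0.05,0.05,16,4,
6,t_shaped,2.0,1.0,20,0.1,0.2,4,29,
7,comet_x,3.0,0.29,25,0.14,0.048,25,20,
8,beta_type,3.5,0.25,15,0.035,0.087,15.5,58,
9,t_shaped,3.5,0.98,30,0.15,0.022,36,19,
10,comet_x,3.4,0.37,35,0.056,0.13,9,10,
11,beta_type,2.4,0.34,15,0.019,0.041,33,40,
12,t_shaped,2.4,0.73,15,0.011,0.060,13,19,printed residence 13'
13,beta_type,3.2,0.25,15,0.068,0.062,22,20,
14,beta_type,3.5,0.53,15,0.067,0.097,14,43,
15,beta_type,3.2,0.35,30,0.044,0.068,20,69,isolated 66
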