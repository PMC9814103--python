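entry,mixer,equiv,tfoh_mol_pct,temp_c,conc_m,flow_ml_min,residence_min,yield_pct,note
1,comet_x,2.0,1.0,60,0.05,0.05,24,68,
2,comet_x,3.0,0.5,40,0.01,0.2,6,73,
3,beta_type,1.0,2.0,60,0.01,0.1,13.5,42,
4,beta_type,3.0,0.5,20,0.1,0.1,13.5,28,
5,t_shaped,1.0,2.0,40,0.05,0.05,16,55,
6,t_shaped,2.0,1.0,20,0.1,0.2,4,75,
7,t_shaped,2.0,1.0,20,0.1,0.15,5.5,81,
8,comet_x,2.3,1.0,55,0.039,0.04,30,77,
9,beta_type,1.1,2.4,85,0.15,0.1,13.5,40,
10,t_shaped,1.3,1.2,15,0.11,0.15,5.5,78,
11,t_shaped,2.1,1.1,30,0.061,0.15,5.5,76,
12,comet_x,2.8,1.0,50,0.014,0.11,11,79,
13,comet_x,3.4,1.3,55,0.01,0.032,37.5,88,
14,comet_x,2.2,1.7,15,0.1,0.014,85.5,44,
15,comet_x,3.0,1.5,25,0.015,0.08,15,96,isolated 93
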