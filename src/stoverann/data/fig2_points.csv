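run_id,k_IA,C_IA_mol_L,T_C,t_min,R_SL_frac,E_FPU_g,C_Glc_g_L,C_Phe_g_L
hcl_0.05,1,0.05,160,60,0.10,20,22.8,1.13
hcl_0.10,1,0.10,160,60,0.10,20,,1.64
hcl_0.20,1,0.20,160,60,0.10,20,,
hcl_0.40,1,0.40,160,60,0.10,20,,
hcl_0.60,1,0.60,160,60,0.10,20,,
h2so4_0.05,2,0.05,160,60,0.10,20,25.6,1.34
h2so4_0.10,2,0.10,160,60,0.10,20,,
h2so4_0.20,2,0.20,160,60,0.10,20,,
h2so4_0.40,2,0.40,160,60,0.10,20,,
h2so4_0.60,2,0.60,160,60,0.10,20,,
h3po4_0.05,3,0.05,160,60,0.10,20,20.3,1.97
h3po4_0.10,3,0.10,160,60,0.10,20,,
h3po4_0.20,3,0.20,160,60,0.10,20,,
h3po4_0.40,3,0.40,160,60,0.10,20,,
h3po4_0.60,3,0.60,160,60,0.10,20,,
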