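gene,variant_id,chromosome,effect_allele,minor_allele,maf_control,maf_case,p_hwe,odds_ratio,ci_low,ci_high,p_value,p_fdr
TNFRSF1B,rs1061624,1,A,G,0.51,0.47,0.088,1.32,1.04,1.69,0.022,0.049
LEPR,rs1137100,1,G,G,0.21,0.29,0.294,1.53,1.17,2.01,0.002,0.007
CRP,rs2794521,1,C,C,0.21,0.29,0.546,1.51,1.16,1.97,0.002,0.007
SEC16B,rs10913469,1,T,C,0.23,0.17,0.197,1.76,1.30,2.38,2.29e-4,1.14e-3
ADCY3,rs17799872,2,A,A,0.08,0.13,0.498,1.57,1.08,2.29,0.018,0.041
GHRL,rs696217,3,A,A,0.08,0.14,0.479,1.89,1.33,2.68,3.67e-4,1.63e-3
NPY2R,rs1047214,4,C,T,0.52,0.38,0.067,2.12,1.64,2.74,7.47e-9,1.50e-7
CDKAL1,rs9295474,6,C,G,0.36,0.16,0.827,2.63,1.97,3.50,4.47e-11,1.79e-9
LPL,rs295,8,C,C,0.25,0.35,0.789,1.46,1.16,1.85,0.002,0.006
SIRT1,rs3818292,10,G,G,0.21,0.28,0.364,1.39,1.07,1.81,0.014,0.034
ADRA2A,rs1800544,10,G,G,0.14,0.25,0.145,2.18,1.62,2.95,2.98e-7,3.98e-6
BDNF,rs11030107,11,G,G,0.13,0.23,0.515,1.90,1.38,2.61,7.49e-5,4.99e-4
CHRM4,rs2067482,11,C,T,0.08,0.04,1,2.29,1.34,3.90,0.002,0.007
CHRM1,rs2067477,11,A,A,0.04,0.12,1,3.08,1.91,4.97,3.77e-6,3.01e-5
HTR3A,rs1062613,11,T,T,0.19,0.30,0.068,2.01,1.50,2.69,2.30e-6,2.30e-5
ZBTB42,rs3803300,14,A,A,0.03,0.07,1,2.34,1.32,4.16,0.004,0.010
FTO,rs9939609,16,A,A,0.18,0.27,0.607,1.72,1.30,2.27,1.52e-4,8.66e-4
GIPR,rs2302382,19,C,A,0.23,0.16,0.391,1.55,1.16,2.08,0.003,0.010
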