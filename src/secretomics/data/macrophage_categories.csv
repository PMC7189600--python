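category,miRNA,direction,weight_ev,weight_iev,regulation,targets
M1_phenotype,miR-29b-3p,M1_suppressing,0.07,0.27,up_ifng,
M1_phenotype,miR-145-5p,M1_promoting,1.84,0.79,down_ifng,
M1_phenotype,miR-27a-3p,M1_promoting,0.90,0.33,down_ifng,
M1_phenotype,miR-27b-3p,M1_promoting,0.32,0.18,down_ifng,
M1_phenotype,miR-130a-3p,M1_promoting,0.57,0.78,,
M1_phenotype,miR-26a-5p,M1_suppressing,0.64,1.06,,
M1_phenotype,miR-26b-5p,M1_suppressing,0.15,0.20,,
M2_phenotype,miR-24-3p,M2_promoting,19.63,18.47,,
M2_phenotype,miR-146b-5p,M2_promoting,0.04,0.51,up_ifng,
M2_phenotype,miR-181a-5p,M2_promoting,0.11,0.18,,
M2_phenotype,miR-34a-5p,M2_promoting,0.70,0.93,,
M2_phenotype,miR-222-3p,M2_promoting,5.74,7.61,,
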