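category,miRNA,direction,weight_ev,weight_iev,regulation,targets
cartilage_protective,hsa-miR-21-5p,protective,5.13,6.73,,GAS5;GDF5
cartilage_protective,hsa-miR-222-3p,protective,5.74,7.61,,MMP13;HDAC4
cartilage_protective,hsa-miR-138-5p,protective,0.19,0.21,,SP1;HIF-2A
cartilage_protective,hsa-miR-24-3p,protective,19.63,18.47,,P16INK4A
cartilage_protective,hsa-miR-210-3p,protective,0.23,0.56,up_ifng,DR6;NF-KB
cartilage_protective,hsa-miR-26a-5p,protective,0.64,1.06,,NF-KB;CD200;COL10A1;COL9A1;CTGF
cartilage_protective,hsa-miR-130a-3p,protective,0.57,0.78,,TNF-A
cartilage_protective,hsa-miR-149-5p,protective,0.13,0.02,down_ifng,TNFA;IL-1;IL-6
cartilage_protective,hsa-miR-199a-3p,protective,0.92,0.97,,COX-2
cartilage_protective,hsa-miR-320-3p,protective,0.00,0.53,only_ievs,MMP13
cartilage_destructive,hsa-miR-21-5p,destructive,5.13,6.73,,GDF5
cartilage_destructive,hsa-miR-145-5p,destructive,1.84,0.79,down_ifng,SOX9;SMAD3
cartilage_destructive,hsa-miR-16-5p,destructive,0.40,0.44,,SMAD3
cartilage_destructive,hsa-miR-193b-5p,destructive,5.00,5.56,,TGF-B2;TGF-BR3;SOX9;COL2
cartilage_destructive,hsa-miR-29b-3p,destructive,0.07,0.27,,SMAD;NF-KB;WNT
cartilage_destructive,hsa-miR-34a-5p,destructive,0.70,0.93,,COL2A1;INOS
cartilage_destructive,hsa-miR-483-5p,destructive,0.12,0.11,,BMP7;TGFB;IL-1B;MMP13
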