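region	network	n_vertices	merge_into
Frontal_Sup_Medial_L	DMN	12	
Frontal_Sup_Medial_R	DMN	12	
Frontal_Med_Orb_L	DMN	12	
Frontal_Med_Orb_R	DMN	12	
Cingulate_Ant_L	DMN	12	
Cingulate_Ant_R	DMN	12	
Cingulate_Post_L	DMN	12	
Cingulate_Post_R	DMN	12	
Precuneus_L	DMN	12	
Precuneus_R	DMN	12	
Angular_L	DMN	12	
Angular_R	DMN	12	
Temporal_Mid_L	DMN	12	
Temporal_Mid_R	DMN	12	
Temporal_Pole_Sup_L	DMN	12	
Temporal_Pole_Sup_R	DMN	12	
Frontal_Sup_L	DMN	12	
Frontal_Sup_R	DMN	12	
Rectus_L	DMN	12	
Rectus_R	DMN	12	
Parietal_Sup_L	DAN	12	
Parietal_Sup_R	DAN	12	
Parietal_Inf_L	DAN	12	
Parietal_Inf_R	DAN	12	
Frontal_Mid_L	DAN	12	
Frontal_Mid_R	DAN	12	
Temporal_Inf_L	DAN	12	
Temporal_Inf_R	DAN	12	
Occipital_Sup_L	DAN	12	
Occipital_Sup_R	DAN	12	
Precentral_L	SMN	12	
Precentral_R	SMN	12	
Postcentral_L	SMN	12	
Postcentral_R	SMN	12	
Paracentral_Lobule_L	SMN	12	
Paracentral_Lobule_R	SMN	12	
Supp_Motor_Area_L	SMN	12	
Supp_Motor_Area_R	SMN	12	
Rolandic_Oper_L	SMN	12	
Rolandic_Oper_R	SMN	12	
Heschl_L	SMN	12	
Heschl_R	SMN	12	
Frontal_Inf_Oper_L	VAN	12	
Frontal_Inf_Oper_R	VAN	12	
Frontal_Inf_Tri_L	VAN	12	
Frontal_Inf_Tri_R	VAN	12	
SupraMarginal_L	VAN	12	
SupraMarginal_R	VAN	12	
Insula_L	VAN	12	
Insula_R	VAN	12	
Cingulate_Mid_L	VAN	12	
Cingulate_Mid_R	VAN	12	
Frontal_Sup_Orb_L	FPN	12	
Frontal_Sup_Orb_R	FPN	12	
Frontal_Mid_Orb_L	FPN	12	
Frontal_Mid_Orb_R	FPN	12	
Frontal_Inf_Orb_L	FPN	12	
Frontal_Inf_Orb_R	FPN	12	
OFCant_L	FPN	12	
OFCant_R	FPN	12	
OFCmed_L	FPN	12	
OFCmed_R	FPN	12	
OFClat_L	FPN	12	
OFClat_R	FPN	12	
Calcarine_L	VN	12	
Calcarine_R	VN	12	
Cuneus_L	VN	12	
Cuneus_R	VN	12	
Lingual_L	VN	12	
Lingual_R	VN	12	
Occipital_Mid_L	VN	12	
Occipital_Mid_R	VN	12	
Occipital_Inf_L	VN	12	
Occipital_Inf_R	VN	12	
Fusiform_L	VN	12	
Fusiform_R	VN	12	
Hippocampus_L	LN	12	
Hippocampus_R	LN	12	
ParaHippocampal_L	LN	12	
ParaHippocampal_R	LN	12	
Amygdala_L	LN	12	
Amygdala_R	LN	12	
Temporal_Pole_Mid_L	LN	12	
Temporal_Pole_Mid_R	LN	12	
Temporal_Sup_L	LN	12	
Temporal_Sup_R	LN	12	
OFCpost_L	LN	12	
OFCpost_R	LN	12	
Caudate_L	SC	12	
Caudate_R	SC	12	
Putamen_L	SC	12	
Putamen_R	SC	12	
Pallidum_L	SC	12	
Pallidum_R	SC	12	
N_Acc_L	SC	12	
N_Acc_R	SC	12	
SN_pc_L	SC	12	
SN_pc_R	SC	12	
Red_N_L	SC	12	
Red_N_R	SC	12	
Cerebellum_Crus1_L	CB	12	
Cerebellum_Crus1_R	CB	12	
Cerebellum_Crus2_L	CB	12	
Cerebellum_Crus2_R	CB	12	
Cerebellum_3_L	CB	12	
Cerebellum_3_R	CB	12	
Cerebellum_4_5_L	CB	12	
Cerebellum_4_5_R	CB	12	
Cerebellum_6_L	CB	12	
Cerebellum_6_R	CB	12	
Cerebellum_7b_L	CB	12	
Cerebellum_7b_R	CB	12	
Thal_AV_L	SC	2	Thalamus
Thal_AV_R	SC	2	Thalamus
Thal_LP_L	SC	2	Thalamus
Thal_LP_R	SC	2	Thalamus
Thal_VA_L	SC	2	Thalamus
Thal_VA_R	SC	2	Thalamus
Thal_VL_L	SC	2	Thalamus
Thal_VL_R	SC	2	Thalamus
Thal_VPL_L	SC	2	Thalamus
Thal_VPL_R	SC	2	Thalamus
Thal_IL_L	SC	2	Thalamus
Thal_IL_R	SC	2	Thalamus
Thal_Re_L	SC	2	Thalamus
Thal_Re_R	SC	2	Thalamus
Thal_MDm_L	SC	2	Thalamus
Thal_MDm_R	SC	2	Thalamus
Thal_MDl_L	SC	2	Thalamus
Thal_MDl_R	SC	2	Thalamus
Thal_LGN_L	SC	2	Thalamus
Thal_LGN_R	SC	2	Thalamus
Thal_MGN_L	SC	2	Thalamus
Thal_MGN_R	SC	2	Thalamus
Thal_PuA_L	SC	2	Thalamus
Thal_PuA_R	SC	2	Thalamus
Thal_PuM_L	SC	2	Thalamus
Thal_PuM_R	SC	2	Thalamus
Thal_PuI_L	SC	2	Thalamus
Thal_PuI_R	SC	2	Thalamus
Thal_PuL_L	SC	2	Thalamus
Thal_PuL_R	SC	2	Thalamus
Olfactory_L	LN	3	
Olfactory_R	LN	3	
Vermis_1_2	CB	3	
Vermis_10	CB	3	
LC_L	SC	3	
LC_R	SC	3	
Raphe_Medial	SC	3	
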