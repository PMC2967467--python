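region	hemisphere	block	cerebellum
Precentral_L	L	frontal	0
Precentral_R	R	frontal	0
Frontal_Sup_L	L	frontal	0
Frontal_Sup_R	R	frontal	0
Frontal_Sup_Orb_L	L	frontal	0
Frontal_Sup_Orb_R	R	frontal	0
Frontal_Mid_L	L	frontal	0
Frontal_Mid_R	R	frontal	0
Frontal_Mid_Orb_L	L	frontal	0
Frontal_Mid_Orb_R	R	frontal	0
Frontal_Inf_Oper_L	L	frontal	0
Frontal_Inf_Oper_R	R	frontal	0
Frontal_Inf_Tri_L	L	frontal	0
Frontal_Inf_Tri_R	R	frontal	0
Frontal_Inf_Orb_L	L	frontal	0
Frontal_Inf_Orb_R	R	frontal	0
Rolandic_Oper_L	L	frontal	0
Rolandic_Oper_R	R	frontal	0
Supp_Motor_Area_L	L	frontal	0
Supp_Motor_Area_R	R	frontal	0
Olfactory_L	L	frontal	0
Olfactory_R	R	frontal	0
Frontal_Sup_Medial_L	L	frontal	0
Frontal_Sup_Medial_R	R	frontal	0
Frontal_Med_Orb_L	L	frontal	0
Frontal_Med_Orb_R	R	frontal	0
Rectus_L	L	frontal	0
Rectus_R	R	frontal	0
Insula_L	L	subcortical	0
Insula_R	R	subcortical	0
Cingulum_Ant_L	L	frontal	0
Cingulum_Ant_R	R	frontal	0
Cingulum_Mid_L	L	parieto-occipital	0
Cingulum_Mid_R	R	parieto-occipital	0
Cingulum_Post_L	L	parieto-occipital	0
Cingulum_Post_R	R	parieto-occipital	0
Hippocampus_L	L	temporal-L	0
Hippocampus_R	R	temporal-R	0
ParaHippocampal_L	L	temporal-L	0
ParaHippocampal_R	R	temporal-R	0
Amygdala_L	L	temporal-L	0
Amygdala_R	R	temporal-R	0
Calcarine_L	L	parieto-occipital	0
Calcarine_R	R	parieto-occipital	0
Cuneus_L	L	parieto-occipital	0
Cuneus_R	R	parieto-occipital	0
Lingual_L	L	parieto-occipital	0
Lingual_R	R	parieto-occipital	0
Occipital_Sup_L	L	parieto-occipital	0
Occipital_Sup_R	R	parieto-occipital	0
Occipital_Mid_L	L	parieto-occipital	0
Occipital_Mid_R	R	parieto-occipital	0
Occipital_Inf_L	L	parieto-occipital	0
Occipital_Inf_R	R	parieto-occipital	0
Fusiform_L	L	temporal-L	0
Fusiform_R	R	temporal-R	0
Postcentral_L	L	parieto-occipital	0
Postcentral_R	R	parieto-occipital	0
Parietal_Sup_L	L	parieto-occipital	0
Parietal_Sup_R	R	parieto-occipital	0
Parietal_Inf_L	L	parieto-occipital	0
Parietal_Inf_R	R	parieto-occipital	0
SupraMarginal_L	L	parieto-occipital	0
SupraMarginal_R	R	parieto-occipital	0
Angular_L	L	parieto-occipital	0
Angular_R	R	parieto-occipital	0
Precuneus_L	L	parieto-occipital	0
Precuneus_R	R	parieto-occipital	0
Paracentral_Lobule_L	L	frontal	0
Paracentral_Lobule_R	R	frontal	0
Caudate_L	L	subcortical	0
Caudate_R	R	subcortical	0
Putamen_L	L	subcortical	0
Putamen_R	R	subcortical	0
Pallidum_L	L	subcortical	0
Pallidum_R	R	subcortical	0
Thalamus_L	L	subcortical	0
Thalamus_R	R	subcortical	0
Heschl_L	L	temporal-L	0
Heschl_R	R	temporal-R	0
Temporal_Sup_L	L	temporal-L	0
Temporal_Sup_R	R	temporal-R	0
Temporal_Pole_Sup_L	L	temporal-L	0
Temporal_Pole_Sup_R	R	temporal-R	0
Temporal_Mid_L	L	temporal-L	0
Temporal_Mid_R	R	temporal-R	0
Temporal_Pole_Mid_L	L	temporal-L	0
Temporal_Pole_Mid_R	R	temporal-R	0
Temporal_Inf_L	L	temporal-L	0
Temporal_Inf_R	R	temporal-R	0
Cerebelum_Crus1_L	L	cerebellar	1
Cerebelum_Crus1_R	R	cerebellar	1
Cerebelum_Crus2_L	L	cerebellar	1
Cerebelum_Crus2_R	R	cerebellar	1
Cerebelum_3_L	L	cerebellar	1
Cerebelum_3_R	R	cerebellar	1
Cerebelum_4_5_L	L	cerebellar	1
Cerebelum_4_5_R	R	cerebellar	1
Cerebelum_6_L	L	cerebellar	1
Cerebelum_6_R	R	cerebellar	1
Cerebelum_7b_L	L	cerebellar	1
Cerebelum_7b_R	R	cerebellar	1
Cerebelum_8_L	L	cerebellar	1
Cerebelum_8_R	R	cerebellar	1
Cerebelum_9_L	L	cerebellar	1
Cerebelum_9_R	R	cerebellar	1
Cerebelum_10_L	L	cerebellar	1
Cerebelum_10_R	R	cerebellar	1
Vermis_1_2	midline	cerebellar	1
Vermis_3	midline	cerebellar	1
Vermis_4_5	midline	cerebellar	1
Vermis_6	midline	cerebellar	1
Vermis_7	midline	cerebellar	1
Vermis_8	midline	cerebellar	1
Vermis_9	midline	cerebellar	1
Vermis_10	midline	cerebellar	1
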