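region_label,macroarea
Frontal_Sup_L,prefrontal
Frontal_Sup_R,prefrontal
Frontal_Mid_L,prefrontal
Frontal_Mid_R,prefrontal
Frontal_Inf_Oper_L,prefrontal
Frontal_Inf_Oper_R,prefrontal
Frontal_Inf_Tri_L,prefrontal
Frontal_Inf_Tri_R,prefrontal
Frontal_Inf_Orb_L,prefrontal
Frontal_Inf_Orb_R,prefrontal
Frontal_Sup_Medial_L,prefrontal
Frontal_Sup_Medial_R,prefrontal
Frontal_Med_Orb_L,prefrontal
Frontal_Med_Orb_R,prefrontal
Rectus_L,prefrontal
Rectus_R,prefrontal
OFCmed_L,prefrontal
OFCmed_R,prefrontal
OFCant_L,prefrontal
OFCant_R,prefrontal
OFCpost_L,prefrontal
OFCpost_R,prefrontal
OFClat_L,prefrontal
OFClat_R,prefrontal
Olfactory_L,prefrontal
Olfactory_R,prefrontal
Cingulate_Ant_L,prefrontal
Cingulate_Ant_R,prefrontal
Precentral_L,other_frontal
Precentral_R,other_frontal
Rolandic_Oper_L,other_frontal
Rolandic_Oper_R,other_frontal
Supp_Motor_Area_L,other_frontal
Supp_Motor_Area_R,other_frontal
Paracentral_Lobule_L,other_frontal
Paracentral_Lobule_R,other_frontal
Cingulate_Mid_L,other_frontal
Cingulate_Mid_R,other_frontal
Insula_L,other_frontal
Insula_R,other_frontal
Calcarine_L,occipital
Calcarine_R,occipital
Cuneus_L,occipital
Cuneus_R,occipital
Lingual_L,occipital
Lingual_R,occipital
Occipital_Sup_L,occipital
Occipital_Sup_R,occipital
Occipital_Mid_L,occipital
Occipital_Mid_R,occipital
Occipital_Inf_L,occipital
Occipital_Inf_R,occipital
Fusiform_L,occipital
Fusiform_R,occipital
Heschl_L,temporal
Heschl_R,temporal
Temporal_Sup_L,temporal
Temporal_Sup_R,temporal
Temporal_Pole_Sup_L,temporal
Temporal_Pole_Sup_R,temporal
Temporal_Mid_L,temporal
Temporal_Mid_R,temporal
Temporal_Pole_Mid_L,temporal
Temporal_Pole_Mid_R,temporal
Temporal_Inf_L,temporal
Temporal_Inf_R,temporal
Hippocampus_L,temporal
Hippocampus_R,temporal
ParaHippocampal_L,temporal
ParaHippocampal_R,temporal
Amygdala_L,temporal
Amygdala_R,temporal
Postcentral_L,parietal
Postcentral_R,parietal
Parietal_Sup_L,parietal
Parietal_Sup_R,parietal
Parietal_Inf_L,parietal
Parietal_Inf_R,parietal
SupraMarginal_L,parietal
SupraMarginal_R,parietal
Angular_L,parietal
Angular_R,parietal
Precuneus_L,parietal
Precuneus_R,parietal
Cingulate_Post_L,parietal
Cingulate_Post_R,parietal
Caudate_L,central_structures
Caudate_R,central_structures
Putamen_L,central_structures
Putamen_R,central_structures
Pallidum_L,central_structures
Pallidum_R,central_structures
Thalamus_L,central_structures
Thalamus_R,central_structures
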