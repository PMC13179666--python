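label	hemisphere	region_class	subdivision
L_thal_anterior	L	thalamic	anterior
L_thal_lateral	L	thalamic	lateral
L_thal_medial	L	thalamic	medial
L_thal_pulvinar	L	thalamic	pulvinar
R_thal_anterior	R	thalamic	anterior
R_thal_lateral	R	thalamic	lateral
R_thal_medial	R	thalamic	medial
R_thal_pulvinar	R	thalamic	pulvinar
L_frontal_pole	L	other	
L_insular_cortex	L	other	
L_superior_frontal_gyrus	L	other	
L_middle_frontal_gyrus	L	other	
L_inferior_frontal_gyrus_pars_triangularis	L	other	
L_inferior_frontal_gyrus_pars_opercularis	L	other	
L_precentral_gyrus	L	other	
L_temporal_pole	L	other	
L_superior_temporal_gyrus_anterior	L	other	
L_superior_temporal_gyrus_posterior	L	other	
L_middle_temporal_gyrus_anterior	L	other	
L_middle_temporal_gyrus_posterior	L	other	
L_middle_temporal_gyrus_temporooccipital	L	other	
L_inferior_temporal_gyrus_anterior	L	other	
L_inferior_temporal_gyrus_posterior	L	other	
L_inferior_temporal_gyrus_temporooccipital	L	other	
L_postcentral_gyrus	L	other	
L_superior_parietal_lobule	L	other	
L_supramarginal_gyrus_anterior	L	other	
L_supramarginal_gyrus_posterior	L	other	
L_angular_gyrus	L	other	
L_lateral_occipital_cortex_superior	L	other	
L_lateral_occipital_cortex_inferior	L	other	
L_intracalcarine_cortex	L	other	
L_frontal_medial_cortex	L	other	
L_juxtapositional_lobule	L	other	
L_subcallosal_cortex	L	other	
L_paracingulate_gyrus	L	other	
L_cingulate_gyrus_anterior	L	other	
L_cingulate_gyrus_posterior	L	other	
L_precuneous_cortex	L	other	
L_cuneal_cortex	L	other	
L_frontal_orbital_cortex	L	other	
L_parahippocampal_gyrus_anterior	L	other	
L_parahippocampal_gyrus_posterior	L	other	
L_lingual_gyrus	L	other	
L_temporal_fusiform_cortex_anterior	L	other	
L_temporal_fusiform_cortex_posterior	L	other	
L_temporal_occipital_fusiform_cortex	L	other	
L_occipital_fusiform_gyrus	L	other	
L_frontal_operculum_cortex	L	other	
L_central_opercular_cortex	L	other	
L_parietal_operculum_cortex	L	other	
L_planum_polare	L	other	
L_heschls_gyrus	L	other	
L_planum_temporale	L	other	
L_supracalcarine_cortex	L	other	
L_occipital_pole	L	other	
L_paracentral_lobule	L	other	
L_inferior_frontal_gyrus_pars_orbitalis	L	other	
L_medial_orbitofrontal_cortex	L	other	
L_entorhinal_cortex	L	other	
L_hippocampus	L	other	
L_amygdala	L	other	
L_accumbens	L	other	
L_caudate	L	other	
L_putamen	L	other	
R_frontal_pole	R	other	
R_insular_cortex	R	other	
R_superior_frontal_gyrus	R	other	
R_middle_frontal_gyrus	R	other	
R_inferior_frontal_gyrus_pars_triangularis	R	other	
R_inferior_frontal_gyrus_pars_opercularis	R	other	
R_precentral_gyrus	R	other	
R_temporal_pole	R	other	
R_superior_temporal_gyrus_anterior	R	other	
R_superior_temporal_gyrus_posterior	R	other	
R_middle_temporal_gyrus_anterior	R	other	
R_middle_temporal_gyrus_posterior	R	other	
R_middle_temporal_gyrus_temporooccipital	R	other	
R_inferior_temporal_gyrus_anterior	R	other	
R_inferior_temporal_gyrus_posterior	R	other	
R_inferior_temporal_gyrus_temporooccipital	R	other	
R_postcentral_gyrus	R	other	
R_superior_parietal_lobule	R	other	
R_supramarginal_gyrus_anterior	R	other	
R_supramarginal_gyrus_posterior	R	other	
R_angular_gyrus	R	other	
R_lateral_occipital_cortex_superior	R	other	
R_lateral_occipital_cortex_inferior	R	other	
R_intracalcarine_cortex	R	other	
R_frontal_medial_cortex	R	other	
R_juxtapositional_lobule	R	other	
R_subcallosal_cortex	R	other	
R_paracingulate_gyrus	R	other	
R_cingulate_gyrus_anterior	R	other	
R_cingulate_gyrus_posterior	R	other	
R_precuneous_cortex	R	other	
R_cuneal_cortex	R	other	
R_frontal_orbital_cortex	R	other	
R_parahippocampal_gyrus_anterior	R	other	
R_parahippocampal_gyrus_posterior	R	other	
R_lingual_gyrus	R	other	
R_temporal_fusiform_cortex_anterior	R	other	
R_temporal_fusiform_cortex_posterior	R	other	
R_temporal_occipital_fusiform_cortex	R	other	
R_occipital_fusiform_gyrus	R	other	
R_frontal_operculum_cortex	R	other	
R_central_opercular_cortex	R	other	
R_parietal_operculum_cortex	R	other	
R_planum_polare	R	other	
R_heschls_gyrus	R	other	
R_planum_temporale	R	other	
R_supracalcarine_cortex	R	other	
R_occipital_pole	R	other	
R_paracentral_lobule	R	other	
R_inferior_frontal_gyrus_pars_orbitalis	R	other	
R_medial_orbitofrontal_cortex	R	other	
R_entorhinal_cortex	R	other	
R_hippocampus	R	other	
R_amygdala	R	other	
R_accumbens	R	other	
R_caudate	R	other	
R_putamen	R	other	
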