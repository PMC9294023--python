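# The 15 regions of interest and their member variables (reduced-column names).
#
# Each ROI combines one grey-matter index (summed cortical thickness, or summed
# TIV-normalised volume for subcortical/infratentorial regions) and one
# white-matter index (summed FA).  The long-association-fibre ROI has no
# grey-matter members; its two FA values are min-max scaled separately and the
# composite is their sum, so every ROI score lives on the same 0-2 scale.
#
# Order below is the canonical ROI order used throughout the package.

rois:
  - name: inferior_frontal
    gm_members: [th_lateral_orbitofrontal, th_medial_orbitofrontal, th_pars_orbitalis,
                 th_frontal_pole, th_rostral_anterior_cingulate]
    wm_members: [fa_inferior_frontal_wm]
    wm_scaling_mode: pooled
  - name: superior_frontal
    gm_members: [th_superior_frontal, th_rostral_middle_frontal, th_caudal_middle_frontal,
                 th_caudal_anterior_cingulate]
    wm_members: [fa_superior_frontal_wm]
    wm_scaling_mode: pooled
  - name: peri_sylvian
    gm_members: [th_pars_opercularis, th_pars_triangularis, th_insula]
    wm_members: [fa_uncinate_fasciculus]
    wm_scaling_mode: pooled
  - name: mesial_inferior_temporal
    gm_members: [th_entorhinal, th_parahippocampal, th_fusiform, th_temporal_pole]
    wm_members: [fa_inferior_longitudinal_fasciculus]
    wm_scaling_mode: pooled
  - name: superior_lateral_temporal
    gm_members: [th_superior_temporal, th_middle_temporal, th_inferior_temporal,
                 th_transverse_temporal, th_bankssts]
    wm_members: [fa_temporal_wm]
    wm_scaling_mode: pooled
  - name: parietal
    gm_members: [th_inferior_parietal, th_superior_parietal, th_supramarginal,
                 th_precuneus, th_posterior_cingulate, th_isthmus_cingulate]
    wm_members: [fa_parietal_wm]
    wm_scaling_mode: pooled
  - name: occipital
    gm_members: [th_lateral_occipital, th_lingual, th_cuneus, th_pericalcarine]
    wm_members: [fa_occipital_wm]
    wm_scaling_mode: pooled
  - name: motor
    gm_members: [th_precentral, th_paracentral]
    wm_members: [fa_corticospinal_tract]
    wm_scaling_mode: pooled
  - name: commissural
    gm_members: [vol_cc_posterior, vol_cc_middle, vol_cc_central, vol_cc_mid_anterior,
                 vol_cc_anterior]
    wm_members: [fa_forceps_major, fa_forceps_minor, fa_body_corpus_callosum]
    wm_scaling_mode: pooled
  - name: brainstem
    gm_members: [vol_medulla, vol_pons, vol_midbrain]
    wm_members: [fa_brainstem_wm]
    wm_scaling_mode: pooled
  - name: cerebellum
    gm_members: [vol_cerebellar_cortex, vol_superior_cerebellar_peduncle]
    wm_members: [fa_inferior_cerebellar_peduncle, fa_middle_cerebellar_peduncle,
                 fa_superior_cerebellar_peduncle, fa_cerebellar_wm]
    wm_scaling_mode: pooled
  - name: subcortical
    gm_members: [vol_thalamus, vol_caudate, vol_putamen, vol_pallidum, vol_accumbens]
    wm_members: [fa_anterior_thalamic_radiation, fa_posterior_thalamic_radiation]
    wm_scaling_mode: pooled
  - name: limbic
    gm_members: [vol_amygdala, vol_hippocampus]
    wm_members: [fa_fornix, fa_cingulum]
    wm_scaling_mode: pooled
  - name: long_association_fibres
    gm_members: []
    wm_members: [fa_inferior_fronto_occipital_fasciculus, fa_superior_longitudinal_fasciculus]
    wm_scaling_mode: separate
  - name: sensory
    gm_members: [th_postcentral]
    wm_members: [fa_medial_lemniscus]
    wm_scaling_mode: pooled
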