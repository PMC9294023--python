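# Column vocabulary and bilateral pairing map for the three raw metric tables.
#
# Raw tables carry one column per lateralised structure ("<base>_lh"/"<base>_rh")
# or one column per midline structure.  Reduction averages each left/right pair
# and passes midline singletons through, then prefixes the reduced name with the
# modality ("th_", "vol_", "fa_") so the three modalities share one namespace.
#
# thickness: 34 Desikan-Killiany cortical labels x 2 hemispheres = 68 columns -> 34 reduced
# volumes:   8 bilateral subcortical/cerebellar structures x 2 + 9 midline = 25 columns -> 17 reduced
#            (the volumes table additionally carries a "tiv" column, not a metric)
# fa:        17 bilateral white-matter labels x 2 + 6 midline = 40 columns -> 23 reduced

thickness:
  prefix: th
  bilateral:
    - bankssts
    - caudal_anterior_cingulate
    - caudal_middle_frontal
    - cuneus
    - entorhinal
    - frontal_pole
    - fusiform
    - inferior_parietal
    - inferior_temporal
    - insula
    - isthmus_cingulate
    - lateral_occipital
    - lateral_orbitofrontal
    - lingual
    - medial_orbitofrontal
    - middle_temporal
    - paracentral
    - parahippocampal
    - pars_opercularis
    - pars_orbitalis
    - pars_triangularis
    - pericalcarine
    - postcentral
    - posterior_cingulate
    - precentral
    - precuneus
    - rostral_anterior_cingulate
    - rostral_middle_frontal
    - superior_frontal
    - superior_parietal
    - superior_temporal
    - supramarginal
    - temporal_pole
    - transverse_temporal
  midline: []

volumes:
  prefix: vol
  bilateral:
    - accumbens
    - amygdala
    - caudate
    - cerebellar_cortex
    - hippocampus
    - pallidum
    - putamen
    - thalamus
  midline:
    - cc_anterior
    - cc_mid_anterior
    - cc_central
    - cc_middle
    - cc_posterior
    - medulla
    - midbrain
    - pons
    - superior_cerebellar_peduncle

fa:
  prefix: fa
  bilateral:
    - anterior_thalamic_radiation
    - cerebellar_wm
    - cingulum
    - corticospinal_tract
    - inferior_cerebellar_peduncle
    - inferior_frontal_wm
    - inferior_fronto_occipital_fasciculus
    - inferior_longitudinal_fasciculus
    - medial_lemniscus
    - occipital_wm
    - parietal_wm
    - posterior_thalamic_radiation
    - superior_cerebellar_peduncle
    - superior_frontal_wm
    - superior_longitudinal_fasciculus
    - temporal_wm
    - uncinate_fasciculus
  midline:
    - body_corpus_callosum
    - brainstem_wm
    - forceps_major
    - forceps_minor
    - fornix
    - middle_cerebellar_peduncle
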