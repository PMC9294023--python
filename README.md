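# alsclust

Data-driven discovery of radiological subtypes in amyotrophic lateral
sclerosis (ALS) from imaging-derived metrics.

ALS is clinically heterogeneous, and most imaging studies stratify patients
by clinical or genetic criteria first and describe the associated imaging
signatures afterwards. This package implements the opposite, data-driven
route: patients are clustered purely on the anatomical distribution of their
disease burden, and the clinical/genetic profiles of the resulting clusters
are examined post hoc. It is written for biostatisticians and neuroimaging
researchers who work with tabular outputs of standard MRI pipelines (cortical
thickness per atlas region, structure volumes, tract-wise fractional
anisotropy) rather than with images.

## Method

The pipeline has four stages, each available as a library function, an
`analysis/` driver script, and a CLI subcommand:

1. **Reduction.** Per-subject tables of 68 cortical thickness values
   (Desikan–Killiany, both hemispheres), 25 volumes + total intracranial
   volume (TIV), and 40 white-matter FA labels are validated, volumes are
   expressed as TIV fractions (v/TIV), and bilateral structures are averaged
   pairwise: 133 metric columns → 74 variables (34 thickness, 17 volume, 23
   FA).

2. **Composite regional scoring.** The 74 variables map into 15 anatomical
   regions of interest (ROIs). Per ROI, a grey-matter index (summed thickness,
   or summed volume fraction for subcortical/infratentorial regions) and a
   white-matter index (summed FA) are each min–max scaled over the cohort,

   `score(subject, ROI) = (g − min g)/(max g − min g) + (w − min w)/(max w − min w) ∈ [0, 2]`,

   higher = better-preserved tissue. The long-association-fibre ROI has no
   grey-matter members; its two FA inputs are scaled separately and summed.

3. **Two-step clustering.** The N×15 score matrix is clustered by the classic
   scalable two-step procedure: an optional CF-tree pre-clustering pass
   (sufficient statistics n, Σx, Σx²; bypassed by default at study scale),
   agglomerative merging under Euclidean centroid distance, and automatic
   selection of the number of clusters k via a likelihood-based BIC,

   `BIC(J) = −2 Σⱼ ξⱼ + 2 d J log N`, `ξⱼ = −Nⱼ Σᵥ ½ log(σ̂ᵥ² + σ̂ⱼᵥ²)`,

   refined by merge-distance ratios. Cluster quality is summarised by the
   mean silhouette coefficient; per-ROI predictor importance is the
   max-normalised −log₁₀ p of a one-way ANOVA across clusters.

4. **Post-hoc profiling.** Clusters are contrasted on demographic, clinical
   and genetic variables: Yates-corrected χ² for 2×2 tables, uncorrected
   Pearson χ² for larger tables (with structural missingness — unscreened
   genotype, unassessed cognition — kept as an explicit category), and Welch
   t tests for continuous variables.

Because no patient-level data are distributed, the package ships a synthetic
cohort generator that emulates the study cohort: 214 subjects, two latent
radiological subtypes (35.5% / 64.5%), a graded frontotemporal-predominant
effect ladder across the 15 ROIs, C9orf72 hexanucleotide-carrier enrichment
in the smaller subtype, and realistic genotyping/ECAS missingness.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_reduce_and_score.py
python analysis/03_cluster_subtypes.py
python analysis/04_rank_predictors.py
python analysis/05_posthoc_profiles.py
```

or equivalently `alsclust all --simulate --seed 1 --out results/run`. With
seed 1 the drivers print:

```
generated 214 subjects (seed 1); latent subtype 1: 69 (32.2%)
214 subjects reduced to 74 variables (17 volume, 34 thickness, 23 FA)
composite scores: 214 x 15, range [0.000, 1.945]
selected k = 2
  cluster 1: n = 69 (32.2%)
  cluster 2: n = 145 (67.8%)
mean silhouette = 0.582
adjusted Rand index vs latent subtypes = 1.000
recovered importance hierarchy (planted position in brackets):
   1. superior_lateral_temporal    importance 1.000 [planted #1]
   2. inferior_frontal             importance 0.958 [planted #2]
   3. superior_frontal             importance 0.895 [planted #3]
   ...
  15. brainstem                    importance 0.000 [planted #15]
Spearman correlation with planted ladder = 0.996
```

The BIC rule selects two clusters; the smaller cluster recovers the planted
minority subtype exactly (adjusted Rand index 1.0); silhouette 0.58 indicates
reasonable cohesion/separation; and the regions that best segregate the
clusters are the frontotemporal ones, while motor, cerebellar and brainstem
involvement — the shared core of the disease — discriminates least. The
post-hoc driver additionally reproduces the published between-cluster
statistics from the study's printed per-cluster counts, e.g. χ² = 23.17
(df = 2) for genotype and 72.7% of the 22 carriers in cluster 1.

## Layout

```
src/alsclust/      library: cohort IO, scoring, two-step clustering,
                   importance, post-hoc stats, simulation, pipeline, CLI
src/alsclust/config/  column vocabulary / pairing map and ROI definitions (YAML)
analysis/          numbered narrative drivers over the library
scripts/           acceptance script
tests/             pytest suite (unit, property and end-to-end tests)
docs/methods.md    model assumptions, parameter choices, limitations
```
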