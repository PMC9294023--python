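# Methods

This note documents the models, parameter choices and numerical conventions
behind `alsclust`, and what the test suite does and does not establish.

## Composite regional integrity scoring

Each of the 15 ROIs is scored as the sum of two cohort-level min–max scaled
indices: a grey-matter index (summed cortical thickness, or summed
TIV-fraction volume for subcortical and infratentorial regions) and a
white-matter index (summed FA). The long-association-fibre ROI is the single
exception: it has no grey-matter members, and its two FA inputs
(inferior fronto-occipital and superior longitudinal fasciculus) are scaled
separately so the composite still spans [0, 2].

Conventions worth stating explicitly:

- **Scaling is cohort-dependent.** Min and max are taken over the analysed
  sample, so a subject's score depends on who else is in the cohort. The
  fitted `ScalingParams` are persisted so new subjects can be projected with
  frozen bounds; a constant index (max = min) is an error, not a silent 0.
- **Summation before scaling.** Member columns are summed raw and the sum is
  scaled, not the other way around. Consequently the pipeline is invariant to
  translations of any raw column and to positive affine maps applied to a
  whole index (and hence to any single-column index), but *not* to rescaling
  one summand of a multi-column index — that genuinely reweights the members.
  The test suite asserts exactly these invariances.
- **Volumes enter as TIV fractions**, making scores invariant to global
  head-size rescaling.
- Missing metric cells cause the subject to be dropped with a logged warning;
  there is no imputation.

## Two-step clustering

Step one is a CF-tree pass holding pre-clusters as sufficient statistics
(n, Σx, Σx²). Insertion descends to the closest leaf entry by Euclidean
centroid distance and absorbs the point when within the distance threshold;
when the tree outgrows its capacity (branching factor 8, 8 leaf entries,
depth 3 by default) it is rebuilt with the threshold raised to the smallest
observed inter-entry distance. The tree is insertion-order dependent, as is
inherent to a sequential pass; insertion order is input row order, with a
seed-controlled shuffle available for sensitivity analysis. At a few hundred
subjects the tree buys nothing, so `bypass_tree=True` (every subject its own
pre-cluster) is the default, which makes the whole procedure deterministic
and exactly equal to naive centroid-linkage agglomeration — a property the
tests verify merge-for-merge against an O(n³) oracle and against scipy.

Step two merges the pair of clusters with minimum Euclidean centroid distance
(ties broken by lowest index pair), with merged statistics as exact sums. For
every partition along the way a likelihood-based BIC is recorded:

    BIC(J) = −2 Σⱼ ξⱼ + 2 d J log N
    ξⱼ     = −Nⱼ Σᵥ ½ log(σ̂ᵥ² + σ̂ⱼᵥ²)

with σ̂ᵥ² the cohort variance and σ̂ⱼᵥ² the within-cluster variance of score
v. Merging uses Euclidean distance while the BIC is likelihood-based; this
mixture mirrors the established two-step procedure's auto-k stage and is an
acknowledged approximation. Two numerical floors guard degeneracy: within-
cluster variances are floored at 1e−9·σ̂ᵥ², and constant dimensions at
1e−12·max(1, max σ̂ᵥ²); both add identical constants across partitions and
cannot affect the selected k.

The number of clusters is chosen in two stages (defaults c₁ = 0.04,
c₂ = 1.15, k ≤ 15): the BIC change ratio dBIC(k)/dBIC(1), with
dBIC(k) = BIC(k) − BIC(k+1), yields a coarse estimate (the smallest k where
the ratio drops below c₁; k = 1 if the BIC never improves past one cluster);
merge-distance ratios R(k) = d(k→k−1)/d(k+1→k) then refine it — the largest
ratio wins if it dominates the second largest by more than c₂, otherwise the
larger of the two candidate k.

This BIC is deliberately conservative: with d = 15 variables, a new cluster
must buy 2·15·log N of log-likelihood, so structure confined to one dimension
will not split a cohort. This matters when designing simulations: separation
must be spread over several score dimensions to be detected, which is also
the anatomically realistic case.

Final labels are 1..k with **cluster 1 the smaller cluster**, matching the
convention of reporting the minority subtype first. An optional refinement
pass reassigning subjects to the nearest final centroid exists and is off by
default, so the reported partition is the dendrogram cut itself.

The silhouette coefficient uses Euclidean distance on the 15 scores, with
s = 0 for members of singleton clusters. The 0–2 composite scores are
clustered as-is, without re-standardisation: the min–max scaling has already
placed all ROIs on a common scale, and re-standardising would re-inflate
noise-only dimensions.

## Predictor importance

Per ROI, a one-way ANOVA F across clusters (identical to the squared pooled-t
for k = 2); importance = −log₁₀ p, max-normalised so the best predictor
scores exactly 1. p-values are floored at 1e−300 so perfect separation stays
finite; a zero between-cluster difference yields importance 0. Ties are
broken alphabetically and logged. This significance-based importance is one
reasonable choice among several (the established procedure's internal formula
for continuous inputs is not published); permutation-based importance is
deliberately out of scope.

## Post-hoc statistics

2×2 tables use the continuity-corrected χ² with the correction capped at
|O−E| (scipy's implementation, which matches the capped Yates formula
exactly); r×c tables use uncorrected Pearson χ² with df = (r−1)(c−1).
Genotype and ECAS carry their structurally missing subjects (not screened /
not assessed) as an explicit third category by default — the published
between-cluster statistics for these variables are numerically consistent
only with that 2×3 construction — while other variables drop missing values.
Continuous variables default to Welch's t. No small-sample exact or
Monte-Carlo options are provided.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
the physics of MRI:

- **Two latent subtypes** drawn with P(subtype 1) = 0.355; subtype 1 carries
  an extra per-ROI burden given by a graded effect ladder, largest for
  superior lateral temporal / inferior frontal / superior frontal regions and
  near zero for motor, cerebellum and brainstem. A separate shared-burden
  term depresses motor, brainstem and commissural metrics in *both* subtypes,
  modelling the core, unifying features of the disease that do not
  discriminate subtypes.
- **Ladder semantics.** The ladder is specified at the index level: entry e
  means the ROI's grey- and white-matter indices each separate the subtypes
  by e pooled SDs. Member columns receive e·SD/√m (m = columns in the index),
  so ROIs with many members are not mechanically favoured and the planted
  importance hierarchy is exactly the ladder ordering — the property the
  rank-recovery tests check.
- **Ladder magnitudes** (4.4 down to 0.1 SD) are calibrated so the recovered
  two-cluster solution shows the cohesion reported for the study cohort
  (mean silhouette ≈ 0.57). Under these defaults the BIC rule selects k = 2
  in 20/20 seeds and the latent labels are recovered with ARI 1.0. Weaker
  ladders degrade gracefully (the monotonicity tests sweep a 3-point grid);
  a zeroed ladder yields k = 1.
- **Raw-column realism.** Effects are injected at the raw-column level:
  thickness ≈ 2.5 ± 0.13 mm, FA ≈ 0.45 ± 0.025, volumes as plausible TIV
  fractions with 7% relative SD, multiplied by a log-normal per-subject TIV
  (mean 1.45 × 10⁶ mm³, CV 0.08) so the TIV-normalisation step is exercised
  for real. Left/right hemispheres share correlated noise (ρ = 0.9).
- **Metadata** are sampled per subtype from the published per-cluster values:
  demographics (age, sex, handedness, education, onset site, ALSFRS-r),
  ALS-FTD comorbidity, genotyping coverage (per-subtype rates whose weighted
  mean is 161/214), carrier probability among the genotyped (23.5% vs 6.5%),
  and ECAS availability/impairment. Missingness is encoded as empty cells.

What the generator does **not** model — and hence what passing tests cannot
show about real data: inter-ROI anatomical covariance beyond the left–right
pairing (ROIs are conditionally independent given subtype), region-specific
baselines within a modality, age/sex effects on the metrics, site or scanner
effects, and any continuous spectrum of disease burden (the latent structure
is exactly two subtypes). Real cohorts may also violate the clean
missing-at-random-within-subtype pattern used here.

## Problem sizes and determinism

All simulation-based tests run at the study scale (n = 214, 20 seeds) or
below; the acceptance script's cluster-structure sweep is 20 cohorts of 214
and completes in seconds. Every random draw flows through one
`numpy.random.default_rng(seed)` per cohort, so all outputs are bit-for-bit
reproducible given the seed; the acceptance script derives its cohort seeds
from the single `--seed` argument. In bypass-tree mode the whole pipeline is
deterministic and permutation-equivariant; CF-tree mode is documented as
insertion-order dependent.

## Known limitations

- The study's exact partition (76/138), silhouette (0.572) and importance
  ordering depend on the unavailable patient data; the package reproduces the
  procedure and its printed count-based statistics, and validates the
  clustering machinery against independent oracles instead.
- The onset-site comparison is reported descriptively but excluded from the
  reproduced statistics: its printed χ² is not recoverable from the published
  counts as any 2×2 (the underlying category structure is unprinted).
- The BIC functional form and the importance formula are the package's
  declared choices for an under-specified procedure, not inferences from
  published internals.
- Cross-sectional only; no survival or longitudinal modelling.
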