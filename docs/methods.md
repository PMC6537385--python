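# Methods

`phenosom` implements a phenotypic-preselection workflow for field breeding
trials: plot-level phenotypic components (traits and trait-like quantities
derived from UAV imagery) are clustered by a mixed-data self-organizing map
followed by hierarchical clustering of the codebooks ("two-step
clustering"), each cluster is characterized by rank-sum over/under-expression
calls and decision-tree rules, and the components themselves are related by a
correlation PCA biplot. This note documents the model, the defaults, the
numerical choices and the limits of what the synthetic experiments show.

## Synthetic population

Real plot-level tables from breeding trials are rarely deposited, so the
package ships a generator that emulates their statistical structure. A
population of `n_plots` plots is drawn from `n_true_clusters` planted
clusters with proportions `cluster_proportions`. Each plot carries:

* **Numeric components** — final plant height `finPH` (cm), final fresh
  biomass `finBiomass` (kg/m²), and three scalars derived from time series
  (below). Each component has a base magnitude (260 cm, 5.5 kg/m², …) and a
  per-plot multiplicative scale drawn from
  N(1 + `effect_size`·`noise_sd`·offset_c, `noise_sd`), where offset_c is the
  planted cluster's offset for that component. `noise_sd` is therefore a
  coefficient of variation: the within-cluster sd on each component's own
  scale, so cluster means are separated by `effect_size` within-cluster sd
  regardless of units. At `effect_size = 0` all clusters draw from the same
  numeric distribution.
* **Time series on a days-after-sowing (DAS) grid** (default 24, 45, 57, 78,
  85): the plant-height and BIOVP (image-derived biomass volume)
  trajectories are logistic growth curves; NDVI is a concave saturation
  curve clipped to [−1, 1]. NDVI uses the first four DAS points (the
  multispectral flights); a small observation noise is added per time point.
  AGRPH (average growth rate of plant height) is derived from the height
  trajectory as per-interval increments divided by interval length and
  padded to five values by repeating the first-interval rate — the padding
  convention is ours; only the five-point arity is fixed by the schema.
* **Categorical components** — flowering and lodging status (Y/N), leaf
  color (green / greenyellow / darkgreen) and genetic background (Mixed /
  TEM / TST), drawn from per-cluster probability profiles.

Two presets encode the study conditions: `paper-like` (482 plots, three
planted clusters in proportions 201/165/116 with the co-expression pattern:
cluster 1 lodging-prone with depressed numerics, cluster 2 without
green-yellow leaves and with peak NDVI, cluster 3 TST-dominated,
non-flowering, with elevated numerics except NDVI) and
`natural-population-2017` (the same, with the genetic-background composition
fixed exactly at 106 Mixed / 162 TEM / 214 TST). When exact background
counts are requested, cluster labels are drawn from
P(cluster | background) ∝ proportion · profile, so cluster sizes are met in
expectation while background counts are met exactly. Default
`effect_size = 5`, `noise_sd = 0.06`.

**What the generator does not emulate:** spatial field layout and neighbor
effects, genotype-by-environment interaction, measurement drift between
flights, missing data, and the continuous (not cluster-discrete) structure
of a real natural population. Passing recovery tests on this generator shows
the machinery is correct under its assumptions, not that a real trial will
yield equally clean clusters — real data produce far fewer dead neurons and
much lower ARI ceilings.

## Feature encoding

Each time series is collapsed to the trapezoidal area under its polyline
over the DAS axis (`dyNDVI`, `dyBIOVP`, `dyAGRPH`); areas are computed on
the raw series first and standardized afterwards. The five numerics are
z-scored with the sample (n−1) sd (prefixed `Z`). Categoricals are expanded
to full one-hot blocks — no reference level is dropped, so the standard
schema gives 5 + 2 + 2 + 3 + 3 = 15 features, and every level (e.g.
`IS_lodging.Y`) appears as its own variable in the biplot. The encoded
columns are organized into SOM layers: one Euclidean layer with all
numerics, one Tanimoto layer per source categorical, equal weights by
default.

## Mixed-data SOM

A 15 × 7 hexagonal lattice (105 neurons; odd rows offset by 0.5, row pitch
√3/2, planar Euclidean grid distance, row-major numbering) is trained online
for 5000 iterations with a Gaussian neighborhood. Sample-to-neuron
similarity sums per-layer distances, each divided by the layer's column
count and multiplied by the layer weight: squared Euclidean for the numeric
layer and Tanimoto distance 1 − a·b/(|a|² + |b|² − a·b) for categorical
layers (extended continuously to the real-valued codebooks; both-zero
vectors count as identical). Update rule: w ← w + α(t)·h(d, r(t))·(x − w)
for every neuron and layer.

Numerical choices: α decays linearly 0.05 → 0.01 and the radius from the
2/3-quantile of neuron-pair grid distances to 0 (linear schedules are the
reference-implementation convention when no schedule is specified);
codebooks initialize from random data rows, which reduces dead neurons
relative to uniform noise; BMU ties break to the lowest neuron index for
determinism; one "iteration" presents one random sample, with an epoch mode
(one shuffled full pass per iteration) behind `iteration_mode="epoch"`
because the convention differs between implementations. The training
history records the mean presented-sample BMU distance over ~50 equal
chunks. With α ≤ 1 every codebook coordinate remains a convex combination
of data and initial values, which bounds the codebooks in the data hull.

## Two-step clustering

Codebooks (dead neurons included — they carry codebooks too) are merged by
Ward's minimum-variance linkage (Ward.D2, `scipy` linkage on the
concatenated codebook vectors). The cluster count is voted: each internal
validity index proposes its optimal k over Ward partitions of the codebooks
for k in [k_min, k_max] (default 2–6), and the mode wins, ties to the
smallest k. Indices are evaluated on the codebooks — the objects that were
clustered — not on raw samples.

Implemented battery (10 indices): Calinski–Harabasz, average silhouette,
Davies–Bouldin, Dunn, C-index, McClain–Rao and point-biserial vote by their
standard max/min rule; Hartigan votes the smallest k with H(k) ≤ 10 (its
original rule; largest drop if none qualifies); Krzanowski–Lai maximizes
KL(k); Ball–Hall votes the k with the largest successive decrease of the
mean per-cluster dispersion. The battery is a documented, extensible subset
of the larger NbClust-style collections; not every published index is
applicable to mixed data, and exact vote tallies depend on the battery
chosen. Sample clusters are obtained by composing neuron clusters with the
BMU map.

## Profiling

Per numeric component, a one-way ANOVA tests whether any cluster means
differ (zero within-variance is flagged rather than erroring). Each
(cluster, component) then receives a rank-sum over/under-expression call
against the total population mean with stars ns / * / ** / *** / **** at
p ≤ 0.05 / 0.01 / 0.001 / 0.0001.

Because the cluster is a subset of the population it is compared with, the
test is formulated as a subset permutation rank-sum: ranks are midranks over
the whole population, the statistic is the cluster's rank sum, and the null
is a uniformly random size-n₁ subset. The null distribution is computed
exactly by a dynamic program over doubled midranks whenever
min(n₁, n − n₁) ≤ 8 (exact under ties as well), otherwise by a normal
approximation with tie-corrected variance and a 0.5 continuity correction.
This subset null coincides with the exact two-sample rank-sum test of
cluster versus complement, so the `reference="total"` and
`reference="complement"` options share p-values and differ only in the mean
used for the over/under direction; the total-population mean is the default
reference. No multiple-testing correction is applied by default (raw stars
are reported); Benjamini–Hochberg is available via `p_adjust="bh"`.

Categorical structure is summarized by intersection counts: for each
(cluster, level) pair the count, within-cluster percentage and a purity
flag (default threshold 100%). Finally the clustering is resolved into
rules with a CART tree: greedy binary splits minimizing Gini impurity,
thresholds at midpoints between sorted distinct values (one-hot columns
split at 0.5, which is a level split), stopping at `max_depth` (4) /
`min_leaf` (5) with no cost-complexity pruning; the reported quality is
resubstitution accuracy, which is optimistic by construction and intended
as a readability check, not a generalization estimate.

## Biplot

The full 15-column encoded matrix — indicator columns rescaled to unit
variance like the numerics, i.e. treated as active variables — is
decomposed by eigenanalysis of its correlation matrix. Loadings are scaled
to equal feature–PC correlations, so arrow lengths are ≤ 1, per-variable
Cos2 (squared loadings) sums to 1 across all PCs, and the cosine of the
full-space angle between two loading vectors equals the sample correlation
of the two features. Eigenvector signs are fixed so each PC's
largest-magnitude loading is positive, making outputs deterministic. Note
the one-hot blocks make the matrix rank-deficient (rank 11 of 15); the
trailing eigenvalues are zero and are clipped at 0 against round-off. The
component dendrogram uses average-linkage AHC on the Spearman correlation
distance 1 − ρ (the linkage is our choice; only the distance is dictated by
the method); constant features are rejected by name.

## Pipeline, determinism, problem sizes

`run_pipeline` (and the `phenosom` CLI) chains
generate/load → encode → SOM → clustering → profiling → biplot, writes
every artifact as CSV/JSON plus a manifest with a config hash, all seeds
consumed, and per-stage summaries (including the adjusted Rand index
against planted labels when present). Identical config + seed reproduces a
byte-identical artifact set; no timestamps enter any artifact.

Test and acceptance experiments use the study-scale defaults throughout:
482 plots, 15 features, 105 neurons, 5000 iterations; recovery statistics
aggregate 10 seeds, and cluster-count voting is additionally exercised on
105-point simplex-separated Gaussian codebook sets (pairwise center
separation 8 within-cluster sd). A full pipeline run takes on the order of
a second on a laptop-class CPU.

## Known limitations

* The SOM is online-only (no batch algorithm, no toroidal grids); results
  depend on presentation order and therefore on the seed.
* Equal layer weights treat one categorical component as comparable in
  influence to the whole numeric block divided by its column count; other
  weightings are supported but unexplored.
* The index battery is a 10-index subset; vote tallies are not comparable
  across batteries of different sizes.
* Area-under-polyline discards trajectory shape: distinct growth curves
  with equal areas are indistinguishable downstream.
* Resubstitution accuracy of the rule tree is not cross-validated.
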