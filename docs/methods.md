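# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `rarebiome`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Data model

An `OTUTable` is an integer read-count matrix (samples × OTUs). Rarefaction
draws each sample down to a common depth *without replacement*
(multivariate hypergeometric), the mothur/QIIME convention; the seed is
mandatory, expected counts are proportional to input composition, and OTUs
reduced to zero everywhere are retained so table axes stay aligned.
Relative abundances are row proportions of the rarefied table. Bray–Curtis
dissimilarity d(x,y) = 1 − 2Σ min(xᵢ,yᵢ)/(Σx + Σy) is computed on rarefied
counts by default; at uniform depth this equals the value on relative
abundances (0.5·L1 on proportions), so the choice is immaterial
post-rarefaction.

Environmental distance applies log(x+1) to every covariate except pH
(already a log-scale quantity), standardizes to zero mean and unit
*population* variance, and takes Euclidean distance. Geographic distance is
haversine on a sphere of radius 6,371 km; the computation is isolated so a
geodesic alternative can be swapped in.

Taxonomic aggregation sums counts over lineage prefixes. Unresolved ranks
are explicit `unclassified` placeholders; at a given rank, a trailing
unclassified run collapses onto its deepest resolved ancestor, so
unrelated unclassified taxa in different clades never merge. Per-sample
totals are conserved exactly at every rank. The finest unit ("species"
level in rank gradients) is the OTU itself.

## Synthetic metacommunity

`simulate_metacommunity` emulates the processed outcome of a
4-habitat × 4-season sediment survey: 16 samples at uniform depth 10,342
reads (defaults), ~10⁴ OTUs. The regional species-abundance distribution is
lognormal (meanlog 0, sdlog 2 — a heavy tail with few abundant and many
rare taxa, typical of 16S surveys). A fraction of OTUs (default 10%) are
specialists: their regional abundance is multiplied by `specialist_effect`
(default 10) in one home habitat, the vector renormalized, and counts drawn
multinomially. Environmental covariates (pH, salinity, TC, TN, TS, TP,
NH4-N, NOx-N) are habitat-specific means — field-plausible baselines times
a per-habitat lognormal factor — plus Gaussian noise, so environment is
collinear with vegetation, as in estuarine gradients. Taxonomy is a random
nested clustering into seven named phyla with ~20% of lineages unresolved
below family, exercising the aggregation rules.

What the generator does *not* emulate: phylogenetic signal in abundances,
temporal autocorrelation across seasons (seasons are exchangeable
replicates), spatially explicit dispersal, compositional sequencing
artifacts (chimeras, copy-number variation). Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
sampling model, not robustness to those real-data features.

`simulate_neutral` draws each sample's relative abundances from
Beta(Nmpᵢ, Nm(1−pᵢ)), renormalizes, and samples counts multinomially at
depth N. This is exactly the marginal distribution the Sloan fit assumes,
which makes it a clean parameter-recovery target; it is not a forward
birth–death simulation.

## Rarity partitioning

Thresholds are relative abundances: rare ⇔ always < 0.01%;
conditionally rare ⇔ sometimes < 0.01% but never ≥ 1%; abundant ⇔ the
literal complement. The complement also captures OTUs that are always
moderate (never < 0.01%, never ≥ 1%); their count is reported
(`never_abundant_count`) so users see how many "abundant" OTUs never reach
1%. OTUs absent from every sample classify as rare with a warning.
Summaries report per-category OTU and read counts with percentages of both
totals; sums are asserted to match the table exactly.

MultiCoLA truncates by whole-dataset relative abundance and scores
structural change as the Spearman rank correlation between the lower
triangles of the full and truncated Bray–Curtis matrices. Default cutoff
series: 0, 10⁻⁵, 2×10⁻⁵, 5×10⁻⁵, 10⁻⁴, 5×10⁻⁴, 10⁻³, 10⁻². A cutoff that
removes everything records an undefined correlation rather than raising.

## Diversity estimators

Chao1 is bias-corrected, S + F₁(F₁−1)/(2(F₂+1)); the classic variant is a
flag. ACE uses the standard rare/abundant split at 10 reads with the γ²
coefficient-of-variation term floored at 0; when every rare read is a
singleton the coverage estimate is undefined and NaN is returned. Shannon
and Pielou use natural log. Simpson is emitted both as concentration
D = Σp² and as Gini–Simpson 1 − D, since reporting conventions differ
between packages. Rarefaction curves are the analytic hypergeometric
expectation E[S(d)] = Σᵢ [1 − C(N−Nᵢ,d)/C(N,d)] evaluated in log-gamma
space — no resampling.

Group tests wrap scipy: one-way ANOVA; all-pairs t-tests with Bonferroni
multiplication capped at 1 and a compact-letters display computed as
connected components of non-significant pairs; Mann–Whitney U exact when
both groups have ≤ 8 untied values, otherwise the tie-corrected normal
approximation. Degenerate inputs follow the natural limits: identical
values everywhere give statistic 0 and p = 1; zero within-group variance
with distinct means raises, naming the groups.

## Habitat specialization

Levins breadth B_j = 1/Σᵢ P²ᵢⱼ uses P from *habitat means* of relative
abundance (seasonal samples averaged per habitat), because seasons act as
replicates of a habitat; a pooled-count alternative is a flag. B is clipped
to [1, n_habitats] against floating-point drift. Generalist/specialist cuts
default to B > 3 and B < 1.5. Both niche breadth and the indicator
analysis consider only OTUs with overall mean relative abundance ≥ 2×10⁻⁵
(taxa below that cannot be meaningfully profiled across habitats at these
depths); the floor applies to the mean over all samples.

IndVal follows the original Dufrêne–Legendre form: specificity
A = (group mean abundance)/(sum of group means), fidelity B = occurrence
fraction within the group, IndVal = max over groups of A·B, ties broken
toward the earliest group and flagged. Because A uses unweighted group
means of relative abundance, the input table must be rarefied; this is
asserted, not assumed. Significance is by permutation of sample-group
labels.

### Permutation conventions (shared by IndVal, ANOSIM, Mantel, RDA)

p-values use the add-one convention p = (b+1)/(m+1). When the number of
*distinct* labelings is ≤ 10,000 the full set is enumerated instead of
sampled; the observed labeling is skipped once during enumeration (it
enters through the +1), so a perfect indicator on a 2+2 design attains
p = (1+1)/(6+1). Sampled permutations are seeded and bit-reproducible.

## Ordination

NMDS minimizes Kruskal stress-1 by SMACOF iterative majorization with
monotone regression (scikit-learn's nonmetric MDS), run from `restarts`
random initializations plus one classical-scaling (metric) initialization;
the best embedding is kept and the result records whether the two best
restarts agreed within 0.01 stress.

ANOSIM uses Clarke's statistic R = (r̄_between − r̄_within)/(n(n−1)/4) on
mid-ranked dissimilarities, so R ∈ [−1, 1] with 1 meaning every
between-group dissimilarity exceeds every within-group one, and is
invariant under monotone transforms of the distances.

RDA centers the response (relative abundances by default; Hellinger is a
flag), builds the design by log(x+1)+standardization for quantitative
predictors (pH exempt) and dummy coding with one reference level dropped
for categoricals, prunes collinearity by iteratively dropping the worst
VIF until all ≤ 20, then optionally forward-selects: the candidate adding
the most explained variance is admitted while its partial permutation
p < 0.05 (reduced-model residuals permuted, Freedman–Lane style), stopping
at the first non-significant best candidate. If nothing is significant the
single best predictor is retained so the stage still reports a model, with
the selection path recording the failed test. Explained variance is
SS(fitted)/SS(total); the Ezekiel adjustment gives adjusted R²; canonical
axes come from the SVD of the fitted values; global significance is a
pseudo-F permutation test on response rows.

Variation partitioning computes adjusted R² for the seven unions of the
three blocks and solves the inclusion–exclusion system for the three pure,
three pairwise-shared and one triple-shared fraction; the residual is
1 − adjR²(full). The identity "fractions + residual = 1" is enforced
exactly; individual fractions can legitimately be negative (adjusted-R²
arithmetic). Pure fractions approximate single-block adjusted R² only up to
the difference in model-size penalties, which shrinks with n.

dbRDA Gower-centers the squared distance matrix, eigendecomposes, keeps
positive-eigenvalue axes scaled by √λ (negative eigenvalues are dropped by
default; a Lingoes-correction flag adds the constant instead), and runs
the same RDA pipeline on those coordinates — which are eigenvalue-weighted,
so explained variation is relative to retained inertia. With Euclidean
input distances this reproduces plain RDA exactly (tested to 1e-8). The
rank gradient aggregates the table from OTU to phylum and reports explained
variation per rank; a rank collapsing to a single taxon has no
compositional variation and reports NaN.

## Neutral community model

Under Sloan's model a taxon with regional relative abundance p has local
abundance Beta(Nmp, Nm(1−p)) at community size N (reads per sample after
rarefaction) and migration probability m; its expected detection frequency
above limit d is 1 − BetaCDF(d; Nmp, Nm(1−p)). The fit estimates m by
bounded least squares of observed occupancies on that curve over
m ∈ (10⁻⁶, 1], restarting the bounded optimizer on log-spaced
sub-intervals and keeping the best SSE (a 200-point log-grid check in the
tests guards against local minima). R² = 1 − SSE/SST on the occupancy
scale; equal weights by default, 1/p weighting by flag. The 95% envelope is
the Wilson score interval (z = 1.959964) around each predicted frequency
with n = number of samples, and taxa are flagged above/within/below.

**Detection limit.** Occupancy is scored from counts: a taxon at local
relative abundance x is detected with probability 1 − (1−x)^N, a smoothed
step whose half-point is x = 1 − 2^(−1/N) ≈ ln2/N. The model's sharp
threshold d is therefore set to that half-point by default. The common
one-read convention d = 1/N lies above the half-point and systematically
overestimates m under count-based presence scoring (about +25% at
N = 1,000 in the package's own recovery simulations, versus ~4% error for
the matched threshold); it remains available via `detection_limit=1/N`.
Note that predicted frequency is monotone in p always, and monotone in m
only for taxa with p > d — for p < d, strong migration pins local
abundance below the limit.

Per-rank fits aggregate counts (depth conserved) and refit; ranks with
fewer than 10 taxa are flagged low-confidence, and a rank where every
taxon occurs in every sample has no occupancy signal and reports NaN.

## Pipeline

`run_all` executes eight stages — simulate (or load), rarefy, rarity,
diversity, niche/indicator, ordination (NMDS/ANOSIM/Mantel), RDA/VPA/dbRDA,
NCM — writing TSVs and a manifest (version, config hash, per-stage seeds
and wall times). All randomness derives from one top-level seed via fixed
per-stage offsets, so repeated runs are byte-identical. Requested stages
write outputs; their prerequisites are computed in memory only. A stage
whose outputs exist under an unchanged config hash is skipped.

## Problem sizes in tests

The suite exercises recovery at deliberately modest sizes chosen to make
the statistical checks sharp yet quick: neutral-model recovery uses 50
samples × 2,000 OTUs at depth 1,000 over 10 seeds (median fitted m within
20% of the true 0.1); specialist recovery uses the 16-sample 4×4 design
with 2,000 OTUs at depth 10,000 over 5 seeds; the ANOSIM type-I check runs
50 replicates of a 300-OTU null community. Exhaustive-oracle comparisons
use ≤ 8 samples where full enumeration is feasible.

## Known limitations

* The RDA permutation test permutes response rows (and reduced-model
  residuals during selection); exchangeability under complex designs
  (e.g. restricted permutations within seasons) is not implemented.
* Forward selection treats each dummy column of a categorical predictor as
  a separate candidate rather than grouping the factor's columns.
* ACE is undefined (NaN) when all rare reads are singletons.
* The neutral fit assumes one regional pool for all samples; per-habitat
  pools must be fitted by subsetting the table.
* The Wilson envelope treats predicted frequencies as independent binomial
  proportions; it is a visualization/partitioning device, not a joint test.
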