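# Methods

`fungalscape` implements the post-clustering stages of a regional
soil-fungal metabarcoding survey: it starts from an OTU-by-sample count
table (clustering, chimera screening and read-level quality control are
upstream concerns of dedicated tools) and carries the data through sample
quality control, taxonomic and functional annotation, diversity and
abundance transforms, niche modeling, community-structure statistics and
co-occurrence analysis.  A synthetic-survey generator with full ground
truth closes the loop: every stage can be tested for exact recovery
without external data.

## The synthetic survey

The generator emulates the structure of a multi-year regional survey of
~10²–10³ plots.

**Environment.** Soil pH (KCl scale) is uniform over the configured
gradient (default 3.0–8.0, a typical boreo-nemoral span).  Calcium (and,
weakly, Mg) rise log-linearly with pH while C and hence C/N fall,
mimicking the calcareous-to-podzol covariance that makes variable
selection non-trivial; P, K, δ¹⁵N and δ¹³C are uncorrelated nuisance.
Tree basal-area proportions are Dirichlet draws with per-habitat
concentration profiles (forests conifer-heavy, parks broadleaf-heavy,
croplands nearly treeless); ectomycorrhizal (EcM) plant percentage is the
sum over EcM tree genera.  Plots get uniform coordinates on a
200 × 150 km rectangle, sampling dates spread over three years, and
collector labels from a pool of five.

**Counts.** Every OTU has a Gaussian realized niche on pH: expected
relative abundance ∝ `base · exp(−(pH − opt)² / 2w²)`, multiplied for
host-linked EcM OTUs by the host genus's basal-area proportion (zero host,
zero expectation).  Counts are multinomial at a lognormal depth clamped to
[504, 12763] reads; the default log-mean 7.675 and log-SD 0.483 give a
depth distribution with mean ≈ 2420 and SD ≈ 1240 reads.  Niche widths are
uniform on 0.6–2.0 pH units.  Niche *optima* are drawn over the gradient
extended by ±3 pH units: the regional species pool is wider than the
sampled window, which keeps the summed expected abundance approximately
flat across the gradient.  This matters: because counts are compositional,
a pool truncated at the window edges makes the denominator dome-shaped in
pH and shifts relative-abundance optima outward by up to ~1.5 pH units
relative to the truth optima, which would defeat parameter-recovery
testing for a reason that has nothing to do with the estimators.

**Artifacts.** A configurable fraction of samples (default 3%) is spoiled
by inflating one mold OTU of a randomly chosen thresholded group until its
within-sample share lies uniformly in (threshold, 0.9], with counts
rounded up so the share strictly exceeds the draw; a multi-OTU spoilage
mode spreads the inflation over 2–3 OTUs of the group.  Another 3% are
downsampled (hypergeometric) below the 500-read floor.  Control samples
alternate negative (≤ 50 reads of scattered noise) and positive (a fixed
8-OTU mock at ~1000 reads each).  Mold OTUs in unspoiled samples carry
damped base abundances and broad niches so that background mold shares
stay far below the flagging thresholds — spoilage detection is tested
against injected signal, not against accidental background exceedances.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about field data: taxonomic misassignment in the reference
database, tag-switching and chimeras, spatial autocorrelation of community
composition (off by default; a flag exists but no strength is assumed),
collector- or season-biased mold prevalence, and non-Gaussian (skewed or
bimodal) niches.

## Quality control

The filter chain runs in a fixed order with full provenance (samples,
sequences, OTUs and removed IDs recorded per stage): (1) remove control
samples; (2) remove samples with < 500 reads; (3) remove blocklisted OTUs;
(4) remove samples emptied by stage 3; (5) profile molds and remove
spoiled samples.  Mold profiles are computed per sample for four groups —
Mortierellales, Umbelopsidales, Mucorales, and mold-forming Pezizomycotina
— as both the group's summed share and the share of its single most
abundant OTU, with whole-sample totals as denominators.  The removal rule
is strict `>` on the per-sample maximum OTU share: 0.30 for Pezizomycotina
molds, 0.15 for Umbelopsidales and Mortierellales.  Mucorales is profiled
and exported but never a removal criterion (its spikes are informative,
e.g. in croplands, rather than diagnostic of spoilage).  Group-share
thresholding exists behind a flag but is off by default, and the
per-sample share of each group's *globally* dominant OTU is exported as a
covariate rather than used for removal.  The chain is idempotent.  Gates
for per-guild analyses (≥ 20 OTUs of the guild per sample; optionally
≥ 100 reads for obligate-mutualist analyses) are provided separately.

## Taxonomy and function

Rank thresholds (similarity %, e-value): kingdom (70, 1e-20), phylum and
class (75, 1e-50), order (80), family (85), genus (90).  Only similarity
bounds are customarily quoted for order/family/genus; the class-level
e-value bound is inherited there, which is conservative and keeps the
criteria monotone.  Both comparisons are strict.  Among threshold-passing
hits carrying a non-empty label at the rank, any disagreement —
operationalized as more than one distinct label, not a majority vote —
leaves the rank unassigned, and unassignment propagates to all deeper
ranks.  Hits with partially empty taxonomy paths count only at ranks where
they carry labels.  Hit order is taken as given in the input; no
re-sorting.

Functional annotation is a genus-keyed lookup (guild; EcM lineage and
exploration type for EcM genera; mold group for the four mold clades).
Genera flagged as multi-lifestyle require a species-level override row;
without one the guild stays unassigned.  Exploration types are treated as
phylogenetically conserved at genus/lineage level and stored per OTU for
convenience.

## Transforms and diversity

- **Anchored log-ratio of a percentage**: `log10((p + 0.01)/(100 − p + 0.01))`,
  the only offset placement that reproduces all three anchors 0% → −4,
  50% → 0, 100% → +4 to < 5e-5.  Antisymmetric about 50%.
- **Hellinger**: square root of within-sample relative abundance; rows are
  unit vectors in the squared sense.
- **Shannon**: natural log by default (base exposed as an option).
- **Depth-residual richness**: richness is regressed (OLS, intercept) on
  √depth and separately on ln depth; the residual is the average of the
  two raw (unstandardized) residuals.  Each single regression
  overestimates residual richness at one end of the depth range; averaging
  compensates.  Constant depths collapse both fits to the intercept, i.e.
  mean-centering.  Residuals sum to zero and are location-invariant.
- **Rarefaction** is the analytic hypergeometric expectation
  `E[S(m)] = S − Σᵢ C(N−Nᵢ, m)/C(N, m)` evaluated with log-gamma
  arithmetic, not resampling.  Pooled mode (default) rarefies the summed
  community; per-sample mode averages per-sample expectations.  The
  singleton-exclusion mode zeroes counts of 1 *within each sample* before
  pooling, discarding locally rare OTUs that may be index-switching
  artifacts.

## Niche models

Variable preselection fits a random forest (999 trees; mtry = p/3 and
minimum leaf size 5, the customary regression-forest settings) to the
candidates plus a label-shuffled decoy copy of each, scoring candidates by
permutation importance in mean-MSE-increase units.  A candidate is
selected when it beats the largest decoy importance in all of three
decoy-shuffle iterations **and** its importance exceeds 0.15 × Var(y).
Both guards were calibrated against the method's own null behaviour: with
a single iteration, the largest real importance beats the largest decoy
about half the time under a pure-noise response (the maxima are
exchangeable); and because a spuriously y-correlated noise column stays
"informative" across iterations while decoys are re-shuffled, iteration
alone is not enough — measured null importance maxima reach 0.04–0.12 ×
Var(y), whereas genuine niche signal in the synthetic surveys sits at
0.2–1.4 × Var(y).  The floor therefore sits above the null range and well
below the signal range.  The cost is deliberate conservatism: predictors
explaining ≲ 7% of response variance will usually not be selected.  A
plain top-k mode bypasses both guards.

Selected predictors are standardized (mean 0, SD 1) and fit one at a time
by quadratic least squares `y = b0 + b1·x + b2·x²`; per-predictor R² is
the squared correlation of fitted and observed values (×100), and a
combined additive model of all selected quadratic terms gives the joint
R².  Response shapes are classified at α = 0.05 on the coefficient
t-tests, with the vertex judged against the observed 5th–95th percentile
range: insignificant curvature → positive/negative/flat by the linear
term; concave with an interior vertex → unimodal; concave with the vertex
beyond the 95th percentile and a positive low-end slope → saturating
(rise-then-plateau); concave with the vertex below the 5th percentile →
negative; convex mirrors to U / positive / negative.  A sigmoid class
cannot be produced by a quadratic and is deliberately not emitted.  No
multiple-testing correction is applied within a model;
Benjamini–Hochberg across responses is available as a flag.  Per-OTU
niche models use the anchored log-ratio of the OTU's percentage of the
sample total as response and skip OTUs present in fewer than a
configurable number of samples (default 20).

## Community structure

Bray-Curtis dissimilarity is computed on (typically Hellinger-transformed)
abundances.  PERMANOVA partitions the Gower-centered inner-product matrix
with sequential (type-I) sums of squares in the user's term order by
default — matching stepwise model-building narratives — and marginal sums
of squares behind ``ss_type='marginal'``.  Sequential term R² values plus
the residual sum to 100%; marginal ones need not, under collinearity.
Each term's pseudo-F uses the full-model residual, and p-values come
from free row permutations, `p = (#{F* ≥ F} + 1)/(n_perm + 1)`, with a
relative tie tolerance of 1e-9 so permutations reproducing the observed
statistic count as ties.  Exhaustive enumeration replaces sampling for
n ≤ 9.  On Euclidean distances of a univariate response with a two-level
factor the pseudo-F equals the classical ANOVA F to 1e-8.  Permutations
are unrestricted; a strata option is left for future work.

Moran eigenvector maps use the classical PCNM construction: truncation at
the longest minimum-spanning-tree edge (guaranteeing connectivity),
distances beyond it replaced by 4t, Gower centering, eigendecomposition,
and retention of positive-eigenvalue vectors in descending order (coarse
to fine waves; on a regular transect successive vectors show 1, 2, 3, …
sign changes).  Temporal distances pool the slow seasons before
differencing — February–April to mid-March, November–January to
mid-December (January joins the preceding year's pool) — then take
absolute day differences.  Plant-phylogeny community distances are
comdist (mean pairwise patristic), comdistnt (mean nearest-taxon, averaged
in both directions) and PhyloSor dissimilarity
(1 − shared branch length / mean total branch length), all on a
user-supplied ultrametric-capable Newick tree.

NMDS minimizes Kruskal stress-1 by SMACOF with pool-adjacent-violators
monotone regression, best of 20 random starts by default.  Environment
vectors are fit to ordination scores by least squares with permutation
p-values; constant variables are skipped with a warning.

## Co-occurrence

The pairwise C-score is `(Rᵢ − S)(Rⱼ − S)`.  Null matrices preserve both
margins through a trial-swap chain: each step picks a random 2×2
sub-matrix and swaps it if it is a checkerboard.  The kernel is symmetric,
so the stationary distribution is uniform over the margin-preserving set
(verified against exhaustive enumeration on small margin classes).
Defaults: 30 000 attempted swaps of burn-in, 1 000 between samples, 999
null matrices; step counts refer to *attempted* swaps.  SES =
(obs − null mean)/null sd with the two-tailed permutation p; SES > 0 means
segregation (avoidance), SES < 0 aggregation.  When the margin class
admits no checkerboard rearrangement affecting a pair, the null collapses
(sd = 0); such pairs are flagged with undefined SES and p = 1 rather than
silently reported.  Presence means count ≥ 1 after QC by default
(threshold configurable).

## Problem sizes and numerical notes

The test suite exercises the pipeline at 80–300 plots and 10–400 OTUs with
999-tree forests, 199–2000 permutations/nulls, and 20-seed repetition for
the stochastic recovery benchmarks; these sizes were chosen so the full
suite completes comfortably on a single core while keeping every
statistical check at meaningful power.  Degenerate inputs are defined
errors rather than silent NaNs: zero-total samples are rejected by the
Hellinger, Shannon and mold-profile routines (depth-filter first),
saturated PERMANOVA designs and single-level factors raise, and a
constant response yields exact zero slopes with flat shape rather than
spurious significance from zero residual variance.

## Known limitations

- Variable selection is conservative by design (see the importance floor);
  weak genuine predictors are sacrificed for a controlled null.
- Sequential-only PERMANOVA sums of squares; no restricted permutations.
- The traits lookup shipped for the generator is a small synthetic table,
  not a curated database; real analyses should supply their own traits
  TSV.
- The swap chain's mixing time grows with matrix size; the defaults are
  calibrated for the few-hundred-sample, few-dozen-OTU scale of the
  co-occurrence analyses it is meant for.
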