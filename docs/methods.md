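# Methods

This note documents the models implemented in `assemblyscope`, the
numerical conventions they follow, what the synthetic-data generator
does and does not emulate, and the design choices made where the
methodology is genuinely open.

## Data model

All analyses operate on a **count table** (samples × taxa, non-negative
integers, unique ids, no empty samples), an optional **rooted
phylogeny** with branch lengths whose tips cover the table's taxa, and
per-sample **metadata**. Matrices are indexed by id, never by position;
taxon and sample order is preserved from input. Rarefaction is a single
multivariate-hypergeometric draw per sample (without replacement) from
one seeded generator in sample-id order; samples below the target depth
are dropped, not resampled upward. Basal polytomies are treated as
unrooted input and rejected unless midpoint rooting is requested
explicitly.

## Diversity

Shannon entropy uses natural log by default (a `log_base` argument is
provided). Faith's PD includes the root-to-subtree stem by default
(rooted convention, toggleable). Bray–Curtis operates on counts as
given — appropriate after rarefaction — with an optional per-sample
normalisation. βMNTD is abundance-weighted by default:

    βMNTD_ij = ½ [ Σ_k f_ik · min_{l ∈ j} d_kl + Σ_k f_jk · min_{l ∈ i} d_kl ]

with `f` the relative abundance (or 1/richness unweighted) and `d` the
patristic distance. A taxon shared by both samples is its own nearest
neighbour (distance 0); conspecifics are not excluded. The weighting
default is a package decision — the convention is not universal — and
an unweighted variant is exposed for sensitivity analyses.

## Null models and process classification

**βNTI** standardises observed βMNTD against a null in which tip labels
are shuffled across all tips of the matched tree (abundances untouched):

    βNTI = (βMNTD_obs − mean(βMNTD_null)) / sd(βMNTD_null)

One shared permutation ensemble (seeded by the global seed) serves all
sample pairs, so results are independent of pair ordering and the cost
is O(n_null) rather than O(n_null · n_pairs). Pairs with zero null
spread (e.g. equidistant-tip geometries, or fully shared communities)
are undefined, reported as missing, and excluded from classification
with a separate count.

**RC_bray** compares the observed Bray–Curtis dissimilarity of a pair
against null community pairs that fix each sample's observed richness
and total abundance. Taxa enter a null sample without replacement with
probability proportional to dataset-wide occupancy (Gumbel top-k
sampling), receive one individual each, and the remaining individuals
are allocated multinomially in proportion to dataset-wide relative
abundance:

    RC_bray = 2 [ #(BC_null < BC_obs) + ½ #(BC_null = BC_obs) ] / n_null − 1

Ties count half so the statistic is centred under its own null. Each
pair has an independent seed stream derived from (global seed, pair
index). Occupancy and abundance weights default to the whole analysed
table ("regional pool" semantics); a different pool table can be
passed.

**Classification** follows the usual five-way rule set: βNTI > 2 →
variable selection; βNTI < −2 → homogeneous selection; otherwise
RC_bray > 0.95 → dispersal limitation; RC_bray < −0.95 → homogenizing
dispersal; else undominated. Boundary values (exactly ±2 or ±0.95) are
non-significant. The stochastic fraction is the sum of the last three
categories. Fractions are reported both as floats and as exact
rationals of the pair counts. `n_null` defaults to 999; at least 99 is
required for classification use.

## Stochasticity measures

**NST.** Observed dissimilarity D (Bray–Curtis default, Jaccard
optional) is compared with the mean dissimilarity E of null pairs drawn
by the same richness/occupancy/abundance-constrained engine as RC_bray.
Selection strength is

    SS = (D − E)/(1 − E)  if D ≥ E,    SS = (E − D)/E  otherwise,

and NST = 1 − SS per pair; the group value is the arithmetic mean over
within-group pairs, in percent, with 50% the conventional
deterministic/stochastic boundary. Null weights come from each group's
own samples by default (a group is judged against its own species
pool), with a whole-table option. Pairs whose null expectation is
degenerate (0 or 1) are excluded with a warning. The published
description of the NST pipeline this mirrors does not state a formula
("based on the phylogenetic distance"); the normalized ratio above with
the proportional null is this package's documented reconstruction, and
the metric is pluggable precisely because that choice is not
recoverable from the text.

**Sloan neutral model.** A taxon with metacommunity mean relative
abundance p has stationary local abundance Beta(Nm·p, Nm(1−p)); its
predicted occurrence frequency at detection limit d is
F(p) = 1 − I_d(Nm·p, Nm(1−p)). Nm is fitted by bounded scalar least
squares on log Nm over [10⁻³·N, 10⁶] (N = mean total counts, d = 1/N by
default and overridable); R² = 1 − SS_res/SS_tot on the frequency
curve; the 95% band is the Wilson interval of the predicted frequency
at the realised sample count, and each taxon is flagged inside, above
or below it.

**Levins' niche breadth.** B_i = 1/Σ_j q_ij² for taxon i's distribution
q across samples (1 = confined to one sample, up to the number of
samples when uniform); Bcom is the unweighted mean over taxa.

**Phylogenetic-signal correlogram.** Niche values are abundance-
weighted means of z-scored environmental variables; taxon-taxon niche
distance is Euclidean; taxa in fewer than two samples are excluded.
Phylogenetic distances are cut into equal-width classes (Sturges
default; classes under 30 pairs dropped, configurable) and each class
gets a Mantel correlation between the niche-distance matrix and the
class indicator, sign-flipped so that positive values at short
distances mean close relatives share niches. P-values come from
two-sided taxon-label permutations with progressive Holm correction
(shortest class corrected first). Two-sided permutation keeps the
type-I error at the nominal level, which the calibration test verifies
directly.

## Co-association networks

Counts are square-root transformed and taxa detected in at most half
the samples are removed (majority rule); Pearson correlation (Spearman
optional) gives the taxon-taxon similarity matrix. The similarity
threshold St is chosen by random-matrix theory: for each candidate
threshold the matrix is sparsified, its eigenvalue nearest-neighbour
spacing distribution (NNSD) computed — degenerate eigenvalues are
collapsed first, spacings are locally unfolded with a 5-point moving
mean, and spacings binned on [0, 3] in 20 bins — and tested against the
Poisson form e^(−s) by chi-square. St is the smallest threshold whose
NNSD is Poisson-consistent (p > 0.05): below it the matrix retains the
Wigner–Dyson level repulsion of correlated noise, at it only block
structure remains. Spectra with fewer than 20 informative spacings are
treated as structure-free. With fewer than ~30 nodes a warning flags
RMT as unreliable.

The network keeps edges with |r| ≥ St, signed by the correlation;
isolated nodes are dropped. Modules come from deterministic greedy
(CNM) modularity maximization weighted by |r| (node ids pre-sorted, so
results are reproducible); reported modularity Q is Newman's unweighted
Q of that partition. Topology metrics: avgK = 2E/N; average clustering
with degree<2 nodes contributing 0; average path distance over
connected pairs only; diameter within components; density; geodesic
efficiency as the mean of 1/d over ordered pairs (unreachable pairs
contribute 0, so it is defined for disconnected networks); harmonic
geodesic distance as its reciprocal; and Freeman centralizations of
degree, betweenness, and stress (shortest-path counts through a node),
each normalised by the star-graph maximum. Zi is the within-module
degree z-score (module sd 0 → Zi = 0), Pi = 1 − Σ_m (k_im/k_i)², and
roles use the conventional thresholds (network hub: Zi > 2.5 and
Pi > 0.62; module hub: Zi > 2.5; connector: Pi > 0.62; else
peripheral). The random reference is Maslov–Sneppen degree-preserving
rewiring (10·E swaps per replicate) with average clustering, average
path distance, and modularity reported as ensemble mean (sd).

## Synthetic communities

The generator provides ground truth for every stage. Yule trees
(pure-birth, unit rate, deterministic from one seed) carry a Brownian
trait whose divergence can be concentrated on deep branches by a
Pagel's-delta-style depth exponent (default 0.2), so that trait
extremes coincide with clades rather than with convergent tips — the
substrate for phylogenetically conserved preferences. Metacommunity
abundances follow a log-series (theta = 0.995).

* **Neutral**: local relative abundances are Dirichlet(N·m·p) draws —
  the stationary law of the Sloan model, whose marginals are exactly
  Beta(Nm·p, Nm(1−p)) — followed by a multinomial of N individuals.
  Defaults N = 5000, m = 0.3.
* **Selection** (homogeneous/variable): a Gaussian filter of width σ
  (default 0.25 trait-sd) around per-sample optima sets expected
  abundances from trait matching alone; sparse Dirichlet drift
  (concentration 20) decides which viable taxa dominate each sample;
  immigrants (2% of individuals, proportional to the metacommunity
  SAD) arrive as a thin post-drift layer that keeps the regional pool
  observable without drifting to dominance. Homogeneous selection
  shares one optimum (all samples select the same clade); variable
  selection spreads optima along a gradient. Because the regime is
  defined by selection *for* a conserved preference, the generator
  conditions the trait realization on exhibiting one: several Brownian
  draws are scored by the phylogenetic coherence of their best filter
  window (mean nearest-neighbour patristic distance of the window's
  taxa relative to equal-sized random sets, window restricted to 5–30%
  of taxa), and the most coherent draw and optimum are used. Selection
  runs default to smaller local communities (N ≈ 800–1000): sparse
  occupancy against a broad observed pool is where nearest-taxon
  statistics have power, mirroring the low per-sample occupancy of
  real OTU tables.
* **Dispersal limitation**: neutral dynamics with sample clusters
  drawing from independently shuffled metacommunities.

`simulate_study` arranges four cells (2 sites × control/N-addition,
default 6 samples each) on one shared tree, one shared metacommunity
and one shared conserved trait, so taxa keep consistent identities and
realized niches across cells. Default cell regimes make N addition at
the short-term site more neutral than its control (and mirror it at
the long-term site), reproducing the qualitative contrast the design
targets. Selection cells receive small per-sample environmental jitter
(0.15 trait-sd) so realized niches vary measurably within a cell; soil
covariates (pH, NO3-N) are linear functions of the per-sample optimum
plus small measurement noise, with an additive pH depression (−0.1)
and a relative NO3-N increase (+56%) in N-addition cells.

**What the generator does not emulate.** Sequencing error, chimeras,
compositional artefacts of relative-abundance data, taxon-specific
detection biases, temporal dynamics, and guild structure are all out of
scope. Purely neutral cells carry no realized-niche signal at all, so a
dataset-level phylogenetic correlogram over a mixed study is weaker
than in field data where every sub-community experiences some
filtering; correlograms are therefore computed per sub-community.
Passing tests demonstrate that the statistics recover known regimes
under these idealised conditions, not that any particular field
community obeys them.

## Problem sizes and runtime conventions

Development-scale defaults were chosen so the full test suite and the
acceptance script run on a single CPU in minutes: regime-recovery
experiments use 1000-tip trees with 8 samples per regime and 199-draw
null ensembles (the 99-draw minimum that classification requires is
respected everywhere); the simulated study uses 600 taxa with 6–12
samples per cell; oracle comparisons use exhaustive enumeration (120
tip permutations) or 10⁵ independent draws on toy tables. All
randomness flows from explicit integer seeds; per-stage pipeline seeds
are derived from the global seed by hashing the stage name, so
upstream results never depend on downstream parameters.

## Known limitations

* βNTI power depends on per-sample occupancy relative to the observed
  pool; dense tables (most taxa in most samples) yield attenuated
  z-scores because shared taxa contribute zero under any tip shuffle.
* The RMT unfolding is a documented reconstruction (local 5-point
  unfolding, dedup of degenerate levels); other unfolding choices can
  shift St by a few hundredths.
* The NST variant implemented here is one member of a family; absolute
  NST values are comparable only within a fixed null configuration.
* Greedy modularity is deterministic but can merge small modules that
  annealing-style optimisers would separate; module counts are
  therefore not comparable across algorithms.
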