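# Methods

This note records the models, conventions and numerical choices behind
`commsig`, the reasoning where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real surveys.

## Data model and conventions

Count tables are taxa × samples with taxa as rows (the common ASV-table
export orientation; a transpose flag handles the other dialect). Counts are
read as non-negative reals; rarefaction re-validates integrality. Taxa
present in the table but absent from the tree are a hard error; extra tree
leaves are only removed under an explicit prune flag, so data are never
dropped silently. Trees must be rooted (bifurcating root); any root-edge
length in the Newick is zeroed on read, since a branch above the root has
no parent and would otherwise leak arbitrarily into PD and UniFrac.

The rare biosphere is defined as taxa whose study-wide relative abundance
(taxon total over grand total of the count table) is strictly below 0.01%;
the boundary case is excluded because the definition is "less than".
Trophic subsetting accepts a two-label map (`chloroplast_containing`,
including mixotrophs, vs `heterotroph`); unmapped taxa fall outside both
subsets and are counted in a warning rather than silently assigned.

## Environmental analyses

Variables are standardized with the sample (n−1) standard deviation; a
constant variable maps to all-zero z-scores with a warning. Euclidean
distances between stations use pairwise deletion for missing values
(comparing each pair only on variables observed in both), matching the NA
behaviour of the common R distance routines. Caveat: under pairwise
deletion distances computed over different variable subsets are not
strictly comparable; this mirrors the upstream tools rather than fixing
them. The linkage criterion for station clustering is complete linkage by
default (the default of the common heatmap/clustering tools); it is a
config option, since nothing in the analysis depends on it structurally.
Group contrasts use Welch's unequal-variance t with Satterthwaite degrees
of freedom.

## Alpha diversity and community phylogenetic structure

Rarefaction draws a multivariate hypergeometric subsample per sample
(without replacement), to an even depth; samples below depth are dropped
with a warning. SR, Faith's PD and Simpson (1 − Σp²) are averaged over
iterations (default 100).

Faith's PD is the branch length of the minimal subtree spanning the
sample's taxa *and the root* (the convention of the common phylogenetic
diversity toolkits; a flag selects the crown-group variant). PD, its
null models and the rarefaction loop are all evaluated against a
precomputed branch × taxa incidence matrix, which turns repeated tree
traversals into matrix products; an O(n²) patristic distance matrix is
likewise precomputed once per tree. Both choices trade memory for speed
and are comfortable at survey scale (10³–10⁴ taxa).

MPD is abundance-weighted: MPD = Σ_{i≠j} δ_ij f_i f_j / Σ_{i≠j} f_i f_j.
The NRI null randomizes each sample's relative-abundance vector across
**all** taxa of the tree (a taxa-label shuffle preserving the abundance
multiset), 1000 draws by default; SES = (obs − null mean)/null sd and
NRI = −SES. "Randomised" is ambiguous in common usage — shuffling over the
full taxon pool vs only the taxa present in a cluster — so both are
available, with the full-pool shuffle as the documented default (it is the
taxa-labels null of the standard community-phylogenetics packages). A
degenerate null (sd = 0, e.g. a star phylogeny) yields NaN with a warning,
never ±inf. SES of Faith's PD uses a richness-preserving random-leaf null.
Per-cluster NRI is computed per sample and averaged within clusters.

## Beta diversity, ordination and group tests

Bray–Curtis, unweighted UniFrac (unique/total branch length over the pair's
union) and weighted UniFrac (branch-wise absolute difference of abundance
proportions, normalized by default, matching the cited implementation's
default) are computed through scikit-bio/scipy and are cross-checked in the
test suite against naive branch-by-branch oracles to 1e-10.

NMDS minimizes Kruskal stress-1 over isotonic fits, taking the best of 20
starts (19 random plus one classical-scaling start); stress and convergence
are reported. PERMANOVA is the one-factor pseudo-F on squared distances
with p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm) under label permutation; the
(1+b)/(1+m) estimator is used for every permutation p in the package so a
p-value is never exactly zero. Which distance matrix fed the group tests
is configurable; weighted UniFrac is the default, as the matrix used for
the headline community partition. PERMDISP embeds samples by principal
coordinates retaining negative eigenvalues, measures each sample's
distance to its group's spatial median (centroid optional) combining real
and imaginary axes as sqrt(|d²_real − d²_imag|), and applies a classical
one-way ANOVA to those distances.

UPGMA ties are broken deterministically by smallest label index. The
consensus tree repeats rarefy → distance → UPGMA (defaults 20,000 reads,
1000 iterations), keeps rooted clades occurring in more than half of the
iterations (majority rule guarantees mutual compatibility) and reports
each clade's frequency as its support. The consensus is computed over
rooted clades rather than unrooted bipartitions because dendrograms are
rooted objects.

## Spatial pattern

Geographic distances are great circles on a sphere of radius 6371.0088 km,
in km — the scale on which a distance-decay slope per km over a
~10³ km study extent is dimensionally sensible. Distance-decay fits
dissimilarity = exp(a + b·distance) as a Gaussian GLM with log link (the
convention of the standard distance-decay fitting tools); fitting
similarities 1 − d instead is a flag. Significance permutes the sample
identities of the community matrix (rows and columns together), refits,
and compares |b|. MRM regresses the unfolded lower triangle of the
response on the predictors' triangles by OLS; the overall F and each
coefficient's pseudo-t are referred to their distributions under
simultaneous row/column permutation of the response matrix. Collinear
predictors are a hard error (singular fit).

## Non-smooth NMF and the signature index

nsNMF interposes S = (1−θ)I + (θ/q)11ᵀ between basis and coefficients and
minimizes KL divergence by multiplicative updates: H is updated against
the effective basis WS and W against the effective coefficients SH, so
each half-step is a standard KL update and the objective is monotonically
non-increasing (asserted in tests at every iteration). θ defaults to 0.5,
the default of the reference nsNMF implementations. Initialization is
uniform random scaled to √(mean(V)/q); convergence is declared at a
relative objective change below 1e-6 (cap 2000 iterations). V is raw
counts by default (relative-abundance mode available); with equal sample
depths the two differ only by a global scale. Multi-run fitting (default
200 runs; rank selection surveys ranks 3–7 at 100 runs) keeps the
best-objective fit and additionally reports the per-run objectives and the
mean adjusted-Rand agreement of each run's dominant-descriptor sample
partition with the best run's; the rank survey reports the cophenetic
correlation of the run-consensus co-assignment matrix per rank, leaving
rank choice to the analyst.

For the index, "normalized" profiles are L2 unit vectors — the only
normalization under which Σ_j a_{i,j} s_{k,j} is literally the cosine of
the angle between the profiles (an L1 option exists). ρ uses average ranks
for ties; a constant taxon profile has no rank order, so ρ is set to 0
with a warning (such a taxon can never be a signature). p(i,k) comes from
raw basis rows normalized to sum 1; an all-zero basis row gets Score 0
with a warning. Signature selection is per descriptor — strictly greater
than mean + 3 sd, with the sample (n−1) sd over all taxa in that
descriptor's index column — because the defining distributions are
per-descriptor.

### Behaviour of the 3-SD rule under dense planting

A property worth knowing: the 3-SD threshold is computed over a column
that *contains* the signature block itself. When a large fraction of taxa
are genuine signatures of one descriptor, the block inflates the column's
sd until the threshold climbs into (or above) the block, so selection
keeps only its extreme top. In the default synthetic recovery experiment
(10 planted signatures per descriptor among 200 taxa = 5% per column, 20%
overall) precision and the sample-partition ARI are 1.0, but recall of the
planted set plateaus around 0.4–0.8: thresholds land at ~0.6–0.87 while
the Spearman factor of a taxon confined to 6 of 24 samples is capped near
0.8–0.9 (out-of-group ranks carry no signal), so the planted block cannot
escape upward. Real surveys are gentler — proportionally about half as
many signatures per taxon pool — but the effect is intrinsic to
thresholding a column on moments it dominates. The index table always
contains the full ranking, which is robust; the 3-SD cut is the
conservative headline rule.

## Synthetic data generator

The generator emulates a multi-habitat amplicon survey at desk scale:

- **Taxon pool**: per-taxon baseline abundances are log-normal with
  log-sd 4.0, chosen so that about four fifths of taxa fall below 0.01% of
  the grand total — the rare-biosphere share typical of marine 18S surveys
  (roughly 1200 of 1450 taxa).
- **Depth**: 5000 reads per sample for 200 taxa (~25 reads per taxon per
  sample), the depth-to-richness regime of a survey rarefied to 25,000
  reads over ~1450 taxa.
- **Signatures**: each group gets disjoint planted signature taxa whose
  baseline is multiplied by 20 within the group's samples. Planted taxa
  are drawn from the expected non-rare pool (expected study-wide share
  ≥ 0.01%): habitat-characteristic taxa are by definition detectable
  within their habitat, and in real surveys the signature and
  rare-biosphere analyses partition the taxa.
- **Counts**: Multinomial(depth, p) per sample; an overdispersion knob
  adds Gamma noise to the expected proportions when heavier-than-
  multinomial noise is wanted.
- **Assembly modes** per group: *random* (all taxa active), *clustered*
  (the group's non-signature pool is the smallest adequate clade's tips),
  and *overdispersed* (a greedy **maximin** patristic selection — the most
  distant pair first, then always the tip farthest from the chosen set).
  Maximin rather than max-sum: a summed-distance greedy piles picks onto
  the extremes of two clades and leaves close sister pairs in the pool.
  In overdispersed mode, abundance rank within the pool follows the
  maximin pick order, so the community's *dominant* taxa are the most
  mutually distant — the competitive-exclusion signature that
  abundance-weighted MPD can actually detect. Without this coupling the
  observed weighted MPD reduces to the distance of one arbitrary pool
  pair and the NRI sign is noise.
- **Metadata**: environmental variables are group means (a cyclic subset
  of variables shifted by 2 sd per group) plus unit Gaussian noise;
  station coordinates are jittered around Beaufort-Sea-like cluster
  centres a few hundred to ~1500 km apart, so distance-decay is
  estimable.

Everything is deterministic given the seed, and the planted truth
(signature sets, assembly modes, environmental means, centres, active
pools) is returned and serialized for recovery scoring.

**What passing tests show — and don't.** The generator provides planted,
exactly-known structure under multinomial sampling. It does not emulate
compositional correlations between taxa, chimeras or sequencing error,
taxonomically realistic name structure, read-depth variation between
samples, or spatially continuous environmental gradients. Recovery results
therefore demonstrate the correctness and statistical calibration of the
estimators under the stated model, not field performance on any particular
real survey.

## Problem sizes used in the checks

The test suite and acceptance script run at desk scale by the package's own
choice: 200-taxon trees, 24-sample surveys, 5000 reads per sample, 20 NMF
runs for recovery experiments, 1000-draw NRI nulls, 50 replicates for sign
recovery, and 1000 null simulations for type-I-error calibration of
PERMANOVA and MRM at α = 0.05. Oracle-equivalence checks compare Faith's
PD, weighted MPD, both UniFracs, Bray–Curtis, UPGMA and the full taxon
index against naive reimplementations on ≥100 random instances at 1e-10
relative tolerance.

## Known limitations

- PERMANOVA is one-factor only (no strata, no multi-way designs).
- The distance-decay GLM assumes Gaussian error on the (dis)similarity
  scale; pair non-independence is handled by permutation, not by the
  likelihood.
- nsNMF multiplicative updates converge to local optima; the multi-run
  protocol mitigates but does not eliminate this, and the rank survey is
  diagnostic, not decisive.
- The NRI full-pool null conditions on the realized abundance multiset;
  alternative nulls (e.g. within-pool shuffles) answer different
  questions and can change signs near zero.
- Subset re-analyses (trophic, rare biosphere) prune the tree to the
  subset's taxa; SES-type statistics are then relative to the pruned pool,
  not the full survey pool.
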