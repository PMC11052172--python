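# Methods

This note documents the models implemented in `enteroassembly`, the
numerical and design choices behind them, what the synthetic generators do
and do not emulate, and known limitations.

## Preprocessing

The canonical order is **filter → rarefy** for ASV-level analyses and
**filter → rarefy → genus aggregation** for enterotyping.  The
low-abundance filter removes ASVs whose count pooled over *all* samples is
strictly below `min_total` (default 5); a taxon sitting exactly on the
threshold is kept.  Rarefaction is a single seeded multivariate-
hypergeometric draw (subsampling reads without replacement) to the
shallowest sample's depth; we deliberately do not average repeated
rarefactions — the draw's seed is recorded in every output's provenance
header, which we consider the more reproducible convention.  Both orders
(filter-first or rarefy-first) are available via `filter_before_rarefy`;
filter-first is the default.  Genus aggregation sums counts exactly
(integer arithmetic), pooling unassigned ASVs under `g__unassigned`.
Tree/table reconciliation is an explicit step that prunes each side to the
shared taxa and reports the counts, never a silent coercion.

Missing newick branch lengths become 0 with a warning; negative branch
lengths are a hard error.

## Enterotyping

Samples are clustered with k-medoids on genus-level Bray–Curtis
dissimilarities.  When the number of candidate medoid sets C(n, k) is at
most 20 000 the globally optimal medoid set is found by enumeration; larger
problems use the deterministic BUILD+SWAP heuristic.  The exact branch
exists because BUILD+SWAP can terminate in a swap-local optimum even on
ten-point instances, and at the scales where enterotyping is typically
model-selected (≈100 samples, k = 2–6) exactness is affordable for the
small k where it matters most.  Ties are broken by lowest index, so
results are reproducible without a meaningful seed.

The number of clusters is the k in `[k_min, k_max]` maximizing the
Calinski–Harabasz pseudo-F, computed on the principal-coordinate embedding
of the distance matrix over all positive-eigenvalue axes (the standard
enterotype-tutorial practice); a distance-only PERMANOVA-style pseudo-F is
available via `criterion="pseudo_f"` for sensitivity analysis.  CH ties go
to the smaller k (parsimony).  A zero within-cluster dispersion reports the
sentinel `1e12` rather than infinity.  Silhouette widths (singletons score
0) are reported alongside but never drive selection.

ANOSIM uses R = (r̄_between − r̄_within) / (M/2) on rank-transformed
distances with label permutations and the estimator
p = (1 + #{R_perm ≥ R_obs}) / (1 + n_perm), so p is never exactly 0.

## Diversity and contrasts

Shannon entropy is reported in nats (base-2 via a flag); "Simpson" means
Gini–Simpson 1 − Σp², with inverse Simpson behind a flag.  The two-group
test is the two-sided Wilcoxon rank-sum: exhaustively enumerated via the
permutation distribution when both groups have n ≤ 8 (exact even under
ties), tie-corrected normal approximation otherwise.  Per-taxon contrasts
are BH-corrected within one taxonomic level at a time, so the genus family
is corrected separately from the phylum family.

## Co-occurrence networks

Taxa with mean relative abundance strictly below 0.01 % are removed, all
remaining pairs are tested with Spearman correlation, and BH correction
runs over the full family of tested pairs.  An edge requires |ρ| strictly
greater than 0.6 *and* q < 0.05; the sign is retained (negative
associations are edges too; a positive-only mode exists).  Constant taxon
vectors make ρ undefined, so such pairs are skipped with a warning.

Topology conventions, chosen for determinism and fixed before any
comparison: density 2E/(N(N−1)); average degree 2E/N; clustering is the
mean local coefficient with degree<2 nodes contributing 0; diameter and
average path length are computed on the largest connected component;
modularity is the Clauset–Newman–Moore greedy maximum on the unweighted
graph (deterministic, unlike seeded Louvain, which remains available in
networkx for users who want it).  An edgeless network reports all zeros
with a warning.

## Sloan neutral community model

The model: a taxon at metacommunity relative abundance p is detected in a
local community of N individuals with probability
1 − BetaCDF(d; Nm·p, Nm·(1−p)), with detection limit d = 1/N (one read)
and Nm = N·m.  N is the mean post-rarefaction depth.  Nm is estimated by a
bounded 1-D least-squares search over log Nm ∈ [0, log 1e7] on the
untransformed observed frequencies; R² = 1 − SSE/SST is reported unclamped
(a negative value is meaningful and must surface).  The 95 % band is the
Wilson score interval for a binomial proportion at the predicted frequency
with n = number of samples (beta-quantile bands via `ci_method="beta"`;
the choice moves the band, never the estimate).  Taxa absent everywhere or
fixed at p ∉ (0,1) are excluded from the SSE but reported.

**Known estimator bias.**  On data whose latent compositions follow the
model exactly but are then observed through multinomial read sampling (as
all real amplicon data are), the detection event P(count > 0) =
E[1 − (1−x)^N] exceeds the beta-tail proxy P(x > 1/N), and the
least-squares Nm compensates upward.  At N = 20 000 and true Nm = 2000 the
overestimate is ≈ +25 % and is insensitive to the metacommunity shape; it
shrinks at lower migration (≈ +11 % at Nm = 200).  The same estimate (to
four significant figures) is produced by the canonical R implementation
(`minpack.lm::nlsLM` on `pbeta`), so this is a property of the standard
estimator, not of this implementation.  Ranks are preserved: estimated Nm
is strictly monotone in true Nm across the tested ladder, so comparative
statements between groups are safe; absolute Nm/m values should be read
with this bias in mind.

## Null models and process partitioning

βMNTD(j,k) is the abundance-weighted mean over each community's taxa of
the patristic distance to the nearest taxon of the other community,
averaged over both directions.  βNTI standardizes the observed βMNTD
against a null built by shuffling taxon labels across the tips of the
*whole table's* taxon pool (999 randomizations by default, seeded;
per-pair pools via flag).  Keeping the study-wide taxon columns — zeros
included — when analysing one sample group is important: the null pool is
then the regional pool, which is what makes filtering detectable at all.
Degenerate nulls (sd = 0) record βNTI = 0.  Uniform branch-length scaling
cancels exactly in the z-score when the same seed is used.

RC_bray reassembles each sample from the metacommunity (species identity
weighted by occupancy via Gumbel-top-k sampling without replacement,
individuals by pooled relative abundance, every chosen species guaranteed
one individual) holding richness and total count fixed, then ranks the
observed Bray–Curtis within the null distribution and rescales to [−1, 1].
On data generated by the null process itself RC is uniform-centered at 0;
on Dirichlet-multinomial neutral data its center depends on the migration
parameter (negative at high Nm, where real communities are *more* similar
than occupancy-preserving nulls), which is worth remembering when reading
absolute RC values.

Partition rules (applied in order, exhaustive and mutually exclusive):
βNTI > +2 → variable selection; βNTI < −2 → homogeneous selection; then
RC > +0.95 → dispersal limitation; RC < −0.95 → homogenizing dispersal;
else drift.  The stochastic band uses |βNTI| ≤ 2 inclusive.

The Mantel test correlates upper-triangle entries (Pearson or Spearman)
with significance from joint row/column permutations of the second matrix,
two-sided on |r|, and the (1 + hits)/(1 + n_perm) estimator.  Host-factor
matrices are pairwise absolute differences of altitude, body length, body
weight, or BMI.  βNTI is the default assembly matrix for Mantel tests,
with βMNTD supported.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of their parameters and a mandatory
seed.

* **Enterotype mixture** — Dirichlet-multinomial around cluster-specific
  mean compositions derived from one shared, geometric (3-decade) baseline.
  Cluster 1 boosts a near-singleton block of top-ranked taxa
  (dominance/low evenness, a *Lactobacillus*-like type); later clusters
  boost broad mid-rank blocks (diversity, a *Muribaculaceae*-like type),
  so the dominant type has the lower Shannon index by construction.
  `effect_size` is the log-fold block boost (default 3; 0 gives
  exchangeable clusters), `concentration` (default 50) sets the
  overdispersion real 16S tables show.
* **Neutral** — metacommunity proportions follow a normalized geometric
  series spanning `decades` orders of magnitude (default 4, a typical
  dynamic range for amplicon surveys); compositions are Dirichlet(Nm·p),
  giving each taxon the Beta(Nm·p, Nm·(1−p)) local marginal the Sloan
  model assumes, then multinomial reads.
* **Selected** — a trait evolves by Brownian motion on a Yule tree (tip
  labels assigned in seeded random order, so identifiers carry no
  topological information); sampling weights are
  base_i · exp(−s·(trait_i − env_s)²).  Optional Dirichlet
  `concentration` adds drift-like turnover among the favored taxa; without
  it, samples under identical selection overlap almost completely and
  phylogenetic turnover indices have nothing to standardize.  Because
  interior trait values are crossed by many lineages, a *detectably*
  filtered community needs its environment near the edge of trait space;
  the positive-control configuration therefore places a uniform
  environment at the 90th percentile of realized traits (selection
  strength 3, concentration 10, 600-taxon tree, depth 1000), and the
  variable-selection control contrasts the 10th vs 90th percentiles.
* **Metadata** — a handful of trapping sites with elevations drawn in
  120–838 m, body length ≈ 95 ± 8 mm, BMI (g/mm², weight/length²) ≈
  3.3·10⁻³, with weight derived from BMI and length so the three columns
  are exactly consistent.

Not emulated: sequencing error, chimeras, compositional biases of PCR,
taxonomy strings beyond a flat synthetic genus map, spatial/temporal
autocorrelation, and co-occurring selection + dispersal gradients.
Passing tests on these generators therefore demonstrate correctness of
the estimators under their own assumptions and calibrated behaviour under
clean nulls — not robustness to real-data artifacts.

## Problem sizes

The bundled checks run at deliberately moderate scales chosen to exercise
the asymptotics that matter while staying desk-sized: neutral-model
recovery at 50 samples × 1000 taxa × 20 000 reads; null-model calibration
at 20 samples × 200 taxa with 199 randomizations; selection controls on
600-taxon trees with 16 samples; enterotype recovery at the 94-sample
study scale over 20 replicates; Mantel calibration with 500 replicates of
n = 30 at 999 permutations.  Defaults inside the package remain the
field-standard 999 randomizations/permutations.

## Known limitations

* The Sloan fit's absolute Nm bias described above.
* Pairwise βNTI/RC values within a group are not independent; rank-sum
  comparisons of pooled pairwise values between groups (as is common
  practice) inherit that non-independence and should be read as
  descriptive.
* The greedy modularity maximum is a lower bound on the true maximum
  modularity.
* PAM's heuristic branch (large C(n,k)) carries the usual local-optimum
  caveat; the exact branch covers every configuration used for model
  selection at study scale with k ≤ 2.
* `raup_crick_bray` draws one null realization per sample per
  randomization and compares all pairs against it, rather than
  re-drawing nulls independently per pair; this is the common
  implementation shortcut and matters only for extreme tail precision.
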