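# Methods

This note documents the models, estimators and simulation designs the
package implements, the defaults and why they were chosen, and what the
synthetic data can and cannot show.

## Contaminant identification

Reagent contaminants are identified by a prevalence contrast against
negative-control samples: for each taxon, the 2×2 presence/absence ×
control/biological table is scored with a one-sided Fisher exact test
(alternative: presence enriched in controls), and a taxon is called a
contaminant when that probability falls below the threshold (default 0.5).
"Presence" means count ≥ 1, with no relative-abundance floor. The Fisher
score is an exact analogue of the prevalence-based contaminant score used by
the common R tooling (which employs a chi-square contrast); at the sample
sizes involved here (≈14 wells) the exact test is the defensible choice.
Flagged taxa are removed from the table by default; a flag keeps them.

## Rarefaction

Expected richness at depth *d* uses the exact hypergeometric closed form
`E[S(d)] = Σ_t (1 − C(N−n_t, d)/C(N, d))` rather than Monte-Carlo
subsampling; this removes replicate-count sensitivity and makes the curves
deterministic. A seeded Monte-Carlo mode exists for cross-checking.

## Diversity statistics

Alpha metrics: observed features (count of taxa with count > 0), Shannon
entropy in log base 2 (bits; the base is configurable), and Pielou evenness
`H / log2(S)`, reported missing when `S = 1`. Group contrasts use the
tie-corrected Kruskal–Wallis test; all-tied inputs are reported as H = 0,
p = 1 rather than an error.

Beta diversity: Bray–Curtis on raw counts (no prior rarefying — an optional
rarefy step exists but defaults off) and Jaccard distance on presence sets.
PCoA is classical scaling of the double-centered squared-distance matrix;
negative eigenvalues are reported, not silently corrected, and their axes
are flagged. PERMANOVA uses the standard squared-distance partition with
the `(1 + x)/(1 + N)` permutation p-value estimator (999 seeded label
permutations by default); when the number of distinct assignments is at
most the permutation budget the null is enumerated exhaustively and the p
becomes an exact proportion. Beta dispersion follows the vegan convention:
samples are embedded by PCoA keeping all axes, negative-eigenvalue axes
contribute negatively to squared distances-to-centroid, and the group
effect on the distances is tested with one-way ANOVA. Sample clustering is
UPGMA on the Jaccard matrix, exported as Newick.

## Basis correlation inference (SparCC)

Counts are compositional, so the estimator works from the variation matrix
`t_ij = Var[log(f_i/f_j)]` and solves the sparsity-approximation linear
system (diagonal `D−1`, off-diagonal 1) for the basis variances `ω`, from
which `r_ij = (ω_i + ω_j − t_ij)/(2√(ω_i ω_j))`, clipped to [−1, 1].
Strongest-pair exclusion is iterated up to `n_iter` times at threshold 0.1;
excluded pairs leave the row sums and reduce the system coefficients, and
exclusion stops before the system degenerates (a taxon saturated with
exclusions is frozen; a singular system reverts to the previous solution).
Fractions are Dirichlet posterior resamples of the counts (pseudocount 1);
the reported matrix is the elementwise median over 20 resamples. Defaults
(pseudocount 1, n_iter 10, exclusion threshold 0.1, 20 resamples) are the
reference method's canonical settings. Non-positive `ω` estimates are
floored at 1e-6 and logged.

**Identifiability filter.** Before inference, the estimator drops taxa that
are all-zero or constant, and — more importantly — taxa whose observed
log-fraction variance is below `max(2 × expected counting-noise variance,
0.25)`, where the counting-noise variance is the mean Dirichlet posterior
variance `ψ₁(count + pseudocount)`. The rationale: the basis-variance solve
carries absolute noise of order `t̄·√(2/(n−1))/√D`; for a taxon whose true
basis variance is below that noise floor, the tiny `√(ω_i ω_j)` denominator
amplifies estimation noise into spurious strong correlations. Two classes
of taxa fail the filter: dominant genera with near-constant relative
abundance (whose variation is purely multinomial), and the rare tail (whose
variation is purely counting noise). This is also the mechanism by which a
*Wolbachia*-like dominant symbiont, despite overwhelming abundance, carries
no edges in the inferred network: connectivity is driven by covariation,
not abundance. The absolute floor (0.25, i.e. log-sd 0.5) is a judgment
call appropriate to n ≈ 10–20 samples and is configurable.

**Small-sample noise floor.** With n = 10 samples per group, the sampling
standard deviation of a null correlation is ≈ 0.33, so a hard |r| ≥ 0.5
edge rule admits roughly 10% of null pairs among fully-informative taxa
(Dirichlet-median attenuation reduces this for lower-count taxa). Synthetic
baseline networks therefore contain a minority of chance edges, roughly
half of them negative. This is a property of the study conditions, not of
the estimator; the acceptance suite quantifies false positives under
independence at n = 20 (≤ 5%) and with D = 30 components, reflecting the
estimator's many-component sparsity assumption (the solve error is
O(1/D)).

Edge rule: `r ≥ cutoff` or `r ≤ −cutoff`, bound inclusive, cutoff 0.5 by
default. No bootstrap pseudo-p filtering: the edge criterion is magnitude
alone.

## Network construction and topology

Networks retain edges of both signs; the sign is an attribute, and |r| is
the weight wherever a non-negative weight is required (Louvain, eigenvector
centrality, weighted degree). Isolated taxa are not nodes ("connected
nodes"). The topology bundle: average degree 2E/N; weighted degree = mean
over nodes of summed incident |r|; clustering = unweighted mean local
clustering coefficient (degree < 2 contributes 0; the Gephi-style
statistic), with global transitivity also emitted; diameter = longest
shortest path within the largest connected component (the global diameter
is undefined on fragmented graphs); modularity and module count from
seeded Louvain at resolution 1.0 on |r| weights (modules of size 2 count).
Centralities: degree, normalized unweighted betweenness, per-component
closeness (no cross-component scaling), eigenvector on |r| weights (power
iteration to 1e-8). Reporting rounds percentages to 1 decimal and degree
metrics to 3 decimals, matching the conventions of published topology
tables. Ego subnetworks are induced subgraphs on a focal taxon's closed
neighborhood; an absent focal taxon yields an empty subnetwork with a flag.

## Cross-network comparison

For each of degree, betweenness, closeness and eigenvector centrality, the
"most central" set contains nodes strictly above the empirical 75th
percentile (linear-interpolation quantile; ties at the threshold excluded —
both choices configurable). Hub taxa are the intersection of the
top-quartile sets for degree, betweenness and eigenvector. The Jaccard
index of two sets is tested against the null in which both sets are drawn
uniformly without replacement from the union of the two networks' node
names with their observed sizes; the overlap is then hypergeometric, and
`P(J ≤ j)` / `P(J ≥ j)` are exact tail sums including the observed value —
no simulation. Differential edges are exact set algebra over unordered
name pairs, split into A-only, B-only, shared-same-sign and sign-flip.

## Robustness

Attack strategies: random (seeded uniform order), degree and betweenness
(static ranking on the intact network, ties by node name), and cascading
(highest current betweenness, recomputed after every removal).
Connectivity loss is the pair-connectivity functional `1 − (connected
pairs)/(initial connected pairs)` — well defined on fragmented graphs,
monotone, 0 at the start and 1 at exhaustion; an LCC-based loss is emitted
alongside. The 80%-disconnection point is the smallest removed fraction at
which loss reaches the level.

Node addition attaches each new node by a single edge to a uniformly chosen
existing node (the simplest random-introduction rule; the attachment count
is configurable), recording LCC size and APL within the LCC after each
addition (APL through igraph's C core; recording can be strided for large
grids). Grid sizes default to {100, 300, 500, 700, 1000} added nodes with
3 replicates. Paired comparison between two networks' curves: replicate
means paired by step, Wilcoxon signed-rank (zeros dropped; exact null for
≤ 25 informative pairs), Benjamini–Hochberg adjustment across the tested
family, and a seeded percentile bootstrap (2.5/97.5, 2000 draws) of the
mean difference.

## Knockouts

A knockout zeroes one taxon's counts in every sample (the column is kept);
the zero-variance guard removes it from inference, so it vanishes from the
re-inferred network. Knockouts are single-taxon and independent, never
cumulative. Baseline and depleted runs share the Dirichlet-resampling seed
so topology differences are attributable to the knockout rather than
resampling noise. Each report carries before/after topology for both
groups, emergent edges (absent before, present after, tagged by sign),
emergent nodes, and the four attack curves on both baseline and depleted
networks.

## Synthetic data generator

The generator emulates a two-site, individually-sequenced mosquito design:
2 × 10 biological samples, a 15-genus shared core whose first member is a
dominant *Wolbachia*-like endosymbiont pinned near 70% of the composition
with near-zero log variance (log-sd 0.01), 100 vs 61 site-specific
accessory genera, 4 sterile-water negative controls carrying 2 contaminant
taxa (also spilled at trace counts into ~20% of biological samples), and
20,000 reads per sample — a realistic post-QC per-sample yield for ONT 16S
profiling; the real study does not report per-sample depths, so this is a
free parameter of the fixture.

Counts arise from a log-normal/multinomial compositional model: log
abundances are multivariate normal with the planted interaction graph
encoded as off-diagonal covariance `±effect·σ²` (effect 0.8 by default),
the dominant taxon is pinned, the vector is closed to proportions, and
reads are drawn multinomially. The default planted structure consists of
positive equicorrelated blocks per site, each anchored by one of the four
knockout-candidate shared genera (*Pantoea*, *Stenotrophomonas*, *Delftia*,
*Alcaligenes*), with larger blocks in the first site — producing the
denser, more clustered first-site network. Abundance profiles are bimodal,
as in real amplicon tables: interacting taxa are moderately abundant
(log-means −1 to −2 relative to the core), the non-interacting accessory
tail is rare (log-means −3.5 to −5.5; expected counts near one read per
sample), and non-anchor core genera are stable (log-sd 0.2) — consistently
detected but too invariant to be network-estimable, mirroring the
observation that most shared genera do not surface in inferred networks.
All randomness flows from a single integer seed.

What the generator does **not** emulate: taxonomic misclassification noise,
chimeras, per-sample depth variation, overdispersion beyond the log-normal,
phylogenetic correlation among genera, and real ecological interaction
topology. Passing tests therefore demonstrate correctness of the estimators
and pipeline under the assumed generative model, not biological validity of
any particular real-data network. In particular, the synthetic design
plants a genuine richness asymmetry (100 vs 61 accessory genera with
appreciable per-sample presence), so alpha-diversity contrasts and
PERMANOVA come out significant on synthetic data even though the real study
reported non-significant contrasts; those real-data p-values depend on the
deposited sequencing data and are out of desk-scale reach.

## Pipeline and reproducibility

A single YAML config (unknown keys rejected, thresholds validated) drives
filter → diversity → per-group SparCC → networks → comparison → robustness
→ knockouts. Every per-stage seed derives from one base seed by fixed
offsets; every output file is checksummed into `manifest.json`, and
identical config + seed reproduces byte-identical outputs. Problem sizes in
the bundled demo (default design, 5-point addition grid, 3 replicates,
addition metrics recorded every 10 steps) run in well under a minute.

## Known limitations

- With n = 10 samples per group, a magnitude-only edge rule cannot separate
  planted from chance correlations perfectly; baseline synthetic networks
  carry ~10% chance edges among informative taxa (see noise-floor section).
- The identifiability floor (log-variance 0.25) is calibrated to this
  sample-size regime; very large studies could lower it.
- Louvain is a heuristic: its modularity is a lower bound on the optimum
  (verified exhaustively on small graphs in the test suite).
- The exact hub definition, attachment rule for node addition, and
  per-component diameter reading are declared conventions; all are
  configurable where alternatives are defensible.
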