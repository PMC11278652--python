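# Methods

This note documents the models, defaults and numerical choices behind
`riverweb`, and what its synthetic-data tests do and do not establish.

## Co-occurrence network model

Edges are strong positive monotone associations between OTU relative
abundances across samples: Spearman ρ > 0.6 with Benjamini–Hochberg q <
0.01, both strict, after restricting to OTUs present in at least 30% of the
scope's samples (inclusive boundary: presence/n ≥ 0.3 retains). Negative
correlations are excluded by default because the analysis this package
implements screens on ρ > 0.6 literally; `use_absolute=True` in
`build_network`/`RunConfig` admits |ρ| instead. Isolated OTUs are dropped:
node counts describe the drawn network.

p-values use the large-sample t approximation t = ρ√((n−2)/(1−ρ²)) on n−2
degrees of freedom; the builder therefore requires ≥ 5 samples. Ranks are
average ranks (tie-corrected), so ρ equals the Pearson correlation of
ranks. Pairs involving a constant abundance vector have no defined ρ and
are excluded with a logged count. BH adjustment is applied once over every
tested pair of a scope, not per domain.

**Two-primer tables.** Bacteria and archaea are typically sequenced with
separate primer sets, so their relative abundances are not on a common
scale. `renormalize_by_domain` rescales each domain to sum 0.5 per sample
(not 1 per domain, which would break the sample-sums-to-1 closure
invariant); since the factor applied to each OTU is a per-domain constant
within each sample's domain profile, every Spearman rank — and hence every
edge — is identical to the sum-to-1-per-domain convention. The pipeline
applies this by default; for synthetic tables, which are generated on one
common scale, it should be disabled (see below).

**Modules.** Louvain on the unweighted graph (`networkx`
`louvain_communities`, fixed seed; ties broken by the library's seeded
order), module ids dense integers ordered by descending size, modularity
recorded on the graph.

## Erdős–Rényi nulls and small-world σ

Null graphs are G(n, m): uniform simple graphs with exactly the observed
node and edge counts. Per replicate: CC is the mean local clustering
coefficient with degree < 2 nodes contributing 0 (this estimator's
ensemble mean converges to the edge density m/C(n,2), matching how null
clustering values are conventionally reported); APL is the mean shortest
path over connected pairs only, keeping it finite on disconnected graphs;
MD is seeded Louvain modularity. σ = (CC/CCr)/(APL/APLr). Edgeless graphs
report APL and MD as missing, never 0. The ensemble default is 1000
replicates; tests and the acceptance script use 100, which bounds the
Monte-Carlo error of CCr well below the ±0.002 tolerance used for it.

**Degree fits.** Both the power law a·k^(−γ) and the Gaussian
A·exp(−(k−μ)²/2s²) are fitted to the raw probabilities P(k) (not
log-residuals) so their adjusted R² = 1 − (1−R²)(n−1)/(n−p−1) values are
directly comparable. Initialization: log–log OLS for the power law (k = 0
bins dropped), histogram moments for the Gaussian, plus a restart grid;
Gaussian parameters are box-bounded (μ within one span of the degree range,
s > 0) so the fit degrades gracefully on monotone data instead of
diverging. Non-convergence yields a flagged fit with missing R².

## O/R incidence and keystones

R is the expected edge fraction when m edges are placed uniformly at random
among the N nodes: the probability a random node pair joins phyla (1, 2) is
n₁n₂/C(N,2) for distinct phyla and C(n₁,2)/C(N,2) within a phylum. This
closed form reproduces published incidence tables exactly, so no Monte
Carlo is used. O and R each sum to 100% over all phylum pairs (both are
normalized distributions over edges / node pairs). Ratios are computed on
unrounded percentages; rounding happens only at display. Report filtering
(O > 0.5%, O/R > 1, both strict) lists intra-phylum rows before
inter-phylum rows.

Keystones: degree > 100 and exact, unweighted, unnormalized betweenness
< 5000, both strict. The cutoffs are meaningful only at the ~1000-node
scale where they originate; they are configuration, and an empty keystone
set is a valid report. Because it is unstated whether published per-phylum
abundance percentages are normalized by the keystone total or the network
total, the report carries both fractions.

## Topology features

The canonical 12-feature set: node count, edge count, density,
transitivity, mean local clustering, mean degree, Freeman degree
centralization Σ(k_max−k_i)/((n−1)(n−2)), mean nearest-neighbor degree
(averaged over non-isolated nodes), APL over connected pairs, mean
unnormalized betweenness, Louvain modularity, degree assortativity
(Pearson on edge-endpoint degrees; missing when degree variance is zero).
Graphs are treated as unweighted throughout. Features undefined on
degenerate graphs are reported missing, never 0.

Per-sample subnetworks are presence-induced subgraphs: a network node
belongs to a sample's subnetwork iff its abundance in that sample is > 0
(no minimum-abundance floor), and edges survive iff both endpoints are
present. Group contrasts use the tie-corrected asymptotic Wilcoxon
rank-sum for two groups (identical pooled values, where the tie-corrected
variance vanishes, are defined as p = 1) and one-way ANOVA for more;
groups under 3 samples flag the comparison rather than computing it.

## Spatial and environmental analyses

Geodetic distances are haversine on a sphere of radius 6371.0088 km rather
than a projected planar distance; the Spearman Mantel statistic is
invariant under this monotone change. The Mantel test is one-sided
(positive association, the distance-decay hypothesis), permuting rows and
columns of one matrix simultaneously, p = (hits+1)/(perms+1); ranks of the
condensed entries are precomputed once since relabeling only permutes
them. Distance decay is the OLS slope of Bray–Curtis *similarity*
(1 − dissimilarity) on distance; a constant-similarity matrix returns
slope 0 with no Mantel attached. Bray–Curtis on topology-feature matrices
(which contain negatives, e.g. assortativity) first min–max scales each
feature to [0, 1] and drops constant features.

db-RDA follows the capscale construction: Bray–Curtis dissimilarities →
classical PCoA with negative-eigenvalue axes dropped → least-squares
projection of the coordinates on z-scored factors. Axis percentages are
constrained-axis sums of squares over the total retained inertia. Marginal
per-factor tests refit single-constraint models; significance is by
permutation of the factor, and the adjusted R² uses the permutation form
1 − (1−R²)/(1−mean R²_perm), which is unbiased near zero for null factors.
Missing environmental values are deleted pairwise for Spearman heatmaps
and listwise for db-RDA; a condition number above 1e8 on the design matrix
raises an error naming the factors.

## Synthetic communities

The generator states a world shaped like a two-season large-river survey:
59 sites spread over 6000 km (defaults), sampled in spring and autumn, 600
OTUs across 14 bacterial and archaeal phyla in proportions typical of such
surveys, 8 planted modules of 40 OTUs. Per module and season, a latent
Gaussian factor over sites is drawn with covariance exp(−d/L) in
along-river distance (default decay length L = 1000 km — long enough that
the ~100-km site spacing resolves the decay); a member OTU's latent value
is √c·factor + √(1−c)·noise, planting pairwise latent correlation c
(default 0.9). Log-abundances add an OTU-specific base mean (SD 1.5 log
units, giving the heavy-tailed abundance distribution real OTU tables
show); rows are closed to sum 1. Environmental factors are additive
(baseline + autumn offset + terrain gradient + noise) with defaults
anchored to the measured contrasts of the study system (e.g. spring WT
11.14 °C vs autumn +10.57; NH₄⁺-N and Ca/Fe/Al/Ni elevated in spring;
nutrients rising toward the plain). Landform follows river position
(plateau → mountain/hill → basin → plain) and the source region is the
upstream fifth of sites. Everything is deterministic given the spec's
seed.

Zero inflation is Bernoulli masking followed by row renormalization —
zeros are placed at random, which is what drives prevalence filtering and
per-sample subnetwork variation, but which also *attenuates rank
correlations* (unlike real detection-limit zeros that co-vary with
abundance). Consequently the planted-module recovery analyses run without
zero inflation, matching their stated conditions; at the default 30%
masking the planted Spearman signal falls below the 0.6 edge threshold,
which is a property of random masking, not a pipeline defect. Likewise,
per-domain renormalization must be disabled on synthetic tables: they are
generated on one common scale, and renormalizing them splits
mixed-domain planted modules into their bacterial and archaeal halves
(different per-domain closure denominators decorrelate them).

What a green synthetic test establishes: the pipeline recovers planted
block correlation (ARI = 1.0 at c = 0.95, 60 samples), controls false
discoveries on independent data, and detects planted spatial decay. What
it does not: compositional-bias robustness (closure attenuates the planted
correlations — e.g. median pairwise ρ within a 0.95-block drops to ~0.68
when one module dominates total abundance), realistic zero structure, or
sequencing noise.

## Known limitations

- Compositionality is handled by thresholded Spearman, not by
  compositionality-aware estimators (SparCC/SPIEC-EASI); closure-induced
  attenuation and spurious negative correlation are documented above.
- Only Erdős–Rényi nulls are provided; no degree-preserving
  (configuration-model) ensembles.
- Distance-decay monotonicity in the decay length holds only once both
  lengths exceed the inter-site spacing; below it the signal saturates and
  the OLS slope shrinks toward zero.
- Published null modularity values (MDr) depend on the original
  modularity optimizer; seeded Louvain on ER replicates gives the same
  qualitative contrast but not necessarily identical values.
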