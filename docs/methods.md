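# Methods

This note documents the models, parameter choices and numerical conventions
behind `vitnet`, and what the synthetic data generator does and does not
emulate.

## Compositional correlation (SparCC backend)

Relative abundances carry only relative information; closing each sample to
a constant sum induces spurious negative correlation under naive estimators.
The backend estimates *basis* correlations from log-ratio variances. For
components i, j with basis log-variance ω², the variation matrix entry
t_ij = Var_s[log(x_i/x_j)] satisfies t_ij = ω_i² + ω_j² − 2 ρ_ij ω_i ω_j.
Summing over j and treating most ρ as negligible gives the linear system
M ω² = t_row_sums with M = (D−2)I + J; correlations then follow from the
identity above, clamped to [−1, 1].

Numerical conventions:

- **Closure and pseudocount.** Each sample is closed to sum 1 before
  anything else; a pseudocount (default 1e−6, a fraction of the closed
  total) is added before the log transform and the sample re-closed. Because
  closure happens first, the estimate is exactly invariant to per-sample
  rescaling.
- **Pair exclusion.** The sparsity assumption fails for strongly correlated
  pairs, so up to `n_exclusion_rounds` (default 10) times, the
  most-correlated remaining pair with |ρ| ≥ `exclusion_threshold` (default
  0.1) is removed from the row sums and the system re-solved. A component is
  kept in at least three pair equations so the system stays well posed;
  negative solved variances are floored at 1e−12.
- **Resampling.** `n_iterations` (default 20) estimation rounds are run:
  round 0 on the observed compositions, later rounds on Dirichlet draws with
  concentration `closed fractions × resample_depth` (default 5000, an
  effective count depth), and the elementwise median is taken. Each
  component's random stream is keyed by a CRC32 of its identifier rather
  than by column position, so permuting or relabeling genomes commutes
  exactly with the estimate.
- **Degenerate inputs.** Fewer than 4 components is an error (the basis
  system is underdetermined). A component constant across samples gets all
  correlations set to 0 with a logged warning.

The estimator is exposed as a scikit-learn-style class (`SparCC` with
`fit`/`correlation_`/`get_params`), with `sparcc_correlations` as the
table-level wrapper. Permutation p-values shuffle each genome's sample
order independently (destroying all pairwise association, preserving
marginals) and use the add-one estimator p = (1 + exceedances)/(1 + n_perm).
Permuted tables intentionally violate the per-sample sum constraint and are
constructed unchecked.

## Network construction and topology

Edges are correlations ρ ≥ threshold (default 0.35), positive only by
default; optional p-value filtering is off by default since thresholding on
ρ alone is the primary rule. Nodes without a retained edge are dropped
(logged): the analyzed network is the correlated subset of the genome set.

- **Betweenness** uses unweighted shortest paths: correlation weights are
  similarities, not path lengths. Reported unnormalized (b(v) = pair-sum of
  shortest-path fractions, endpoints excluded, disconnected pairs contribute
  0), with a normalized column emitted alongside for cross-tool comparison.
- **Density** is 2m/(n(n−1)), evaluated exactly; mean degree is 2m/n.
- **Hubs**: the criterion "elevated betweenness" is implemented two ways —
  `top_k` (default k = max(1, round(0.07 n)), roughly the hub fraction of a
  120-node network with eight hubs) and `mean_plus_sd` (b > mean + c·sd).
  Ties break by higher degree, then lexicographic node id, so results are
  total-order deterministic.
- **Modules**: Louvain (weighted, resolution 1.0, seeded and deterministic)
  is the default; Girvan–Newman is the cross-check, returning the partition
  of maximal weighted modularity along its edge-removal hierarchy, with the
  trivial one-module partition included as a candidate so a single clique
  yields Q = 0 rather than a forced split. Module ids are numbered by each
  module's lexicographically first member, making partitions comparable
  across runs.

## Vitamin capability calls

A pathway is an ordered list of stages; a stage is satisfied iff the genome
carries at least one of its alternative KOs. Status is *complete* when all
stages are satisfied; *near-complete* when every unsatisfied stage could
only have been satisfied by KOs inside the catalog's exempt set; *absent*
otherwise. For thiamine the exempt set is {K03147} (thiC,
phosphomethylpyrimidine synthase), so a genome missing only thiC is
near-complete — organisms can often scavenge the pyrimidine moiety while
still needing the other three enzymatic steps (thiazole production, moiety
linking, kinases). Status is monotone in the KO set: adding annotations can
only promote.

The shipped catalog covers thiamine, biotin, tetrahydrofolate, riboflavin,
NAD and pantothenate with standard KEGG KO alternatives per stage. It is
plain JSON configuration: users substitute their own stage/KO definitions
without code changes, and calls are only as good as the catalog and the
annotation completeness (poor transporter or ortholog annotation biases
toward auxotrophy).

Roles: producers are complete genomes plus, under the default
`near_complete_policy="producer"`, near-complete ones; every non-producer is
an auxotroph. This is a genomic operating definition — absence of a pathway
does not prove the requirement for growth — and the stricter policy is a
first-class switch. The genome-size comparison bins genomes by the number
of complete pathways (bins 0–1, 2, 3, 4, 5–6) and compares genome lengths
pairwise with Welch's two-sided t-test (unequal variances); bins with fewer
than two genomes are reported as not computable.

## Vitamin-hubness and its null

For a producer v: h(v) = D_total·D_auxotroph / [(1/N)·Σ_a P(a)], where the
denominator is the mean number of producers adjacent to each of v's N
auxotrophic neighbors. Conventions, each of which matters numerically:

- The focal producer counts in its neighbors' producer tallies, so the
  denominator is ≥ 1 and h ≤ D_total·D_auxotroph; when v's auxotrophic
  neighbors have no other provider the denominator collapses to exactly 1.
- Producer adjacency is counted network-wide, not within v's module.
- N = 0 (no auxotrophic neighbors) gives h = 0: no provisioning evidence.
- Scores are computed only for producer-labeled nodes; others are
  not-applicable rather than 0.
- Rankings break ties by (higher auxotroph-neighbor count, node id).

The null preserves the observed producer count and relabels uniformly at
random, recomputing h(focal) per draw. Under the default
`focal_forced_producer` policy the focal node is always a producer and the
remaining producers are drawn from the other nodes; under `free_relabel`
draws that label the focal node auxotroph are recorded as h = 0 and counted
separately, since the metric is not meaningful for non-producers. The z
score uses the sample sd (ddof 1) and is reported as not-computable when
the null is degenerate (sd = 0); the empirical p uses the add-one rule and
a ≥ comparison with a 1e−12 tolerance. This null asks specifically whether
the observed score reflects the focal node's position (auxotroph-enriched
neighborhood with few alternative providers) or would arise for any
producer placement; it deliberately permutes labels, not edges — a
degree-preserving rewiring null answers a different question and is out of
scope.

## Ecology comparisons

Entities (single genomes or module aggregates, where module abundance is
the exact per-sample sum of member abundances) are compared between the two
categories of a binary metadata axis (biofilm/planktonic lifestyle,
high/low thiocyanate). Frequency is the fraction of category samples with
abundance above the presence threshold (default 0: any detection counts;
no detection cutoff is assumed). The t statistic is Welch's, first category
minus second in sorted label order; categories with fewer than two samples
make the test not-computable while frequencies are still reported. The
high/low thiocyanate labels are user-supplied metadata, not inferred from a
concentration cutoff. No multiple-testing correction is applied across
entities; raw tests are reported.

## Synthetic communities

The generator stands in for a 92-sample bioreactor metagenome series and
provides ground truth for recovery tests. Defaults: 120 genomes × 92
samples; four planted modules of 25 genomes with within-module basis
correlation 0.7; one producer hub with eight dependent auxotrophs at
hub–dependent correlation 0.8 (dependents load on the hub's latent factor,
so dependent–dependent correlation is 0.64); 38 thiamine producers;
background correlation 0.

- **Sampling model.** Latent log abundances are multivariate normal with
  the planted correlation structure (checked positive semidefinite; a
  violation is an error naming the blocks), exponentiated, then observed as
  multinomial counts at depth 100,000 per sample and closed to fractions.
  The depth keeps count noise well below a 0.7 signal at 92 samples while
  still exercising the compositional distortion SparCC must undo —
  correlations are planted on the basis scale and recovered on the inferred
  scale.
- **Producer placement.** The hub is always a thiamine producer and its
  dependents always auxotrophs. The remaining producers are placed by
  module-stratified quotas (largest-remainder rounding, uniform draws
  within each module and the background pool). This mirrors the emulated
  communities, where producer capability is phylogenetically widespread and
  every module contains several producers; the planted signal is the hub's
  *exclusive* provisioning role for its dependents, not accidental producer
  scarcity in some module. Unstratified placement occasionally creates
  modules with one or two producers whose members out-score the planted hub
  — a legitimate provisioning pattern, but not the planted one.
- **Annotations.** KO sets are generated to reproduce the planted statuses
  exactly under the shipped catalog: producers get one KO per stage,
  near-complete genomes satisfy every non-exemptable stage, auxotrophs lack
  one non-exemptable stage entirely (choices avoid KOs that would break
  another vitamin's planted status; decoy KOs outside the catalog are added
  as noise). Genome lengths are base 2.5 Mbp + 0.4 Mbp per planted pathway
  with 10% lognormal noise, so the size–breadth association is recoverable
  but noisy.
- **Metadata.** Samples split ~50/50 on each axis; configurable per-module
  log-abundance shifts (defaults: module 1 elevated in planktonic samples,
  module 2 in high-thiocyanate samples) create detectable condition
  preferences.

What the generator does **not** emulate: time-series autocorrelation
between samples, strain-level variation, uneven genome detectability,
annotation error in the direction of false presence, and realistic network
sparsity — planted modules become near-cliques, so synthetic networks are
denser than typical co-occurrence networks. Passing recovery tests
therefore shows the pipeline recovers planted provisioning structure
through compositional noise; it does not certify performance on real data
with weaker, sparser correlation structure.

## Problem sizes and determinism

Tests verify exact oracle equivalence on small graphs (≤ 12 nodes for the
hubness oracle; the full graph atlas ≤ 7 nodes plus random 8-node graphs
for betweenness), simulation-based properties at 20 seeds each (50 × 200
correlation recovery; 120 × 92 end-to-end recovery with 300-draw nulls),
and exhaustive enumeration of all C(10,4) labelings for the star-graph
null. The acceptance script runs a single full-scale pass with a 1000-draw
null. Every stochastic stage takes an explicit seed and is bit-reproducible;
derived seeds stay below 2³¹.
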