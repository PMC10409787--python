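# vitnet

Predicting vitamin-provisioning hub organisms in microbial communities from
genome-resolved metagenomic time series.

In engineered and natural microbial communities many organisms are
**auxotrophs**: their genomes lack the biosynthetic pathway for a B vitamin
they need, so they depend on neighbors that produce it. `vitnet` finds the
likely providers. It builds a co-occurrence network from genome relative
abundances across samples, overlays per-genome vitamin-biosynthesis
capability calls derived from KEGG ortholog (KO) annotations, and scores
each producer with a *vitamin-hubness* metric whose significance is assessed
with a label-randomization null. The intended users are microbial ecologists
with a genome × sample abundance table (e.g. from read mapping of
metagenome-assembled genomes) and per-genome KO annotations.

## Method

**Compositional correlation.** Relative abundances are compositional, so
naive correlations are biased. The SparCC approach works on log-ratio
variances t_ij = Var[log(x_i/x_j)]; under a sparsity assumption the basis
(log-scale) variances ω_i² solve a linear system, and correlations follow as

    ρ_ij = (ω_i² + ω_j² − t_ij) / (2 ω_i ω_j),

with iterative exclusion of strongly correlated pairs and a median over
Dirichlet-resampled compositions. Pearson/Spearman backends and precomputed
matrices are supported as alternatives.

**Network.** Correlations ρ ≥ 0.35 (positive only, by default) become
weighted edges. Topology is summarized by unnormalized betweenness
centrality b(v) = Σ σ(s,t|v)/σ(s,t), density d = 2m/(n(n−1)), hub
delineation from elevated betweenness, and modularity-maximizing partitions
(Louvain, cross-checked with Girvan–Newman).

**Capability calls.** A vitamin pathway is an ordered list of stages, each
satisfied by any of a set of alternative KOs. All stages present ⇒
*complete*; only the exempt KO missing (thiamine: thiC/K03147) ⇒
*near-complete*; otherwise *absent*. Producers are complete (and, by
default policy, near-complete) genomes; all others are treated as
auxotrophs.

**Vitamin-hubness.** For a producer v,

    h(v) = D_total(v) · D_auxotroph(v) / [ (1/N) Σ_a P(a) ],

where D_total is v's degree, D_auxotroph (= N) its number of auxotrophic
neighbors, and P(a) counts producers adjacent to auxotrophic neighbor a
(including v). High h means many dependent neighbors with few alternative
providers. Significance: relabel nodes at random (preserving the observed
producer count, focal node forced producer by default), recompute h over
(default) 1000 draws, and report the null mean, sd, z and empirical p.

## Worked example

A synthetic community mimicking a 92-sample bioreactor series (120 genomes,
four correlated modules, 38 thiamine producers, and one planted producer hub
with eight dependent auxotrophs) is built in, so the full analysis runs
without any external data:

```python
from vitnet import *
from vitnet.io import PathwayCatalog

spec = SyntheticSpec(seed=7)
tab, meta, truth = simulate_community(spec)
cat = PathwayCatalog.default()
ann = simulate_annotations(truth, cat, spec)

corr = sparcc_correlations(tab, seed=7)
net = build_network(corr, threshold=0.35)
summary = summarize(net, part=detect_modules(net, "louvain", seed=7))
print(f"network: {summary.n} nodes, {summary.m} edges, "
      f"density {100*summary.d:.1f}%, modularity {summary.Q:.2f}")

labels = classify_roles(call_all_pathways(ann, cat), "thiamine")
net_labels = labels.restricted_to(net.nodes)
ranked = rank_hub_scores(net, net_labels)
for s in ranked[:3]:
    print(f"{s.node}: h={s.h:.1f} (degree {s.D_total}, "
          f"{s.D_auxotroph} auxotroph neighbors, mean alt. producers {s.denom:.2f})")

null = randomization_null(net, net_labels, ranked[0].node, n_sim=1000, seed=7)
print(f"null for {null.focal}: mean {null.mean:.1f}, sd {null.sd:.1f}, "
      f"z = {null.z:.2f}, empirical p = {null.empirical_p:.3f}")
```

prints

```
network: 111 nodes, 1237 edges, density 20.3%, modularity 0.76
g001: h=64.0 (degree 8, 8 auxotroph neighbors, mean alt. producers 1.00)
g035: h=51.0 (degree 24, 17 auxotroph neighbors, mean alt. producers 8.00)
g036: h=51.0 (degree 24, 17 auxotroph neighbors, mean alt. producers 8.00)
null for g001: mean 16.7, sd 13.0, z = 3.64, empirical p = 0.049
```

The planted hub `g001` tops the ranking: its eight correlated auxotrophs
have no provider other than it (mean alternative producers 1.00), so its
score collapses to degree × auxotroph-neighbors = 64. Under random
relabeling of producer status the expected score is ~17, putting the
observed score 3.6 standard deviations above the null mean — the signature
of a genuine provisioning hub rather than of producer scarcity alone.

The same analysis is available from the shell via subcommands
(`vitnet simulate`, `correlate`, `network`, `pathways`, `hubness`,
`ecology`, and `run` for a config-driven end-to-end pass); see
`vitnet --help`.

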