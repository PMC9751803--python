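# otunet

Signed microbial co-occurrence networks from OTU tables: random-matrix-theory
(RMT) threshold selection, topology against degree-preserving nulls,
Guimerà–Amaral keystone classification, and robustness-based stability
comparison between sample groups.

## The problem

Gut-microbiome studies routinely ask not just *which* taxa change between
groups, but whether the *interaction structure* of the community changes:
does an intervention make the microbial network denser, more modular, more
stable?  The standard workflow — popularised by the molecular ecological
network analysis (MENA) lineage of tools — goes:

1. filter an OTU count table to taxa present in ≥ 50% of samples;
2. correlate log₁₀ relative abundances of every OTU pair (Pearson *r*);
3. pick the similarity threshold *sₜ* **objectively** via RMT: scanning
   thresholds, the nearest-neighbour spacing distribution (NNSD) of the
   thresholded matrix's unfolded eigenvalues transitions from the
   Gaussian-orthogonal-ensemble (Wigner) law
   *P(d) = (πd/2)·exp(−πd²/4)* to the Poisson law *P(d) = e^(−d)*;
   the transition point — the smallest threshold whose spacings are
   statistically Poisson — defines the network;
4. keep every pair with |r| ≥ *sₜ* as a signed edge (+ co-occurrence,
   − exclusion), and compare topology (nodes N, links L, average degree
   2L/N, clustering, path distance, modularity
   *Q = Σₘ [lₘ/L − (dₘ/2L)²]*, power-law R²) against 100 degree-preserving
   (Maslov–Sneppen) rewired networks;
5. classify node roles in the Zi/Pi plane (within-module degree z-score
   vs. participation coefficient *Pᵢ = 1 − Σₛ(κ_is/kᵢ)²*); non-peripheral
   nodes (Zi ≥ 2.5 or Pi ≥ 0.62) are potential keystone taxa;
6. measure stability as **robustness**: the fraction of taxa still
   connected after removing 50% of nodes (random) or 50% of keystones
   (targeted), with secondary extinction of newly isolated taxa, compared
   across groups by one-way ANOVA.

`otunet` implements this pipeline as a tested Python library, plus a
synthetic-data generator that plants correlation modules, hubs, and signed
associations in compositional count data — so every stage can be validated
against known ground truth without any sequencing data.

## Worked example

```python
from otunet import (CommunitySpec, generate_community, prevalence_filter,
                    log_relative_abundance, pearson_similarity,
                    scan_thresholds, select_threshold, build_network,
                    edge_sign_proportions)

table, truth = generate_community(CommunitySpec(n_samples=24, seed=7))
filtered = prevalence_filter(table)                  # >= 50% prevalence
abund = log_relative_abundance(filtered, full_table=table)
sim = pearson_similarity(abund.values)
threshold = select_threshold(scan_thresholds(sim))   # RMT transition point
net = build_network(sim, threshold, filtered.taxonomy)
print(threshold, net.n_nodes, net.n_edges, edge_sign_proportions(net))
```

prints

```
0.61 216 392 (82.39795918367346, 17.602040816326536)
```

i.e. the NNSD turns Poisson at *sₜ* = 0.61, giving a network of 216 taxa
and 392 edges, 82.4% of them co-occurrences — close to the 78.4% positive
associations the generator planted.  Comparing that network against 100
degree-preserving rewirings (`random_ensemble`) gives, for the same seed
family,

```
property              observed  null mean  null sd       z
clustering               0.375      0.048    0.010    32.9
modularity               0.765      0.460    0.007    45.7
```

— clustering and modularity far above the null, the signature of genuine
modular ecological structure.  The scripts in `examples/` walk through each
capability (simulation, threshold selection, null-model comparison,
keystones, stability contrast) and print the interpretation alongside the
numbers.

## Layout

| path | contents |
| --- | --- |
| `src/otunet/otu_table.py` | OTU table I/O, prevalence filter, log relative abundance, alpha diversity |
| `src/otunet/rmt.py` | Pearson similarity, spectral unfolding, NNSD χ², threshold scan/selection, network construction |
| `src/otunet/topology.py` | global properties, power-law R², Maslov–Sneppen nulls, ensemble z-scores |
| `src/otunet/communities.py` | greedy modularity, Zi/Pi roles, keystones, module composition |
| `src/otunet/stability.py` | secondary extinction, robustness, ANOVA + Tukey letters |
| `src/otunet/synthetic.py` | ground-truth community generator, GOE/block matrices, two-group scenarios |
| `src/otunet/pipeline.py`, `cli.py` | per-group orchestration, TSV/GraphML artifacts, `otunet` CLI |

The CLI (`otunet simulate | build-network | topology | modules |
robustness | run | compare`) is a thin layer over these functions; GraphML
and node/edge TSV outputs load directly into Gephi or Cytoscape.
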