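"""Compare network stability between a sparse and a dense community.

Robustness = fraction of taxa still connected after removing 50% of
nodes at random (plus secondary extinction of newly isolated taxa).
A better-connected community should tolerate removal better — the
complexity-begets-stability pattern.
"""

from otunet import (
    CommunitySpec,
    RemovalScheme,
    build_network,
    compare_robustness,
    generate_two_group_scenario,
    log_relative_abundance,
    pearson_similarity,
    prevalence_filter,
    robustness,
    scan_thresholds,
    select_threshold,
)

spec_a = CommunitySpec(seed=2, n_samples=24, rho=0.65, loading_range=(0.5, 0.85))
(table_a, _), (table_b, _) = generate_two_group_scenario(spec_a)

sims = {}
for name, table in (("control", table_a), ("dense", table_b)):
    filtered = prevalence_filter(table)
    ab = log_relative_abundance(filtered, full_table=table)
    sims[name] = (pearson_similarity(ab.values), filtered)

# one shared threshold across both networks, as when several group
# networks of a study are built under the same similarity cutoff
shared = max(select_threshold(scan_thresholds(s)) for s, _ in sims.values())
print(f"shared similarity threshold: {shared:.2f}")

results = {}
for name, (sim, filtered) in sims.items():
    net = build_network(sim, shared, filtered.taxonomy, group=name)
    results[name] = robustness(
        net, RemovalScheme("random_nodes", fraction=0.5, repetitions=100, seed=9)
    )
    print(
        f"{name}: N={net.n_nodes} L={net.n_edges} "
        f"robustness={results[name].mean:.3f} +/- {results[name].sd:.3f}"
    )

cmp = compare_robustness(results)
print(f"\none-way ANOVA: F={cmp['F']:.1f}, p={cmp['p']:.2e}")
print(
    "the denser community keeps a larger fraction of taxa connected "
    "after losing half its nodes — higher robustness means a more "
    "stable co-occurrence structure."
)
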