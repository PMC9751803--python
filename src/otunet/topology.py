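"""Global network topology and degree-preserving null ensembles.

The summary statistics are the standard molecular-ecological-network set:
node and link counts, average degree ``2L/N``, average clustering
coefficient, average path distance over connected pairs, modularity of the
detected partition, and the R-squared of a log-log degree-frequency
regression (the "scale-free" fit).  Significance of the empirical values
is judged against an ensemble of degree-preserving rewired networks
(Maslov-Sneppen double-edge swaps): z-scores report how many ensemble
standard deviations the observed network lies above random expectation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .communities import detect_modules
from .rmt import CoNetwork

logger = logging.getLogger(__name__)

#: properties recomputed for every ensemble member
ENSEMBLE_PROPERTIES = ("avg_clustering", "avg_path_distance", "modularity")


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    avg_degree: float
    avg_clustering: float
    avg_path_distance: float
    modularity: float
    powerlaw_r2: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "avg_degree": self.avg_degree,
            "avg_clustering": self.avg_clustering,
            "avg_path_distance": self.avg_path_distance,
            "modularity": self.modularity,
            "powerlaw_r2": self.powerlaw_r2,
        }


@dataclass
class RandomEnsembleSummary:
    """Mean, sd and z-score of topology properties over rewired networks."""

    n_networks: int
    mean: dict[str, float]
    sd: dict[str, float]
    z: dict[str, float]  # NaN where ensemble sd is 0
    seed: int | None = None


def average_path_distance(g: nx.Graph, largest_component_only: bool = False) -> float:
    """Mean shortest-path length over connected node pairs.

    Disconnected pairs are excluded from the average (so two disjoint
    triangles have distance 1).  With ``largest_component_only`` the
    calculation is restricted to the largest connected component.
    """
    if g.number_of_nodes() <= 1 or g.number_of_edges() == 0:
        return float("nan")
    if largest_component_only:
        comp = max(nx.connected_components(g), key=len)
        g = g.subgraph(comp)
    total = 0.0
    n_pairs = 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
        n_pairs += len(comp) * (len(comp) - 1)
    if n_pairs == 0:
        return float("nan")
    return total / n_pairs  # each unordered pair counted twice, cancels


def powerlaw_r2(degrees) -> float:
    """R-squared of the log10(frequency) ~ log10(degree) regression.

    The "scale-free" fit reported for molecular ecological networks: raw
    degree frequencies for k >= 1 on log-log axes, ordinary least squares.
    Returns NaN (with a warning) when fewer than 2 distinct positive
    degrees exist.
    """
    deg = np.asarray(list(degrees), dtype=float)
    deg = deg[deg >= 1]
    ks, counts = np.unique(deg, return_counts=True)
    if ks.size < 2:
        logger.warning("degree distribution degenerate; power-law R2 undefined")
        return float("nan")
    if ks.size < 3:
        logger.warning("only %d distinct degrees; power-law fit unstable", ks.size)
    res = stats.linregress(np.log10(ks), np.log10(counts))
    return float(res.rvalue**2)


def global_properties(
    net: CoNetwork, seed: int | None = None, partition: dict | None = None
) -> TopologySummary:
    """Compute the topology summary of a co-occurrence network.

    Local clustering of degree-<2 nodes counts as 0 and is included in the
    average; path distance averages over connected pairs only; modularity
    comes from greedy module detection unless a partition is supplied.
    """
    g = net.graph
    n, l = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValueError("empty network")
    if partition is None:
        part = detect_modules(net)
        q = part.modularity
    else:
        from .communities import modularity as _q

        q = _q(net, partition)
    return TopologySummary(
        n_nodes=n,
        n_edges=l,
        avg_degree=2.0 * l / n,
        avg_clustering=float(nx.average_clustering(g)),
        avg_path_distance=average_path_distance(g),
        modularity=q,
        powerlaw_r2=powerlaw_r2([d for _, d in g.degree()]),
    )


def rewire_degree_preserving(
    net: CoNetwork, n_swaps: int | None = None, seed: int | None = None
) -> CoNetwork:
    """Degree-preserving randomization by double-edge swaps.

    Performs ``n_swaps`` (default ``10 * L``) Maslov-Sneppen swaps that
    reject self-loops and multi-edges, so every node keeps its degree
    while edges are shuffled.  Edge signs are reassigned at random
    preserving the empirical sign ratio; weights are dropped (the null
    model randomizes topology, not correlation values).
    """
    g = net.graph.copy()
    l = g.number_of_edges()
    if l < 2:
        logger.warning("fewer than 2 edges; returning copy without rewiring")
        return CoNetwork(graph=g, threshold=net.threshold, group=net.group)
    if n_swaps is None:
        n_swaps = 10 * l
    rng = np.random.default_rng(seed)
    try:
        nx.double_edge_swap(
            g,
            nswap=n_swaps,
            max_tries=100 * n_swaps,
            seed=int(rng.integers(2**31 - 1)),
        )
    except nx.NetworkXError as exc:  # no valid swap left
        logger.warning("rewiring stopped early: %s", exc)
    n_pos = sum(1 for _, _, d in net.graph.edges(data=True) if d.get("sign", 1) > 0)
    signs = np.array([1] * n_pos + [-1] * (l - n_pos))
    rng.shuffle(signs)
    for s, (u, v) in zip(signs, g.edges()):
        g.edges[u, v].clear()
        g.edges[u, v]["sign"] = int(s)
    return CoNetwork(graph=g, threshold=net.threshold, group=net.group)


def random_ensemble(
    net: CoNetwork, n: int = 100, seed: int | None = None
) -> RandomEnsembleSummary:
    """Compare a network against ``n`` degree-preserving rewirings.

    Degree-dependent properties (N, L, average degree, degree-distribution
    fit) are identical across the ensemble by construction, so only
    clustering, path distance and modularity are summarised; ``z`` is
    ``(observed - ensemble mean) / ensemble sd`` and NaN when the sd is 0.
    """
    if n < 2:
        raise ValueError("ensemble needs n >= 2 for a standard deviation")
    rng = np.random.default_rng(seed)
    obs = global_properties(net)
    values: dict[str, list[float]] = {p: [] for p in ENSEMBLE_PROPERTIES}
    for _ in range(n):
        member = rewire_degree_preserving(net, seed=int(rng.integers(2**31 - 1)))
        summary = global_properties(member)
        for p in ENSEMBLE_PROPERTIES:
            values[p].append(getattr(summary, p))
    mean = {p: float(np.mean(values[p])) for p in ENSEMBLE_PROPERTIES}
    sd = {p: float(np.std(values[p], ddof=1)) for p in ENSEMBLE_PROPERTIES}
    z = {}
    for p in ENSEMBLE_PROPERTIES:
        if sd[p] == 0:
            z[p] = float("nan")
            logger.warning("ensemble sd of %s is 0; z undefined", p)
        else:
            z[p] = (getattr(obs, p) - mean[p]) / sd[p]
    return RandomEnsembleSummary(n_networks=n, mean=mean, sd=sd, z=z, seed=seed)


def brute_force_path_distance(g: nx.Graph) -> float:
    """All-pairs BFS-free oracle: Floyd-Warshall over connected pairs.

    Exponent-free but O(n^3); intended for cross-checks on tiny graphs.
    """
    nodes = list(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0)
    for u, v in g.edges:
        dist[idx[u], idx[v]] = dist[idx[v], idx[u]] = 1
    for k in range(n):
        dist = np.minimum(dist, dist[:, k : k + 1] + dist[k : k + 1, :])
    iu = np.triu_indices(n, 1)
    finite = dist[iu][np.isfinite(dist[iu])]
    return float(finite.mean()) if finite.size else float("nan")


def brute_force_clustering(g: nx.Graph) -> float:
    """Average local clustering by explicit triple enumeration."""
    total = 0.0
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b)
        )
        total += 2.0 * links / (k * (k - 1))
    return total / g.number_of_nodes()
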