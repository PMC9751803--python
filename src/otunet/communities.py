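"""Module detection, modularity, and Zi/Pi keystone classification.

Modules are communities maximising Newman modularity

    Q = sum_m [ l_m / L - (d_m / 2L)^2 ]

(within-module link fraction minus its degree-based expectation), found by
greedy agglomeration.  Node roles follow the Guimera-Amaral scheme: the
within-module degree z-score ``Zi`` measures how much of a hub a node is
inside its own module, the participation coefficient
``Pi = 1 - sum_s (k_is / k_i)^2`` how evenly its links spread over
modules.  Nodes with ``Zi >= 2.5`` are module hubs, ``Pi >= 0.62``
connectors, both network hubs; any non-peripheral node is flagged as a
potential keystone taxon.  Edges are treated as unweighted and unsigned
throughout — the sign structure is analysed separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .rmt import CoNetwork

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62
LARGE_MODULE_MIN_SIZE = 5


@dataclass
class ModulePartition:
    """Node -> module assignment with its modularity score.

    Module ids are integers ordered by decreasing size (ties: smallest
    member node id first), so the labelling is deterministic.
    """

    assignment: dict[str, int]
    modularity: float

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, module_id: int) -> list[str]:
        return sorted(n for n, m in self.assignment.items() if m == module_id)

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for m in self.assignment.values():
            out[m] = out.get(m, 0) + 1
        return dict(sorted(out.items()))

    def large_modules(self, min_size: int = LARGE_MODULE_MIN_SIZE) -> list[int]:
        return [m for m, s in self.sizes().items() if s >= min_size]


@dataclass
class NodeRole:
    node: str
    module: int
    degree: int
    zi: float
    pi: float
    role: str  # peripheral | module hub | connector | network hub
    keystone: bool


def detect_modules(net: CoNetwork, resolution: float = 1.0) -> ModulePartition:
    """Greedy modularity maximisation (Clauset-Newman-Moore agglomeration).

    Deterministic for a fixed graph: nodes are inserted in sorted order at
    network construction and the greedy merge sequence is tie-stable.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if g.number_of_edges() == 0:
        communities = [{n} for n in sorted(g.nodes)]
    else:
        communities = nx.community.greedy_modularity_communities(
            g, resolution=resolution
        )
    ordered = sorted(communities, key=lambda c: (-len(c), min(str(n) for n in c)))
    assignment = {n: i for i, c in enumerate(ordered) for n in c}
    q = modularity_from_assignment(g, assignment)
    return ModulePartition(assignment=assignment, modularity=q)


def modularity_from_assignment(g: nx.Graph, assignment: dict) -> float:
    groups: dict[int, set] = {}
    for n, m in assignment.items():
        groups.setdefault(m, set()).add(n)
    if g.number_of_edges() == 0:
        return 0.0
    return float(nx.community.modularity(g, list(groups.values()), weight=None))


def modularity(net: CoNetwork, partition: ModulePartition | dict) -> float:
    """Newman Q of an arbitrary partition (unweighted edges)."""
    assignment = (
        partition.assignment if isinstance(partition, ModulePartition) else partition
    )
    missing = set(net.graph.nodes) - set(assignment)
    if missing:
        raise ValueError(f"partition misses nodes: {sorted(missing)[:5]} ...")
    return modularity_from_assignment(net.graph, assignment)


def node_roles(
    net: CoNetwork,
    partition: ModulePartition | dict,
    zi_threshold: float = ZI_THRESHOLD,
    pi_threshold: float = PI_THRESHOLD,
) -> pd.DataFrame:
    """Guimera-Amaral Zi/Pi coordinates and role for every node.

    ``Zi = (k_i_in - mean) / sd`` with mean/sd of within-module degree
    taken over the node's module (population sd; ``Zi = 0`` when sd is 0).
    ``Pi = 1 - sum_s (k_is / k_i)^2``.  Returns a DataFrame indexed by
    node with columns module, degree, zi, pi, role, keystone.
    """
    assignment = (
        partition.assignment if isinstance(partition, ModulePartition) else partition
    )
    g = net.graph
    missing = set(g.nodes) - set(assignment)
    if missing:
        raise ValueError(f"partition misses nodes: {sorted(missing)[:5]} ...")
    isolated = [n for n in g.nodes if g.degree(n) == 0]
    if isolated:
        raise ValueError(f"isolated nodes in network: {isolated[:5]}")

    # within-module degree of every node
    kappa = {
        n: sum(1 for nb in g.neighbors(n) if assignment[nb] == assignment[n])
        for n in g.nodes
    }
    by_module: dict[int, list[str]] = {}
    for n in g.nodes:
        by_module.setdefault(assignment[n], []).append(n)
    stats: dict[int, tuple[float, float]] = {}
    for m, members in by_module.items():
        vals = [kappa[n] for n in members]
        mean = sum(vals) / len(vals)
        var = sum((v - mean) ** 2 for v in vals) / len(vals)
        stats[m] = (mean, var**0.5)

    rows = []
    for n in sorted(g.nodes, key=str):
        m = assignment[n]
        mean, sd = stats[m]
        zi = 0.0 if sd == 0 else (kappa[n] - mean) / sd
        k = g.degree(n)
        per_module: dict[int, int] = {}
        for nb in g.neighbors(n):
            per_module[assignment[nb]] = per_module.get(assignment[nb], 0) + 1
        pi = 1.0 - sum((c / k) ** 2 for c in per_module.values())
        is_mh = zi >= zi_threshold
        is_co = pi >= pi_threshold
        role = (
            "network hub"
            if is_mh and is_co
            else "module hub"
            if is_mh
            else "connector"
            if is_co
            else "peripheral"
        )
        rows.append(
            {
                "node": n,
                "module": m,
                "degree": k,
                "zi": zi,
                "pi": pi,
                "role": role,
                "keystone": role != "peripheral",
            }
        )
    return pd.DataFrame(rows).set_index("node")


def keystones(roles: pd.DataFrame) -> list[str]:
    """Potential keystone taxa: all non-peripheral nodes."""
    return list(roles.index[roles["keystone"]])


def module_composition(
    net: CoNetwork,
    partition: ModulePartition | dict,
    min_size: int = LARGE_MODULE_MIN_SIZE,
) -> pd.DataFrame:
    """Phylum composition of every large module (size >= ``min_size``).

    Returns one row per (module, phylum) with the proportion of module
    nodes in that phylum and the module's dominant phylum.
    """
    assignment = (
        partition.assignment if isinstance(partition, ModulePartition) else partition
    )
    by_module: dict[int, list[str]] = {}
    for n, m in assignment.items():
        by_module.setdefault(m, []).append(n)
    rows = []
    for m in sorted(by_module):
        members = by_module[m]
        if len(members) < min_size:
            continue
        phyla: dict[str, int] = {}
        for n in members:
            ph = net.graph.nodes[n].get("phylum", "Unclassified")
            phyla[ph] = phyla.get(ph, 0) + 1
        dominant = max(sorted(phyla), key=lambda p: phyla[p])
        for ph in sorted(phyla):
            rows.append(
                {
                    "module": m,
                    "size": len(members),
                    "phylum": ph,
                    "proportion": phyla[ph] / len(members),
                    "dominant_phylum": dominant,
                }
            )
    return pd.DataFrame(
        rows, columns=["module", "size", "phylum", "proportion", "dominant_phylum"]
    )
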