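"""Network robustness under random and keystone-targeted node removal.

Robustness is the fraction of the original taxa still connected after a
perturbation: a set of nodes is deleted, then any node left with no
remaining link goes "secondarily extinct" (iterated until stable), and
the surviving fraction is recorded.  Random removal deletes half the
nodes; targeted removal deletes half the potential keystones — the attack
scenario.  Distributions over repetitions are compared across groups by
one-way ANOVA with a Tukey HSD compact letter display for more than two
groups (groups sharing a letter are not significantly different).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .rmt import CoNetwork

RANDOM_NODES = "random_nodes"
TARGETED_KEYSTONES = "targeted_keystones"


@dataclass
class RemovalScheme:
    kind: str = RANDOM_NODES
    fraction: float = 0.5
    repetitions: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in (RANDOM_NODES, TARGETED_KEYSTONES):
            raise ValueError(f"unknown removal scheme {self.kind!r}")
        if not 0 < self.fraction < 1:
            raise ValueError("fraction must be in (0, 1)")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class RobustnessResult:
    values: np.ndarray  # one surviving fraction per repetition
    scheme: RemovalScheme
    group: str = ""

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0


def secondary_extinction(net: CoNetwork, removed) -> set:
    """Survivors after removing ``removed`` and cascading isolation.

    Nodes whose remaining degree drops to zero are deleted iteratively
    (isolated = extinct); the rule is deterministic and abundance-free.
    """
    removed = set(removed)
    unknown = removed - set(net.graph.nodes)
    if unknown:
        raise ValueError(f"nodes not in network: {sorted(unknown)[:5]}")
    g = net.graph.copy()
    g.remove_nodes_from(removed)
    while True:
        isolated = [n for n, d in g.degree() if d == 0]
        if not isolated:
            break
        g.remove_nodes_from(isolated)
    return set(g.nodes)


def robustness(
    net: CoNetwork,
    scheme: RemovalScheme,
    keystones=None,
) -> RobustnessResult:
    """Distribution of surviving fractions under a removal scheme.

    ``random_nodes``: each repetition removes ``floor(fraction * N)``
    uniformly chosen nodes.  ``targeted_keystones``: removes
    ``ceil(fraction * |keystones|)`` keystones (a random subset per
    repetition when more keystones exist than are removed).  Survivors
    are counted after the secondary-extinction cascade and divided by the
    original node count N.
    """
    nodes = sorted(net.graph.nodes, key=str)
    n = len(nodes)
    rng = np.random.default_rng(scheme.seed)
    if scheme.kind == TARGETED_KEYSTONES:
        if not keystones:
            raise ValueError(
                "targeted scheme needs a non-empty keystone set; "
                "use the random_nodes scheme for networks without keystones"
            )
        pool = sorted(set(keystones), key=str)
        missing = set(pool) - set(nodes)
        if missing:
            raise ValueError(f"keystones not in network: {sorted(missing)[:5]}")
        n_remove = int(np.ceil(scheme.fraction * len(pool)))
    else:
        pool = nodes
        n_remove = int(np.floor(scheme.fraction * n))

    values = np.empty(scheme.repetitions)
    for i in range(scheme.repetitions):
        chosen = rng.choice(len(pool), size=n_remove, replace=False)
        removed = {pool[j] for j in chosen}
        survivors = secondary_extinction(net, removed)
        values[i] = len(survivors) / n
    return RobustnessResult(values=values, scheme=scheme, group=net.group)


def _compact_letter_display(
    groups: list[str], significant: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different; every pair
    not in ``significant`` shares at least one letter.
    """
    letter_sets: list[set[str]] = [set(groups)]
    for a, b in sorted(significant):
        new_sets: list[set[str]] = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb subsets
        letter_sets = []
        for s in sorted(new_sets, key=lambda x: (-len(x), sorted(x))):
            if s and not any(s <= t for t in letter_sets):
                letter_sets.append(s)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def compare_robustness(
    results: dict[str, RobustnessResult], alpha: float = 0.05
) -> dict:
    """One-way ANOVA across groups of per-repetition robustness values.

    For more than two groups a Tukey HSD compact letter display is added
    (groups labelled with the same letter do not differ at ``alpha``).
    Returns a dict with F, p, per-group mean/sd, and letters.
    """
    if len(results) < 2:
        raise ValueError("need at least two groups")
    for g, r in results.items():
        if len(r.values) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 repetitions")
    names = list(results)
    arrays = [results[g].values for g in names]
    if all(np.array_equal(arrays[0], a) for a in arrays[1:]):
        f, p = 0.0, 1.0  # identical distributions: no evidence of difference
    else:
        f, p = stats.f_oneway(*arrays)
        if not np.isfinite(f):
            f, p = 0.0, 1.0
    summary = {
        "F": float(f),
        "p": float(p),
        "groups": {
            g: {"mean": results[g].mean, "sd": results[g].sd, "n": len(results[g].values)}
            for g in names
        },
    }
    if len(names) > 2:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values = np.concatenate(arrays)
        labels = np.concatenate([[g] * len(a) for g, a in zip(names, arrays)])
        if np.ptp(values) == 0:
            significant: set[tuple[str, str]] = set()
        else:
            tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
            significant = {
                tuple(sorted((g1, g2)))
                for (g1, g2), rej in zip(
                    ((r[0], r[1]) for r in tk.summary().data[1:]), tk.reject
                )
                if rej
            }
        summary["letters"] = _compact_letter_display(names, significant)
    else:
        summary["letters"] = (
            {names[0]: "a", names[1]: "a"}
            if p >= alpha
            else {names[0]: "a", names[1]: "b"}
        )
    return summary
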