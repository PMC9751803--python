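"""End-to-end per-group pipeline and cross-group comparison.

One co-occurrence network is built per metadata group: prevalence
filtering within the group, log relative abundance, Pearson similarity,
RMT threshold (auto per group, or one shared fixed value as when a single
threshold is applied across all networks of a study), network
construction, topology against a degree-preserving null ensemble, module
and keystone detection, and robustness under random and keystone-targeted
removal.  All artifacts are written as TSV/GraphML/JSON plus a manifest
that records the configuration and seeds, so a rerun with the same
manifest reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .communities import (
    detect_modules,
    keystones,
    module_composition,
    node_roles,
)
from .otu_table import (
    OtuTable,
    alpha_diversity,
    compare_alpha,
    log_relative_abundance,
    prevalence_filter,
    read_otu_table,
)
from .rmt import (
    CoNetwork,
    build_network,
    edge_sign_proportions,
    pearson_similarity,
    scan_thresholds,
    select_threshold,
)
from .stability import (
    RANDOM_NODES,
    TARGETED_KEYSTONES,
    RemovalScheme,
    RobustnessResult,
    compare_robustness,
    robustness,
)
from .topology import global_properties, random_ensemble

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Everything a run needs; serialised into the run manifest."""

    min_prevalence: float = 0.5
    zero_factor: float = 0.01
    correlation: str = "pearson"
    threshold_mode: str = "auto"      # "auto" per group or "fixed"
    fixed_threshold: float | None = None
    scan_min: float = 0.30
    scan_max: float = 0.99
    scan_step: float = 0.01
    ensemble_size: int = 100
    removal_fraction: float = 0.5
    repetitions: int = 100
    shannon_base: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("auto", "fixed"):
            raise ValueError("threshold_mode must be 'auto' or 'fixed'")
        if self.threshold_mode == "fixed":
            if self.fixed_threshold is None or not 0 < self.fixed_threshold < 1:
                raise ValueError("fixed threshold mode needs a value in (0, 1)")


@dataclass
class GroupResult:
    group: str
    threshold: float
    network: CoNetwork
    topology: dict
    ensemble: dict
    sign_proportions: tuple[float, float]
    n_keystones: int
    robustness_random: RobustnessResult
    robustness_targeted: RobustnessResult | None
    roles: pd.DataFrame


@dataclass
class PipelineResult:
    groups: dict[str, GroupResult]
    alpha: pd.DataFrame
    alpha_anova: dict
    robustness_anova: dict
    config: PipelineConfig
    output_dir: Path | None = None


def _analyse_group(
    table: OtuTable, group: str, config: PipelineConfig, seed: int
) -> GroupResult:
    sub = table.subset_group(group)
    filt = prevalence_filter(sub, config.min_prevalence)
    abund = log_relative_abundance(filt, config.zero_factor, full_table=sub)
    sim = pearson_similarity(abund.values, method=config.correlation)
    if config.threshold_mode == "fixed":
        threshold = float(config.fixed_threshold)
    else:
        scan = scan_thresholds(
            sim, config.scan_min, config.scan_max, config.scan_step
        )
        threshold = select_threshold(scan)
    net = build_network(sim, threshold, filt.taxonomy, group=group)

    partition = detect_modules(net)
    roles = node_roles(net, partition)
    keys = keystones(roles)
    topo = global_properties(net, partition=partition)
    ens = random_ensemble(net, n=config.ensemble_size, seed=seed)

    rnd = robustness(
        net,
        RemovalScheme(
            RANDOM_NODES, config.removal_fraction, config.repetitions, seed + 1
        ),
    )
    targ = None
    if keys:
        targ = robustness(
            net,
            RemovalScheme(
                TARGETED_KEYSTONES,
                config.removal_fraction,
                config.repetitions,
                seed + 2,
            ),
            keystones=keys,
        )
    return GroupResult(
        group=group,
        threshold=threshold,
        network=net,
        topology=topo.as_dict(),
        ensemble={"mean": ens.mean, "sd": ens.sd, "z": ens.z},
        sign_proportions=edge_sign_proportions(net),
        n_keystones=len(keys),
        robustness_random=rnd,
        robustness_targeted=targ,
        roles=roles,
    )


def run_pipeline(
    table: OtuTable,
    config: PipelineConfig | None = None,
    output_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis for every group in the table's metadata.

    When ``output_dir`` is given, per-group artifacts (filtered table,
    similarity matrix, threshold scan, GraphML network, node/edge TSVs,
    reports) and cross-group comparison tables are written there together
    with a run manifest.
    """
    config = config or PipelineConfig()
    groups = table.groups()
    if not groups:
        raise ValueError("no groups in metadata")
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    results: dict[str, GroupResult] = {}
    for i, group in enumerate(groups):
        seed = config.seed + 1000 * (i + 1)
        logger.info("analysing group %s (seed %d)", group, seed)
        try:
            res = _analyse_group(table, group, config, seed)
        except Exception as exc:
            _write_manifest(out, config, groups, failed_at=group, error=str(exc))
            raise RuntimeError(f"pipeline failed at group {group!r}: {exc}") from exc
        results[group] = res
        if out is not None:
            _write_group(out, table, res, config)

    alpha = alpha_diversity(table, base=config.shannon_base)
    alpha_groups = [
        alpha.loc[alpha["group"] == g, "shannon"].values for g in groups
    ]
    alpha_anova = (
        compare_alpha(alpha_groups)
        if len(groups) >= 2 and all(len(a) >= 2 for a in alpha_groups)
        else {"F": float("nan"), "p": float("nan")}
    )
    rob_anova = (
        compare_robustness({g: r.robustness_random for g, r in results.items()})
        if len(groups) >= 2
        else {"F": float("nan"), "p": float("nan")}
    )

    result = PipelineResult(
        groups=results,
        alpha=alpha,
        alpha_anova=alpha_anova,
        robustness_anova=rob_anova,
        config=config,
        output_dir=out,
    )
    if out is not None:
        _write_cross_group(out, result)
        _write_manifest(out, config, groups)
    return result


def read_and_run(
    otu_path, metadata_path, config: PipelineConfig | None = None, output_dir=None
) -> PipelineResult:
    """Convenience wrapper: read input files then run the pipeline."""
    table = read_otu_table(otu_path, metadata_path)
    return run_pipeline(table, config=config, output_dir=output_dir)


def compare_groups(result: PipelineResult, contrasts: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Pairwise property deltas between group networks (later minus earlier).

    ``contrasts`` lists (group_a, group_b) pairs; default: consecutive
    groups in metadata order.
    """
    groups = list(result.groups)
    if contrasts is None:
        contrasts = list(zip(groups[:-1], groups[1:]))
    unmatched = [g for pair in contrasts for g in pair if g not in result.groups]
    if unmatched:
        raise ValueError(f"unknown groups in contrast: {sorted(set(unmatched))}")
    rows = []
    for a, b in contrasts:
        ra, rb = result.groups[a], result.groups[b]
        row = {"group_a": a, "group_b": b}
        for prop in ("n_nodes", "n_edges", "avg_degree", "avg_clustering",
                     "avg_path_distance", "modularity", "powerlaw_r2"):
            row[f"delta_{prop}"] = rb.topology[prop] - ra.topology[prop]
        row["delta_positive_pct"] = (
            rb.sign_proportions[0] - ra.sign_proportions[0]
        )
        row["delta_robustness_random"] = (
            rb.robustness_random.mean - ra.robustness_random.mean
        )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# artifact writers


def _write_group(out: Path, table: OtuTable, res: GroupResult, config: PipelineConfig) -> None:
    gdir = out / f"group_{res.group}"
    gdir.mkdir(parents=True, exist_ok=True)

    sub = table.subset_group(res.group)
    filt = prevalence_filter(sub, config.min_prevalence)
    filt.to_tsv(gdir / "filtered_table.tsv")
    abund = log_relative_abundance(filt, config.zero_factor, full_table=sub)
    sim = pearson_similarity(abund.values, method=config.correlation)
    pd.DataFrame(sim.r, index=sim.otu_ids, columns=sim.otu_ids).to_csv(
        gdir / "similarity.tsv", sep="\t", float_format=_FLOAT_FMT
    )
    if config.threshold_mode == "auto":
        scan = scan_thresholds(sim, config.scan_min, config.scan_max, config.scan_step)
        select_threshold(scan)
        scan.to_frame().to_csv(
            gdir / "threshold_scan.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT,
        )

    nx.write_graphml(res.network.graph, gdir / "network.graphml")
    nodes = pd.DataFrame(
        [
            {"node": n, "phylum": d.get("phylum", "Unclassified")}
            for n, d in sorted(res.network.graph.nodes(data=True))
        ]
    )
    nodes = nodes.merge(res.roles.reset_index(), on="node", how="left")
    nodes.to_csv(gdir / "nodes.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    edges = pd.DataFrame(
        [
            {"source": u, "target": v, "weight": d["weight"], "sign": d["sign"]}
            for u, v, d in sorted(res.network.graph.edges(data=True))
        ]
    )
    edges.to_csv(gdir / "edges.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    part = detect_modules(res.network)
    module_composition(res.network, part).to_csv(
        gdir / "module_composition.tsv", sep="\t", index=False,
        float_format=_FLOAT_FMT,
    )

    topo = dict(res.topology)
    topo.update({f"ensemble_mean_{k}": v for k, v in res.ensemble["mean"].items()})
    topo.update({f"ensemble_sd_{k}": v for k, v in res.ensemble["sd"].items()})
    topo.update({f"z_{k}": v for k, v in res.ensemble["z"].items()})
    topo["threshold"] = res.threshold
    topo["positive_pct"], topo["negative_pct"] = res.sign_proportions
    topo["n_keystones"] = res.n_keystones
    pd.DataFrame([topo]).to_csv(
        gdir / "topology.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )

    rob_rows = [
        {"scheme": RANDOM_NODES, "repetition": i, "robustness": v}
        for i, v in enumerate(res.robustness_random.values)
    ]
    if res.robustness_targeted is not None:
        rob_rows += [
            {"scheme": TARGETED_KEYSTONES, "repetition": i, "robustness": v}
            for i, v in enumerate(res.robustness_targeted.values)
        ]
    pd.DataFrame(rob_rows).to_csv(
        gdir / "robustness.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )


def _write_cross_group(out: Path, result: PipelineResult) -> None:
    rows = []
    for g, r in result.groups.items():
        row = {"group": g, "threshold": r.threshold}
        row.update(r.topology)
        row["positive_pct"], row["negative_pct"] = r.sign_proportions
        row["n_keystones"] = r.n_keystones
        row["robustness_random_mean"] = r.robustness_random.mean
        row["robustness_random_sd"] = r.robustness_random.sd
        if r.robustness_targeted is not None:
            row["robustness_targeted_mean"] = r.robustness_targeted.mean
            row["robustness_targeted_sd"] = r.robustness_targeted.sd
        rows.append(row)
    pd.DataFrame(rows).to_csv(
        out / "group_summary.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    result.alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", float_format=_FLOAT_FMT)
    stat_rows = [
        {"comparison": "alpha_shannon", **{k: v for k, v in result.alpha_anova.items() if not isinstance(v, dict)}},
        {"comparison": "robustness_random", **{k: v for k, v in result.robustness_anova.items() if not isinstance(v, dict)}},
    ]
    pd.DataFrame(stat_rows).to_csv(
        out / "group_tests.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )


def _write_manifest(
    out: Path | None,
    config: PipelineConfig,
    groups: list[str],
    failed_at: str | None = None,
    error: str | None = None,
) -> None:
    if out is None:
        return
    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "groups": groups,
        "status": "failed" if failed_at else "ok",
    }
    if failed_at:
        manifest["failed_at"] = failed_at
        manifest["error"] = error
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
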