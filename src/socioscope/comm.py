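"""Multimodal signal co-occurrence networks.

Nodes are signal components (ear positions, vocalizations, touches, ...);
an edge weight counts the multimodal postures in which two components were
produced concurrently.  Because components within one morphological group
(e.g. the ear positions) are mutually exclusive, some node pairs can never
co-occur; the adjusted density divides observed edges by the possible pairs
after removing those impossible connections:

    adjusted density = |E| / ( C(n,2) - sum_g n_g (n_g - 1) / 2 )

over the morphological groups g present in the network.  Repertoire-level
comparisons across time periods use resampling nulls: a posture-subsampling
(jackknife) null for component diversity and a node-subsampling null for
adjusted density, each with a two-tailed 0.025/0.975-percentile decision.
Context modules come from greedy (Clauset-Newman-Moore) modularity
maximization on the weighted graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence
import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .ingest import Ethogram, InteractionRecord, Posture
from .stats import PermutationResult, two_sided_percentile_decision


@dataclass
class CleaningReport:
    postures_in: int
    postures_removed: int
    removed_components: dict[str, int]  # code -> number of interactions it appeared in
    passes: int = 1

    @property
    def postures_out(self) -> int:
        return self.postures_in - self.postures_removed


def _component_interaction_counts(interactions: Sequence[InteractionRecord]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rec in interactions:
        seen = set()
        for p in rec.postures:
            seen |= p.components
        for c in seen:
            counts[c] = counts.get(c, 0) + 1
    return counts


def clean_postures(interactions: Sequence[InteractionRecord],
                   min_interactions: int = 2,
                   to_fixpoint: bool = True) -> tuple[list[InteractionRecord], CleaningReport]:
    """Remove every posture containing a component observed in fewer than
    ``min_interactions`` distinct interactions.

    Rarely seen components cannot support reliable co-occurrence estimates,
    so postures contaminated by them are dropped wholesale.  Removing
    postures can drop a further component below threshold; by default the
    filter iterates to a fixpoint (``to_fixpoint=False`` gives the single
    pass).  Interactions left with no postures are dropped.
    """
    n_in = sum(len(r.postures) for r in interactions)
    removed: dict[str, int] = {}
    current = list(interactions)
    passes = 0
    while True:
        passes += 1
        counts = _component_interaction_counts(current)
        rare = {c for c, k in counts.items() if k < min_interactions}
        if not rare:
            break
        removed.update({c: counts[c] for c in rare})
        nxt = []
        for rec in current:
            kept = [p for p in rec.postures if not (p.components & rare)]
            if kept:
                nxt.append(
                    InteractionRecord(rec.interaction_id, rec.period_label,
                                      rec.focal_id, kept, rec.context_tag)
                )
        current = nxt
        if not to_fixpoint:
            break
    n_out = sum(len(r.postures) for r in current)
    report = CleaningReport(
        postures_in=n_in, postures_removed=n_in - n_out,
        removed_components=removed, passes=passes,
    )
    return current, report


@dataclass
class CommNetwork:
    """Undirected co-occurrence graph over signal components for one period."""

    period_label: str
    graph: nx.Graph
    groups: dict[str, str]  # component code -> morphological group id
    modules: dict[str, int] | None = None
    modularity_q: float | None = None

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def group_sizes(self, nodes: Iterable[str] | None = None) -> dict[str, int]:
        nodes = self.nodes if nodes is None else list(nodes)
        sizes: dict[str, int] = {}
        for v in nodes:
            g = self.groups.get(v, v)
            sizes[g] = sizes.get(g, 0) + 1
        return sizes


def postures_of(interactions: Sequence[InteractionRecord]) -> list[Posture]:
    return [p for rec in interactions for p in rec.postures]


def build_comm_network(interactions: Sequence[InteractionRecord],
                       ethogram: Ethogram,
                       period_label: str = "",
                       unit: str = "posture") -> CommNetwork:
    """Build the co-occurrence network from (cleaned) interactions.

    ``unit="posture"`` (default) counts the postures in which two components
    co-occur; ``unit="interaction"`` counts distinct interactions instead.
    Nodes include every component occurring in at least one posture.
    """
    g = nx.Graph()
    for rec in interactions:
        per_interaction: set[frozenset] = set()
        for p in rec.postures:
            p.validate_against(ethogram)
            g.add_nodes_from(p.components)
            for pair in itertools.combinations(sorted(p.components), 2):
                if unit == "interaction":
                    per_interaction.add(frozenset(pair))
                else:
                    u, v = pair
                    g.add_edge(u, v, weight=g.get_edge_data(u, v, {"weight": 0})["weight"] + 1)
        for pair in per_interaction:
            u, v = sorted(pair)
            g.add_edge(u, v, weight=g.get_edge_data(u, v, {"weight": 0})["weight"] + 1)
    groups = {c: ethogram.group_of(c) for c in g.nodes}
    return CommNetwork(period_label=period_label, graph=g, groups=groups)


def neutral_subgraph(net: CommNetwork, ethogram: Ethogram) -> CommNetwork:
    """Induced subgraph excluding the highly central neutral-state components
    (baseline states such as "eyes open"), preserving edge weights."""
    neutral = ethogram.neutral_codes
    if not neutral:
        warnings.warn("ethogram defines no neutral components; returning the "
                      "network unchanged", stacklevel=2)
    keep = [v for v in net.graph.nodes if v not in neutral]
    sub = net.graph.subgraph(keep).copy()
    return CommNetwork(
        period_label=net.period_label, graph=sub,
        groups={v: net.groups[v] for v in sub.nodes},
    )


def component_diversity(net: CommNetwork) -> int:
    """Number of connected nodes (degree >= 1) in the network."""
    return sum(1 for _, d in net.graph.degree if d > 0)


def impossible_pairs(group_sizes: Mapping[str, int] | Iterable[int]) -> int:
    """Number of within-group (mutually exclusive, hence impossible) node
    pairs: sum over groups of n(n-1)/2."""
    sizes = group_sizes.values() if isinstance(group_sizes, Mapping) else group_sizes
    return sum(n * (n - 1) // 2 for n in sizes)


def adjusted_density(net: CommNetwork, nodes: Sequence[str] | None = None) -> float | None:
    """Edges divided by possible pairs after removing impossible within-group
    pairs, computed on the node set of the network at hand (or the induced
    subgraph on ``nodes``).  None when fewer than 2 nodes or no possible pair
    remains."""
    if nodes is None:
        g = net.graph
        node_list = list(g.nodes)
    else:
        node_list = list(nodes)
        g = net.graph.subgraph(node_list)
    n = len(node_list)
    if n < 2:
        return None
    possible = n * (n - 1) // 2 - impossible_pairs(net.group_sizes(node_list))
    if possible <= 0:
        return None
    return g.number_of_edges() / possible


# ---------------------------------------------------------------------------
# resampling nulls
# ---------------------------------------------------------------------------


def _multi_component_incidence(postures: Sequence[Posture]):
    """Boolean posture x component incidence over multi-component postures
    (single-component postures create no edges, hence no connected nodes)."""
    codes = sorted({c for p in postures for c in p.components})
    index = {c: i for i, c in enumerate(codes)}
    rows = []
    for p in postures:
        if len(p.components) >= 2:
            row = np.zeros(len(codes), dtype=bool)
            for c in p.components:
                row[index[c]] = True
            rows.append(row)
    mat = np.array(rows, dtype=bool) if rows else np.zeros((0, len(codes)), dtype=bool)
    return mat, codes


def diversity_jackknife(postures_ref: Sequence[Posture],
                        observed_diversity: int,
                        n_sub: int,
                        n_perm: int = 1000,
                        seed: int | None = None,
                        alpha: float = 0.05) -> PermutationResult:
    """Posture-subsampling null for component diversity.

    Each replicate draws ``n_sub`` postures without replacement from the
    reference period, rebuilds the co-occurrence network, and records its
    diversity; the comparison period's observed diversity is then placed
    against the 0.025/0.975 percentiles of this null (two-tailed).
    """
    if n_sub > len(postures_ref):
        raise ValueError(f"n_sub={n_sub} exceeds the {len(postures_ref)} reference postures")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    mat, _ = _multi_component_incidence(postures_ref)
    n_total = len(postures_ref)
    multi_idx = np.array(
        [i for i, p in enumerate(postures_ref) if len(p.components) >= 2], dtype=np.intp
    )
    # map posture index -> row of mat
    row_of = {int(pi): ri for ri, pi in enumerate(multi_idx)}
    null = np.empty(n_perm)
    for r in range(n_perm):
        take = rng.choice(n_total, size=n_sub, replace=False)
        rows = [row_of[int(i)] for i in take if int(i) in row_of]
        if rows:
            null[r] = int(mat[rows].any(axis=0).sum())
        else:
            null[r] = 0
    sig, lo, hi = two_sided_percentile_decision(observed_diversity, null, alpha)
    return PermutationResult(
        observed=float(observed_diversity), null_values=null,
        p_value=min(float(np.mean(null >= observed_diversity)),
                    float(np.mean(null <= observed_diversity))),
        n_perm=n_perm, seed=seed, tail="two_sided", method="posture_jackknife",
        statistic="component_diversity", significant=sig, lower_cut=lo, upper_cut=hi,
    )


def density_node_subsample_null(net_ref: CommNetwork,
                                observed_density: float,
                                n_nodes_sub: int,
                                n_perm: int = 1000,
                                seed: int | None = None,
                                alpha: float = 0.05) -> PermutationResult:
    """Node-subsampling null for adjusted density.

    Each replicate induces the subgraph of the reference network on a uniform
    random node subset of size ``n_nodes_sub`` — preserving the connectivity
    of the sampled nodes — and recomputes the adjusted density with the
    subset's own group sizes.  This is the null of a pure repertoire-size
    reduction with no loss of combinatorial flexibility.  Two-tailed
    percentile decision as in :func:`diversity_jackknife`.
    """
    if n_nodes_sub < 2:
        raise ValueError("n_nodes_sub must be >= 2")
    nodes = net_ref.nodes
    if n_nodes_sub > len(nodes):
        raise ValueError(f"n_nodes_sub={n_nodes_sub} exceeds the {len(nodes)} reference nodes")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    node_arr = np.array(nodes, dtype=object)
    for r in range(n_perm):
        sub = node_arr[rng.choice(len(nodes), size=n_nodes_sub, replace=False)]
        d = adjusted_density(net_ref, list(sub))
        null[r] = np.nan if d is None else d
    null = null[~np.isnan(null)]
    sig, lo, hi = two_sided_percentile_decision(observed_density, null, alpha)
    return PermutationResult(
        observed=float(observed_density), null_values=null,
        p_value=min(float(np.mean(null >= observed_density)),
                    float(np.mean(null <= observed_density))),
        n_perm=n_perm, seed=seed, tail="two_sided", method="node_subsample",
        statistic="adjusted_density", significant=sig, lower_cut=lo, upper_cut=hi,
    )


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

MODULARITY_DISCRETE_THRESHOLD = 0.3  # conventional cutoff: > 0.3 ~ discrete modules


def detect_modules(net: CommNetwork) -> tuple[dict[str, int], float]:
    """Greedy agglomerative (Clauset-Newman-Moore) modularity maximization on
    the weighted graph.  Stores and returns the partition of nodes and its
    weighted modularity Q; isolated nodes each form their own module.  An
    edgeless graph yields singleton modules with Q = 0."""
    g = net.graph
    isolated = [v for v, d in g.degree if d == 0]
    core = g.subgraph([v for v in g.nodes if v not in isolated])
    if core.number_of_edges() == 0:
        modules = {v: i for i, v in enumerate(sorted(g.nodes))}
        net.modules, net.modularity_q = modules, 0.0
        return modules, 0.0
    communities = nx.community.greedy_modularity_communities(core, weight="weight")
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    modules: dict[str, int] = {}
    for i, comm in enumerate(communities):
        for v in comm:
            modules[v] = i
    q = nx.community.modularity(core, [set(c) for c in communities], weight="weight")
    for j, v in enumerate(sorted(isolated)):
        modules[v] = len(communities) + j
    net.modules, net.modularity_q = modules, float(q)
    return modules, float(q)


def compare_modules(net_pre: CommNetwork, net_late: CommNetwork) -> pd.DataFrame:
    """Long-format module-flow table across periods: one row per component
    present in the pre-period network (module_late is "LOST" for components
    absent late) plus rows for components gained late.  Suitable for
    alluvial-style plotting."""
    for net in (net_pre, net_late):
        if net.modules is None:
            detect_modules(net)
    rows = []
    pre_nodes, late_nodes = set(net_pre.nodes), set(net_late.nodes)
    for v in sorted(pre_nodes):
        rows.append(
            {"component": v,
             "module_pre": net_pre.modules[v],
             "module_late": net_late.modules[v] if v in late_nodes else "LOST",
             "status": ("retained" if v in late_nodes else "lost")}
        )
    for v in sorted(late_nodes - pre_nodes):
        rows.append(
            {"component": v, "module_pre": "ABSENT",
             "module_late": net_late.modules[v], "status": "gained"}
        )
    return pd.DataFrame(rows, columns=["component", "module_pre", "module_late", "status"])


def modality_loss_summary(net_pre: CommNetwork, net_late: CommNetwork,
                          ethogram: Ethogram) -> pd.DataFrame:
    """Per-modality counts and fractions of components present in the
    pre-period network but absent from the late-period network."""
    pre_nodes, late_nodes = set(net_pre.nodes), set(net_late.nodes)
    rows = []
    for modality in ("visual", "acoustic", "tactile", "chemical"):
        total = [v for v in sorted(pre_nodes) if ethogram[v].modality == modality]
        lost = [v for v in total if v not in late_nodes]
        rows.append(
            {"modality": modality, "lost": len(lost), "total": len(total),
             "fraction_lost": len(lost) / len(total) if total else 0.0}
        )
    return pd.DataFrame(rows, columns=["modality", "lost", "total", "fraction_lost"])
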