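"""Validation studies: oracle equivalence, calibration, and recovery.

These routines score the package's resampling tests against independent
ground truth: exhaustive enumeration on instances small enough to enumerate,
empirical rejection rates under null generators (which should sit at the
nominal level), and recovery of planted structure.  They are the same
studies the test suite runs; the acceptance script reports their numbers.

Study sizes are scaled-down but structurally faithful analogues of a field
campaign: single harems of 6 adults scanned over 40 sampling periods,
81-component signal inventories (24 components in multi-state morphological
groups, 57 free components) over ~100 coded interactions, and 200 inner
permutations per replicate (the analysis default is 1000; 200 keeps
replicated studies tractable while the exact-rank percentile cutoffs remain
level-accurate at any permutation count).
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from .association import HaremNetwork, build_harem_networks, preferred_associate_test
from .comm import (
    CommNetwork,
    adjusted_density,
    build_comm_network,
    clean_postures,
    density_node_subsample_null,
    detect_modules,
    diversity_jackknife,
    postures_of,
)
from .ingest import Component, Ethogram, InteractionRecord, Posture
from .synthetic import CommSimConfig, SocialSimConfig, simulate_interactions, simulate_scans

# frozen study conditions -----------------------------------------------------

CALIB_HAREM_SIZE = 6
CALIB_N_PERIODS = 40
CALIB_ALONE_PROB = 0.2
CALIB_PRESENCE_PROB = 0.95
INNER_N_PERM = 200

COMM_GROUP_SIZES = (6, 4, 4, 3, 3, 2, 2)   # 24 multi-state components
COMM_N_SINGLETONS = 57                      # + 57 free components = 81 total
COMM_N_INTERACTIONS = 100
COMM_RATE_LOG10_RANGE = (-2.0, -0.2)        # spread of per-component rarity
COMM_POSTURE_SUBSAMPLE_FRAC = 0.3
COMM_NODE_SUBSAMPLE_FRAC = 0.8


def ks_distance(a, b) -> float:
    """Kolmogorov-Smirnov distance between two empirical distributions."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    vals = np.union1d(a, b)
    fa = np.searchsorted(np.sort(a), vals, side="right") / len(a)
    fb = np.searchsorted(np.sort(b), vals, side="right") / len(b)
    return float(np.abs(fa - fb).max())


def _social_cfg(seed: int, multiplier: float = 1.0,
                n_periods: int = CALIB_N_PERIODS) -> SocialSimConfig:
    return SocialSimConfig(
        n_harems=1, harem_size_range=(CALIB_HAREM_SIZE, CALIB_HAREM_SIZE),
        n_periods=n_periods, presence_prob=CALIB_PRESENCE_PROB,
        alone_prob=CALIB_ALONE_PROB,
        planted_dyads_per_harem=(1 if multiplier > 1 else 0),
        preference_multiplier=multiplier, seed=seed,
    )


# ---------------------------------------------------------------------------
# preferred-associate test
# ---------------------------------------------------------------------------


def preferred_associate_rejection_rate(n_reps: int, seed: int,
                                       multiplier: float = 1.0,
                                       n_periods: int = CALIB_N_PERIODS,
                                       n_perm: int = INNER_N_PERM,
                                       alpha: float = 0.05) -> float:
    """Fraction of synthetic harems flagged (p < alpha) by the
    preferred-associate test.  ``multiplier=1`` is the null generator
    (expected rate ~ alpha); ``multiplier >= 3`` measures planted-dyad
    recovery power."""
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_reps) % (2**31)
    hits = 0
    for r in range(n_reps):
        sim = simulate_scans(_social_cfg(int(seeds[r]), multiplier, n_periods))
        net = next(iter(build_harem_networks(sim.scans, sim.roster, "x").values()))
        res = preferred_associate_test(net, scans=sim.scans, n_perm=n_perm,
                                       seed=int(seeds[n_reps + r]))
        hits += res.p_value < alpha
    return hits / n_reps


def edge_shuffle_toy_network() -> HaremNetwork:
    """5 nodes, 4 edges, weights {0.9, 0.1, 0.1, 0.1}: small enough to
    enumerate every labeled graph x weight assignment."""
    g = nx.Graph()
    g.add_nodes_from("abcde")
    for (u, v), w in zip([("a", "b"), ("a", "c"), ("b", "c"), ("d", "e")],
                         [0.9, 0.1, 0.1, 0.1]):
        g.add_edge(u, v, weight=w)
    return HaremNetwork("H", "x", g, {})


def edge_shuffle_enumeration() -> np.ndarray:
    """Exhaustive null for the toy network: all C(10,4)=210 labeled 5-node
    4-edge graphs x 4 placements of the large weight, scored by the CV of
    per-node mean SRIs (computed independently of the test code)."""
    pairs = list(itertools.combinations(range(5), 2))
    out = []
    for combo in itertools.combinations(range(len(pairs)), 4):
        for big in range(4):
            sri = np.zeros((5, 5))
            for ei, k in enumerate(combo):
                i, j = pairs[k]
                w = 0.9 if ei == big else 0.1
                sri[i, j] = sri[j, i] = w
            means = sri.sum(axis=1) / 4
            out.append(means.std(ddof=1) / means.mean())
    return np.array(out)


def edge_shuffle_ks(n_perm: int = 10_000, seed: int = 0) -> float:
    net = edge_shuffle_toy_network()
    res = preferred_associate_test(net, n_perm=n_perm, seed=seed,
                                   method="edge_shuffle")
    return ks_distance(res.null_values, edge_shuffle_enumeration())


# ---------------------------------------------------------------------------
# communication-network resampling tests
# ---------------------------------------------------------------------------


def _comm_codes() -> list[str]:
    return (
        [f"g{gi}s{si}" for gi, gs in enumerate(COMM_GROUP_SIZES) for si in range(gs)]
        + [f"c{k:02d}" for k in range(COMM_N_SINGLETONS)]
    )


def _comm_dataset(seed: int):
    """One cleaned synthetic posture stream under the frozen repertoire
    conditions; per-component rarity drawn log-uniformly so repertoire
    membership is stochastic."""
    ss = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    rng = np.random.default_rng(int(ss[0]))
    codes = _comm_codes()
    lo, hi = COMM_RATE_LOG10_RANGE
    rates = dict(zip(codes, 10 ** rng.uniform(lo, hi, size=len(codes))))
    cfg = CommSimConfig(
        group_sizes=COMM_GROUP_SIZES, n_singleton_components=COMM_N_SINGLETONS,
        n_modules=3, n_interactions=COMM_N_INTERACTIONS, base_rates=rates,
        seed=int(ss[1]),
    )
    sim = simulate_interactions(cfg, "ref")
    kept, _ = clean_postures(sim.interactions)
    return kept, sim.ethogram


def diversity_rejection_rate(n_reps: int, seed: int,
                             n_perm: int = INNER_N_PERM,
                             alpha: float = 0.05) -> float:
    """Rejection rate of the diversity jackknife under its null: the
    observed period is a uniform random posture subsample of the reference
    (identical repertoire and combinatorics), so the observed diversity is
    exchangeable with the null replicates and the rate should sit at
    ~alpha."""
    seeds = np.random.SeedSequence(seed).generate_state(3 * n_reps) % (2**31)
    hits = 0
    for r in range(n_reps):
        kept, _ = _comm_dataset(int(seeds[r]))
        postures = postures_of(kept)
        rng = np.random.default_rng(int(seeds[n_reps + r]))
        n_sub = max(10, int(COMM_POSTURE_SUBSAMPLE_FRAC * len(postures)))
        take = rng.choice(len(postures), size=n_sub, replace=False)
        obs = len({c for i in take for c in postures[i].components
                   if len(postures[i].components) >= 2})
        res = diversity_jackknife(postures, obs, n_sub, n_perm=n_perm,
                                  seed=int(seeds[2 * n_reps + r]), alpha=alpha)
        hits += res.significant is not None
    return hits / n_reps


def density_rejection_rate(n_reps: int, seed: int,
                           n_perm: int = INNER_N_PERM,
                           alpha: float = 0.05) -> float:
    """Rejection rate of the adjusted-density node-subsampling test under
    its null: the observed period is the induced subgraph on a uniform
    random node subset of the reference network (repertoire reduction with
    preserved connectivity)."""
    seeds = np.random.SeedSequence(seed).generate_state(3 * n_reps) % (2**31)
    hits = 0
    for r in range(n_reps):
        kept, eth = _comm_dataset(int(seeds[r]))
        net = build_comm_network(kept, eth)
        nodes = np.array(net.nodes, dtype=object)
        rng = np.random.default_rng(int(seeds[n_reps + r]))
        n_sub = max(2, int(COMM_NODE_SUBSAMPLE_FRAC * len(nodes)))
        subset = list(nodes[rng.choice(len(nodes), size=n_sub, replace=False)])
        obs = adjusted_density(net, subset)
        res = density_node_subsample_null(net, obs, n_sub, n_perm=n_perm,
                                          seed=int(seeds[2 * n_reps + r]),
                                          alpha=alpha)
        hits += res.significant is not None
    return hits / n_reps


def tiny_jackknife_fixture():
    """Six postures over six components; every C(6,3) subsample enumerable."""
    raw = [{"A", "B"}, {"B", "C"}, {"C", "D"}, {"D"}, {"A", "E"}, {"E", "F"}]
    return [Posture(frozenset(p)) for p in raw]


def tiny_jackknife_enumeration() -> np.ndarray:
    raw = [p.components for p in tiny_jackknife_fixture()]
    return np.array([
        len({c for i in combo for c in raw[i] if len(raw[i]) >= 2})
        for combo in itertools.combinations(range(6), 3)
    ])


def diversity_jackknife_ks(n_perm: int = 10_000, seed: int = 0) -> float:
    postures = tiny_jackknife_fixture()
    res = diversity_jackknife(postures, observed_diversity=4, n_sub=3,
                              n_perm=n_perm, seed=seed)
    return ks_distance(res.null_values, tiny_jackknife_enumeration())


def tiny_density_network() -> CommNetwork:
    """Six components, one two-state morphological group; every C(6,4)
    induced subgraph enumerable."""
    eth = Ethogram([
        Component("p", "G1"), Component("q", "G1"), Component("r", "R"),
        Component("t", "T"), Component("u", "U"), Component("v", "V"),
    ])
    postures = [{"p", "r"}, {"q", "t"}, {"r", "u"}, {"t", "v"},
                {"p", "v"}, {"u", "v"}, {"q", "r"}]
    inter = [
        InteractionRecord(f"I{i}", "x", "F", [Posture(frozenset(p))])
        for i, p in enumerate(postures)
    ]
    return build_comm_network(inter, eth)


def tiny_density_enumeration() -> np.ndarray:
    net = tiny_density_network()
    return np.array([
        adjusted_density(net, list(c))
        for c in itertools.combinations(net.nodes, 4)
    ], dtype=float)


def density_subsample_ks(n_perm: int = 10_000, seed: int = 0) -> float:
    net = tiny_density_network()
    res = density_node_subsample_null(net, adjusted_density(net), 4,
                                      n_perm=n_perm, seed=seed)
    return ks_distance(res.null_values, tiny_density_enumeration())


# ---------------------------------------------------------------------------
# module recovery
# ---------------------------------------------------------------------------


def module_recovery_ari(n_reps: int = 5, seed: int = 0,
                        p_within: float = 0.4, p_between: float = 0.02) -> float:
    """Mean adjusted Rand index between planted 2-module labels and the
    greedy-modularity partition."""
    from sklearn.metrics import adjusted_rand_score

    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    aris = []
    for r in range(n_reps):
        sim = simulate_interactions(
            CommSimConfig(n_modules=2, n_interactions=80,
                          p_within=p_within, p_between=p_between,
                          seed=int(seeds[r]))
        )
        kept, _ = clean_postures(sim.interactions)
        net = build_comm_network(kept, sim.ethogram)
        mods, _ = detect_modules(net)
        truth = [sim.modules[c] for c in net.nodes]
        pred = [mods[c] for c in net.nodes]
        aris.append(adjusted_rand_score(truth, pred))
    return float(np.mean(aris))


def two_clique_modularity() -> tuple[int, float]:
    """Two disconnected 4-cliques: the closed-form optimum is 2 modules at
    Q = 2 (1/2 - 1/4) = 0.5."""
    g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
    g = nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes})
    nx.set_edge_attributes(g, 1.0, "weight")
    net = CommNetwork("x", g, {v: v for v in g.nodes})
    mods, q = detect_modules(net)
    return len(set(mods.values())), q


# ---------------------------------------------------------------------------
# cleaning fixture
# ---------------------------------------------------------------------------


def cleaning_fixture():
    """Ten postures in three interactions; component "zz" occurs in three
    postures of a single interaction, so cleaning must drop exactly those
    three."""
    eth = Ethogram([
        Component("A", "GA"), Component("B", "GB"),
        Component("C", "GC"), Component("zz", "GZ"),
    ])
    spec = [
        ("I1", [{"A", "zz"}, {"B", "zz"}, {"A", "B", "zz"}, {"A", "B"}]),
        ("I2", [{"A", "B"}, {"A", "C"}, {"B", "C"}]),
        ("I3", [{"A", "C"}, {"B", "C"}, {"C"}]),
    ]
    inter = [
        InteractionRecord(iid, "x", "F", [Posture(frozenset(p)) for p in ps])
        for iid, ps in spec
    ]
    return inter, eth
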