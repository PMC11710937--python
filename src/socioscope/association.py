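"""Nearest-neighbor association networks.

Association is scored per sampling period from scan samples: two individuals
are "in association" in a period if either named the other as nearest
neighbor (the recorded relation is asymmetric, the index is dyadic, so the
relation is symmetrized).  Dyadic association strength is the simple ratio
index

    SRI = x / (y_a + y_b + y_ab + x)

where, over sampling periods, x counts periods with the pair in association,
y_a periods with only a observed, y_b periods with only b observed, and
y_ab periods with both observed but not in association.  The four counts
partition the periods in which at least one member was observed, so the SRI
is the fraction of a dyad's joint observation history spent in association.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps

from .ingest import NONE_NEIGHBOR, Individual, ScanRecord
from .stats import PermutationResult, coefficient_of_variation, upper_tail_p

ADULT_AGE_MONTHS = 12.0  # nodes younger than one year are excluded from networks


def compute_sri(x: float, y_a: float, y_b: float, y_ab: float) -> float:
    """Simple ratio index x/(y_a+y_b+y_ab+x); 0 (with a warning) if all counts are 0."""
    if min(x, y_a, y_b, y_ab) < 0:
        raise ValueError("SRI counts must be non-negative")
    denom = x + y_a + y_b + y_ab
    if denom == 0:
        warnings.warn("SRI undefined for all-zero counts; returning 0.0", stacklevel=2)
        return 0.0
    return x / denom


@dataclass(frozen=True)
class DyadTally:
    """The four SRI counts and the resulting index for one unordered pair."""

    a_id: str
    b_id: str
    x: int
    y_a: int
    y_b: int
    y_ab: int

    @property
    def sri(self) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return compute_sri(self.x, self.y_a, self.y_b, self.y_ab)

    @property
    def pair(self) -> frozenset:
        return frozenset((self.a_id, self.b_id))


def _periods(scans: Iterable[ScanRecord]):
    """Per sampling period: (present individual ids, symmetrized associated pairs)."""
    by_period: dict[str, list[ScanRecord]] = {}
    for r in scans:
        by_period.setdefault(r.period_id, []).append(r)
    out = {}
    for pid, recs in by_period.items():
        present = {r.individual_id for r in recs}
        present |= {r.neighbor_id for r in recs if r.neighbor_id != NONE_NEIGHBOR}
        pairs = {
            frozenset((r.individual_id, r.neighbor_id))
            for r in recs
            if r.neighbor_id != NONE_NEIGHBOR
        }
        out[pid] = (present, pairs)
    return out


def tally_dyads(scans: Sequence[ScanRecord],
                roster: Sequence[Individual] | None = None) -> list[DyadTally]:
    """Tally SRI counts for every unordered pair whose members were each
    observed in at least one sampling period.

    ``scans`` should cover a single harem and time period of interest; if a
    roster is given the candidate individuals are its members (so co-resident
    pairs never seen in association still receive a zero-SRI tally), otherwise
    the individuals observed in the scans.
    """
    if not scans:
        return []
    harems = {r.harem_id for r in scans}
    if len(harems) > 1:
        raise ValueError(f"tally_dyads expects scans from one harem, got {sorted(harems)}")
    periods = _periods(scans)
    observed: set[str] = set()
    for present, _ in periods.values():
        observed |= present
    if roster is not None:
        ids = sorted(i.id for i in roster if i.id in observed)
    else:
        ids = sorted(observed)

    tallies = []
    for a, b in itertools.combinations(ids, 2):
        x = y_a = y_b = y_ab = 0
        pair = frozenset((a, b))
        for present, pairs in periods.values():
            a_in, b_in = a in present, b in present
            if a_in and b_in:
                if pair in pairs:
                    x += 1
                else:
                    y_ab += 1
            elif a_in:
                y_a += 1
            elif b_in:
                y_b += 1
        tallies.append(DyadTally(a, b, x, y_a, y_b, y_ab))
    return tallies


@dataclass
class HaremNetwork:
    """Weighted undirected graph of one harem's adults with SRI edge weights.

    Node metrics (degree over positive-SRI edges, mean and CV of the node's
    dyadic SRIs) and harem-level metrics (density over possible pairs, CV of
    the dyadic SRIs) are populated at construction.  By default the dyadic
    SRI set used for means and CVs includes zeros for co-resident dyads never
    seen in association; excluding them would conflate density with
    heterogeneity (``include_zero_dyads=False`` toggles this).
    """

    harem_id: str
    period_label: str
    graph: nx.Graph
    tallies: dict[frozenset, DyadTally]
    node_metrics: dict[str, dict] = field(default_factory=dict)
    density: float | None = None
    cv_harem: float | None = None
    include_zero_dyads: bool = True

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def dyadic_sris(self, nodes: Sequence[str] | None = None) -> dict[frozenset, float]:
        nodes = sorted(nodes) if nodes is not None else self.nodes
        out = {}
        for a, b in itertools.combinations(nodes, 2):
            pair = frozenset((a, b))
            t = self.tallies.get(pair)
            sri = t.sri if t is not None else 0.0
            if sri > 0 or self.include_zero_dyads:
                out[pair] = sri
        return out


def build_harem_network(tallies: Sequence[DyadTally],
                        roster: Sequence[Individual],
                        period_label: str = "",
                        min_age_months: float = ADULT_AGE_MONTHS,
                        include_zero_dyads: bool = True) -> HaremNetwork:
    """Build one harem's association network for one time period.

    Only individuals at least ``min_age_months`` old become nodes (infant
    mortality makes younger animals unreliable network members); individuals
    with unknown age are retained.  Edges carry sri > 0 weights.
    """
    harem_ids = {i.harem_id for i in roster}
    if len(harem_ids) != 1:
        raise ValueError(f"roster must cover exactly one harem, got {sorted(harem_ids)}")
    nodes = sorted(
        i.id for i in roster
        if i.age_months is None or i.age_months >= min_age_months
    )
    node_set = set(nodes)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    tally_map = {t.pair: t for t in tallies
                 if t.a_id in node_set and t.b_id in node_set}
    for t in tally_map.values():
        if t.sri > 0:
            g.add_edge(t.a_id, t.b_id, weight=t.sri)

    net = HaremNetwork(
        harem_id=next(iter(harem_ids)),
        period_label=period_label,
        graph=g,
        tallies=tally_map,
        include_zero_dyads=include_zero_dyads,
    )
    n = len(nodes)
    if n >= 2:
        net.density = g.number_of_edges() / (n * (n - 1) / 2)
        dyads = net.dyadic_sris()
        if len(dyads) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cv = coefficient_of_variation(dyads.values())
            net.cv_harem = None if np.isnan(cv) else cv
    for node in nodes:
        own = [
            sri for pair, sri in net.dyadic_sris().items() if node in pair
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = coefficient_of_variation(own) if len(own) >= 2 else float("nan")
        net.node_metrics[node] = {
            "degree": g.degree(node),
            "mean_sri": float(np.mean(own)) if own else float("nan"),
            "cv_sri": float(cv),
        }
    return net


def build_harem_networks(scans: Sequence[ScanRecord],
                         roster: Sequence[Individual],
                         period_label: str = "",
                         **kwargs) -> dict[str, HaremNetwork]:
    """Tally and build one network per harem present in the scans."""
    by_harem: dict[str, list[ScanRecord]] = {}
    for r in scans:
        by_harem.setdefault(r.harem_id, []).append(r)
    roster_by_harem: dict[str, list[Individual]] = {}
    for ind in roster:
        roster_by_harem.setdefault(ind.harem_id, []).append(ind)
    nets = {}
    for hid, hscans in sorted(by_harem.items()):
        members = roster_by_harem.get(hid, [])
        tallies = tally_dyads(hscans, members or None)
        if not members:
            members = [Individual(i, hid) for i in
                       sorted({t.a_id for t in tallies} | {t.b_id for t in tallies})]
        nets[hid] = build_harem_network(tallies, members, period_label, **kwargs)
    return nets


# ---------------------------------------------------------------------------
# preferred-associate permutation test
# ---------------------------------------------------------------------------

MIN_TEST_HAREM_SIZE = 5  # the CV test is uninformative in harems of <= 4


def _dyadic_cv(sri_values: np.ndarray) -> float:
    m = sri_values.mean()
    if sri_values.size < 2 or m <= 0:
        return float("nan")
    return float(sri_values.std(ddof=1) / m)


def preferred_associate_test(net: HaremNetwork,
                             scans: Sequence[ScanRecord] | None = None,
                             n_perm: int = 1000,
                             seed: int | None = None,
                             method: str = "node_label",
                             statistic: str | None = None,
                             convention: str = "count_over_n") -> PermutationResult:
    """Test whether a harem has preferred associates: is the observed CV of
    bond strengths higher than expected under a null of undifferentiated
    association?

    Two null models are available:

    * ``"node_label"`` (default; requires ``scans``): a data-stream
      permutation — within every sampling period the identities of the
      present individuals are shuffled, the SRIs retallied, and the CV of
      the dyadic SRIs recomputed.  Per-period group structure, presence and
      gregariousness are preserved; only the *identity* of who associates
      with whom is broken, which is exactly the preferred-associate signal.
    * ``"edge_shuffle"``: each replicate places the observed multiset of SRI
      weights onto a uniformly random simple graph with the same node and
      edge counts.  Any statistic of the weight multiset is invariant under
      this null, so here the CV is taken over per-node mean SRIs, which does
      respond to how weights are arranged on the graph.

    The p-value is the fraction of null CVs >= the observed CV (ties count
    toward the upper tail), per the count-over-n convention;
    ``convention="plus_one"`` gives (count+1)/(n+1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n_nodes = net.graph.number_of_nodes()
    if n_nodes < MIN_TEST_HAREM_SIZE:
        raise ValueError(
            f"harem {net.harem_id!r} has {n_nodes} network members; the "
            f"preferred-associate CV test is only meaningful for harems of "
            f"more than 4 individuals, in which strong bonds with every "
            f"member are not simultaneously attainable"
        )
    if net.graph.number_of_edges() < 1:
        raise ValueError("network has no edges; CV of bond strengths is undefined")
    rng = np.random.default_rng(seed)

    if method == "node_label":
        if scans is None:
            raise ValueError("method='node_label' requires the scan records")
        statistic = statistic or "dyadic_cv"
        return _node_label_test(net, scans, n_perm, seed, rng, statistic, convention)
    elif method == "edge_shuffle":
        statistic = statistic or "node_mean_cv"
        return _edge_shuffle_test(net, n_perm, seed, rng, statistic, convention)
    raise ValueError(f"unknown method {method!r}")


def _period_arrays(scans, nodes):
    """Precompute per-period presence masks and association pair indices
    restricted to the network's node set."""
    index = {v: i for i, v in enumerate(nodes)}
    out = []
    for present, pairs in _periods(scans).values():
        pres = np.array(sorted(index[v] for v in present if v in index), dtype=np.intp)
        if pres.size == 0:
            continue
        uv = [
            tuple(sorted(index[w] for w in pair))
            for pair in pairs
            if all(w in index for w in pair)
        ]
        u = np.array([p[0] for p in uv], dtype=np.intp)
        v = np.array([p[1] for p in uv], dtype=np.intp)
        out.append((pres, u, v))
    return out


def _sri_matrices(period_arrays, n):
    """Observed association-count matrix X and joint-observation denominator D."""
    x = np.zeros((n, n))
    denom = np.zeros((n, n))
    for pres, u, v in period_arrays:
        mask = np.zeros(n, dtype=bool)
        mask[pres] = True
        either = mask[:, None] | mask[None, :]
        denom += either
        x[u, v] += 1
        x[v, u] += 1
    return x, denom


def _node_label_test(net, scans, n_perm, seed, rng, statistic, convention):
    nodes = net.nodes
    n = len(nodes)
    harem_scans = [r for r in scans if r.harem_id == net.harem_id]
    periods = _period_arrays(harem_scans, nodes)
    x, denom = _sri_matrices(periods, n)
    iu = np.triu_indices(n, 1)
    valid = denom[iu] > 0
    if not net.include_zero_dyads:
        valid &= x[iu] > 0

    def stat_from_x(xm):
        with np.errstate(invalid="ignore", divide="ignore"):
            sri = np.where(denom > 0, xm / np.maximum(denom, 1), 0.0)
        vals = sri[iu][valid]
        if statistic == "node_mean_cv":
            means = sri.sum(axis=1) / max(n - 1, 1)
            return _dyadic_cv(means)
        return _dyadic_cv(vals)

    observed = stat_from_x(x)
    null = np.empty(n_perm)
    labels = np.arange(n)
    for r in range(n_perm):
        xp = np.zeros((n, n))
        for pres, u, v in periods:
            perm = labels.copy()
            perm[pres] = rng.permutation(pres)
            pu, pv = perm[u], perm[v]
            xp[pu, pv] += 1
            xp[pv, pu] += 1
        null[r] = stat_from_x(xp)
    null = np.nan_to_num(null, nan=0.0)
    obs = 0.0 if np.isnan(observed) else observed
    p = upper_tail_p(obs, null, convention)
    return PermutationResult(
        observed=obs, null_values=null, p_value=p, n_perm=n_perm, seed=seed,
        tail="upper", method="node_label", statistic=statistic,
    )


def _edge_shuffle_test(net, n_perm, seed, rng, statistic, convention):
    nodes = net.nodes
    n = len(nodes)
    pairs = list(itertools.combinations(range(n), 2))
    weights = np.array(
        [d["weight"] for _, _, d in net.graph.edges(data=True)], dtype=float
    )
    m = len(weights)

    def stat_from_placement(pair_idx, w):
        sri = np.zeros((n, n))
        for (i, j), wt in zip((pairs[k] for k in pair_idx), w):
            sri[i, j] = sri[j, i] = wt
        if statistic == "dyadic_cv":
            iu = np.triu_indices(n, 1)
            return _dyadic_cv(sri[iu])
        means = sri.sum(axis=1) / (n - 1)
        return _dyadic_cv(means)

    index = {v: i for i, v in enumerate(nodes)}
    obs_idx = [pairs.index(tuple(sorted((index[a], index[b]))))
               for a, b in net.graph.edges]
    observed = stat_from_placement(obs_idx, weights)
    null = np.empty(n_perm)
    for r in range(n_perm):
        idx = rng.choice(len(pairs), size=m, replace=False)
        null[r] = stat_from_placement(idx, rng.permutation(weights))
    null = np.nan_to_num(null, nan=0.0)
    obs = 0.0 if np.isnan(observed) else observed
    p = upper_tail_p(obs, null, convention)
    return PermutationResult(
        observed=obs, null_values=null, p_value=p, n_perm=n_perm, seed=seed,
        tail="upper", method="edge_shuffle", statistic=statistic,
    )


# ---------------------------------------------------------------------------
# cross-period comparisons
# ---------------------------------------------------------------------------


def cross_period_dyad_regression(tallies_pre: Sequence[DyadTally],
                                 tallies_late: Sequence[DyadTally]) -> dict | None:
    """OLS of late-period dyadic SRI on pre-period dyadic SRI over dyads
    present in both periods.  Returns None (with a warning) for < 3 shared
    dyads."""
    pre = {t.pair: t.sri for t in tallies_pre}
    late = {t.pair: t.sri for t in tallies_late}
    shared = sorted(pre.keys() & late.keys(), key=sorted)
    if len(shared) < 3:
        warnings.warn(f"only {len(shared)} shared dyads; regression not run", stacklevel=2)
        return None
    xv = np.array([pre[d] for d in shared])
    yv = np.array([late[d] for d in shared])
    res = sps.linregress(xv, yv)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p": float(res.pvalue),
        "n_dyads": len(shared),
    }


def compare_periods(nets_pre: Mapping[str, HaremNetwork],
                    nets_late: Mapping[str, HaremNetwork]):
    """Paired long-format table of network metrics restricted to harems,
    individuals and dyads present in both periods; ready for paired tests
    (the tests themselves are delegated to standard routines)."""
    import pandas as pd

    rows = []
    shared_harems = sorted(nets_pre.keys() & nets_late.keys())
    if not shared_harems:
        warnings.warn("no harems shared across periods", stacklevel=2)
    for hid in shared_harems:
        a, b = nets_pre[hid], nets_late[hid]
        for metric, pre_v, late_v in (
            ("density", a.density, b.density),
            ("cv_harem", a.cv_harem, b.cv_harem),
        ):
            if pre_v is not None and late_v is not None:
                rows.append(
                    {"harem_id": hid, "unit": hid, "level": "harem",
                     "metric": metric, "pre": pre_v, "late": late_v,
                     "delta": late_v - pre_v}
                )
        for node in sorted(set(a.nodes) & set(b.nodes)):
            for metric in ("degree", "mean_sri", "cv_sri"):
                pre_v = a.node_metrics[node][metric]
                late_v = b.node_metrics[node][metric]
                rows.append(
                    {"harem_id": hid, "unit": node, "level": "individual",
                     "metric": metric, "pre": pre_v, "late": late_v,
                     "delta": late_v - pre_v}
                )
        pre_d, late_d = a.dyadic_sris(), b.dyadic_sris()
        for pair in sorted(pre_d.keys() & late_d.keys(), key=sorted):
            rows.append(
                {"harem_id": hid, "unit": "--".join(sorted(pair)), "level": "dyad",
                 "metric": "sri", "pre": pre_d[pair], "late": late_d[pair],
                 "delta": late_d[pair] - pre_d[pair]}
            )
    return pd.DataFrame(rows, columns=["harem_id", "unit", "level", "metric",
                                       "pre", "late", "delta"])
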