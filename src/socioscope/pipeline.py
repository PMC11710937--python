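"""End-to-end orchestration: ingest -> association networks + permutation
tests -> communication networks + resampling tests -> budgets -> results
bundle.

A run is deterministic given (inputs, seed, flags).  The bundle is a plain
dict mirrored to disk as CSV/GraphML/JSON artifacts plus a manifest of
versions, seeds and flags.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .association import (
    build_harem_networks,
    compare_periods,
    cross_period_dyad_regression,
    preferred_associate_test,
    MIN_TEST_HAREM_SIZE,
)
from .budgets import aggregate_budget, compute_budget
from .comm import (
    adjusted_density,
    build_comm_network,
    clean_postures,
    compare_modules,
    component_diversity,
    density_node_subsample_null,
    detect_modules,
    diversity_jackknife,
    modality_loss_summary,
    postures_of,
)
from .ingest import (
    read_activity_table,
    read_ethogram,
    read_interaction_table,
    read_roster,
    read_scan_table,
)
from .synthetic import (
    BudgetSimConfig,
    CommSimConfig,
    SocialSimConfig,
    simulate_budgets,
    simulate_interactions,
    simulate_scans,
)


@dataclass
class RunConfig:
    """One pipeline run.

    Either ``simulate=True`` (no external files; synthetic data for two
    periods) or paths for whichever stages should run: ``scan_paths`` maps
    period label -> scan CSV, plus roster/interactions/ethogram/activity
    paths.  Flags mirror the analysis toggles documented on the individual
    functions.
    """

    out_dir: str = "socioscope_out"
    simulate: bool = False
    seed: int = 0
    n_perm: int = 1000
    period_labels: tuple[str, str] = ("pre", "late")
    scan_paths: Mapping[str, str] = field(default_factory=dict)
    roster_path: str | None = None
    interactions_path: str | None = None
    ethogram_path: str | None = None
    activity_path: str | None = None
    # analysis flags
    include_zero_dyads: bool = True
    assoc_null_method: str = "node_label"
    cooccurrence_unit: str = "posture"
    cleaning_to_fixpoint: bool = True
    exclude_neutral: bool = False

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def run_pipeline(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seeds = np.random.SeedSequence(cfg.seed).generate_state(8) % (2**31)
    bundle: dict = {"manifest": {
        "socioscope_version": __version__,
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "flags": {
            "include_zero_dyads": cfg.include_zero_dyads,
            "assoc_null_method": cfg.assoc_null_method,
            "cooccurrence_unit": cfg.cooccurrence_unit,
            "cleaning_to_fixpoint": cfg.cleaning_to_fixpoint,
            "exclude_neutral": cfg.exclude_neutral,
        },
    }}

    data = _load_or_simulate(cfg, rng_seeds)
    if data.get("scans"):
        bundle["association"] = _association_stage(cfg, data, out, int(rng_seeds[4]))
    if data.get("interactions"):
        bundle["communication"] = _comm_stage(cfg, data, out, int(rng_seeds[5]))
    if data.get("intervals"):
        bundle["budgets"] = _budget_stage(cfg, data, out)

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(bundle["manifest"], fh, indent=2)
    with open(out / "results.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(bundle), fh, indent=2)
    return bundle


def _load_or_simulate(cfg: RunConfig, rng_seeds) -> dict:
    pre, late = cfg.period_labels
    data: dict = {}
    if cfg.simulate:
        # one 80-period campaign split in half: both periods share rosters and
        # planted structure but have independent scan draws
        sim = simulate_scans(SocialSimConfig(
            n_harems=6, n_periods=80, planted_dyads_per_harem=1,
            preference_multiplier=3.0, seed=int(rng_seeds[0])))
        cut = "P040"
        data["scans"] = {
            pre: [r for r in sim.scans if r.period_id < cut],
            late: [r for r in sim.scans if r.period_id >= cut],
        }
        data["roster"] = sim.roster
        # repertoire-scale inventory with spread component rarity; the late
        # period loses a random sixth of the repertoire and is observed for
        # a third of the effort
        group_sizes, n_single = (6, 4, 4, 3, 3, 2, 2), 57
        codes = [f"g{gi}s{si}" for gi, gs in enumerate(group_sizes)
                 for si in range(gs)] + [f"c{k:02d}" for k in range(n_single)]
        rng = np.random.default_rng(int(rng_seeds[1]))
        rates = dict(zip(codes, 10 ** rng.uniform(-2.0, -0.2, size=len(codes))))
        lost = frozenset(rng.choice(codes, size=len(codes) // 6, replace=False))
        sim_i_pre = simulate_interactions(
            CommSimConfig(group_sizes=group_sizes, n_singleton_components=n_single,
                          n_interactions=120, base_rates=rates,
                          seed=int(rng_seeds[2])),
            period_label=pre,
        )
        sim_i_late = simulate_interactions(
            CommSimConfig(group_sizes=group_sizes, n_singleton_components=n_single,
                          n_interactions=40, base_rates=rates,
                          lost_components=lost, seed=int(rng_seeds[2]) + 1),
            period_label=late,
        )
        data["interactions"] = {pre: sim_i_pre.interactions,
                                late: sim_i_late.interactions}
        data["ethogram"] = sim_i_pre.ethogram
        iv_pre, steps_pre, _ = simulate_budgets(
            BudgetSimConfig(period_label=pre, seed=int(rng_seeds[3])))
        iv_late, steps_late, _ = simulate_budgets(
            BudgetSimConfig(period_label=late, seed=int(rng_seeds[3]) + 1))
        data["intervals"] = iv_pre + iv_late
        data["steps"] = pd.concat([steps_pre, steps_late], ignore_index=True)
        return data

    if cfg.scan_paths:
        roster = read_roster(cfg.roster_path) if cfg.roster_path else None
        data["roster"] = roster
        data["scans"] = {
            label: read_scan_table(path, roster=roster)
            for label, path in cfg.scan_paths.items()
        }
    if cfg.interactions_path and cfg.ethogram_path:
        ethogram = read_ethogram(cfg.ethogram_path)
        records = read_interaction_table(cfg.interactions_path, ethogram)
        by_label: dict[str, list] = {}
        for r in records:
            by_label.setdefault(r.period_label, []).append(r)
        data["ethogram"] = ethogram
        data["interactions"] = by_label
    if cfg.activity_path:
        data["intervals"] = read_activity_table(cfg.activity_path)
        data["steps"] = None
    return data


def _association_stage(cfg: RunConfig, data: dict, out: Path, seed: int) -> dict:
    nets_by_period = {}
    tallies_by_period: dict[str, list] = {}
    results: dict = {"harems": {}}
    for label, scans in data["scans"].items():
        nets = build_harem_networks(
            scans, data["roster"] or [], period_label=label,
            include_zero_dyads=cfg.include_zero_dyads,
        )
        nets_by_period[label] = nets
        tallies_by_period[label] = [t for n in nets.values() for t in n.tallies.values()]
        edge_rows, node_rows, perm_rows = [], [], []
        for hid, net in nets.items():
            for t in net.tallies.values():
                edge_rows.append(
                    {"harem_id": hid, "a": t.a_id, "b": t.b_id, "x": t.x,
                     "y_a": t.y_a, "y_b": t.y_b, "y_ab": t.y_ab, "sri": t.sri}
                )
            for node, m in net.node_metrics.items():
                node_rows.append({"harem_id": hid, "individual_id": node, **m})
            results["harems"].setdefault(hid, {})[label] = {
                "n_nodes": net.graph.number_of_nodes(),
                "n_edges": net.graph.number_of_edges(),
                "density": net.density,
                "cv_harem": net.cv_harem,
            }
            if (net.graph.number_of_nodes() >= MIN_TEST_HAREM_SIZE
                    and net.graph.number_of_edges() >= 1):
                res = preferred_associate_test(
                    net, scans=scans, n_perm=cfg.n_perm, seed=seed,
                    method=cfg.assoc_null_method,
                )
                results["harems"][hid][label]["preferred_associate_p"] = res.p_value
                perm_rows.append({"harem_id": hid, "period": label,
                                  "observed_cv": res.observed, "p": res.p_value,
                                  "n_perm": res.n_perm, "method": res.method})
            nx.write_graphml(net.graph, out / f"assoc_{hid}_{label}.graphml")
        pd.DataFrame(edge_rows).to_csv(out / f"assoc_edges_{label}.csv", index=False)
        pd.DataFrame(node_rows).to_csv(out / f"assoc_nodes_{label}.csv", index=False)
        if perm_rows:
            pd.DataFrame(perm_rows).to_csv(
                out / f"assoc_permutations_{label}.csv", index=False)

    labels = list(data["scans"])
    if len(labels) == 2:
        a, b = labels
        paired = compare_periods(nets_by_period[a], nets_by_period[b])
        paired.to_csv(out / "assoc_paired_deltas.csv", index=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reg = cross_period_dyad_regression(
                tallies_by_period[a], tallies_by_period[b])
        results["cross_period_regression"] = reg
        results["n_paired_rows"] = int(len(paired))
    return results


def _comm_stage(cfg: RunConfig, data: dict, out: Path, seed: int) -> dict:
    ethogram = data["ethogram"]
    results: dict = {"periods": {}}
    nets, cleaned = {}, {}
    for label, interactions in data["interactions"].items():
        kept, report = clean_postures(interactions,
                                      to_fixpoint=cfg.cleaning_to_fixpoint)
        cleaned[label] = kept
        net = build_comm_network(kept, ethogram, period_label=label,
                                 unit=cfg.cooccurrence_unit)
        if cfg.exclude_neutral:
            from .comm import neutral_subgraph
            net = neutral_subgraph(net, ethogram)
        modules, q = detect_modules(net)
        nets[label] = net
        results["periods"][label] = {
            "postures_in": report.postures_in,
            "postures_out": report.postures_out,
            "removed_components": sorted(report.removed_components),
            "diversity": component_diversity(net),
            "adjusted_density": adjusted_density(net),
            "n_modules": len(set(modules.values())),
            "modularity_q": q,
        }
        nx.write_graphml(net.graph, out / f"comm_{label}.graphml")
        pd.DataFrame(
            [{"component": c, "module": m} for c, m in sorted(modules.items())]
        ).to_csv(out / f"comm_modules_{label}.csv", index=False)
        with open(out / f"comm_cleaning_{label}.json", "w", encoding="utf-8") as fh:
            json.dump({"postures_in": report.postures_in,
                       "postures_removed": report.postures_removed,
                       "postures_out": report.postures_out,
                       "removed_components": report.removed_components,
                       "passes": report.passes}, fh, indent=2)

    labels = list(data["interactions"])
    if len(labels) == 2:
        ref_label, cmp_label = labels
        ref_postures = postures_of(cleaned[ref_label])
        n_sub = len(postures_of(cleaned[cmp_label]))
        if 0 < n_sub <= len(ref_postures):
            dres = diversity_jackknife(
                ref_postures,
                observed_diversity=results["periods"][cmp_label]["diversity"],
                n_sub=n_sub, n_perm=cfg.n_perm, seed=seed,
            )
            results["diversity_test"] = {
                "observed": dres.observed, "null_mean": float(dres.null_values.mean()),
                "null_sd": float(dres.null_values.std(ddof=1)),
                "significant": dres.significant,
                "lower_cut": dres.lower_cut, "upper_cut": dres.upper_cut,
            }
            pd.DataFrame({"null_diversity": dres.null_values}).to_csv(
                out / "comm_diversity_null.csv", index=False)
        n_nodes_sub = nets[cmp_label].graph.number_of_nodes()
        obs_density = results["periods"][cmp_label]["adjusted_density"]
        if (obs_density is not None and 2 <= n_nodes_sub
                <= nets[ref_label].graph.number_of_nodes()):
            nres = density_node_subsample_null(
                nets[ref_label], observed_density=obs_density,
                n_nodes_sub=n_nodes_sub, n_perm=cfg.n_perm, seed=seed + 1,
            )
            results["density_test"] = {
                "observed": nres.observed, "null_mean": float(nres.null_values.mean()),
                "significant": nres.significant,
                "lower_cut": nres.lower_cut, "upper_cut": nres.upper_cut,
            }
            pd.DataFrame({"null_adjusted_density": nres.null_values}).to_csv(
                out / "comm_density_null.csv", index=False)
        flow = compare_modules(nets[ref_label], nets[cmp_label])
        flow.to_csv(out / "comm_module_flow.csv", index=False)
        loss = modality_loss_summary(nets[ref_label], nets[cmp_label], ethogram)
        loss.to_csv(out / "comm_modality_loss.csv", index=False)
        results["modality_loss"] = loss.to_dict(orient="records")
    return results


def _budget_stage(cfg: RunConfig, data: dict, out: Path) -> dict:
    budget = compute_budget(data["intervals"], steps=data.get("steps"))
    budget.to_csv(out / "budgets.csv", index=False)
    agg = aggregate_budget(budget)
    agg.to_csv(out / "budgets_aggregate.csv", index=False)
    return {
        "n_focal_periods": int(budget.groupby(["focal_id", "period_label"]).ngroups),
        "per_period_means": {
            label: sub.set_index("behavior_category")["proportion"].to_dict()
            for label, sub in agg.groupby("period_label")
        },
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (pd.DataFrame, pd.Series)):
        return obj.to_dict()
    return obj
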