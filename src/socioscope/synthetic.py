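"""Synthetic field data with known ground truth.

Three generators emulate the structure of the field datasets — scan-sampled
nearest-neighbor records, coded multimodal interactions, and focal activity
intervals — with planted effects (preferred dyads, context modules, lost
signal components, target budget proportions) so every downstream stage can
be scored against a known truth without any field data.

Defaults follow the study system: harems of 2-13 members (mean ~5), two
focal-follow blocks per observation day with a scan between blocks, posture
streams of a few hundred interactions with 3-4 signal modalities and
mutually exclusive morphological groups.

All generators take a single master seed; per-harem / per-interaction
sub-streams are derived deterministically via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield
from typing import Mapping, Sequence

import numpy as np

from .ingest import (
    ActivityInterval,
    Component,
    Ethogram,
    Individual,
    InteractionRecord,
    NONE_NEIGHBOR,
    Posture,
    ScanRecord,
)

_BEHAVIORS = ("grazing", "resting", "standing", "vigilant", "traveling")


# ---------------------------------------------------------------------------
# scan samples
# ---------------------------------------------------------------------------


@dataclass
class SocialSimConfig:
    """Generator settings for nearest-neighbor scan samples.

    ``planted_dyads_per_harem`` disjoint pairs in each harem are preferred
    associates: their per-period (symmetrized) association probability is
    ``preference_multiplier`` times the baseline association probability of
    an unpreferred dyad, capped at 0.95 (1.0 = no preference, the null
    generator).  The multiplier is realized through each member's
    nearest-neighbor choice weights, so draws remain independent per
    individual and are symmetrized downstream.
    """

    n_harems: int = 5
    harem_size_range: tuple[int, int] = (2, 13)
    n_periods: int = 40
    presence_prob: float = 0.95
    alone_prob: float = 0.2
    planted_dyads_per_harem: int = 0
    preference_multiplier: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        for p in (self.presence_prob, self.alone_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.preference_multiplier < 1:
            raise ValueError("preference multiplier must be >= 1")
        lo, hi = self.harem_size_range
        if lo < 2 or hi < lo:
            raise ValueError("harem size range must satisfy 2 <= lo <= hi")


@dataclass
class SimulatedScans:
    scans: list[ScanRecord]
    roster: list[Individual]
    planted_dyads: dict[str, list[tuple[str, str]]]  # harem -> planted pairs
    config: SocialSimConfig


def _choice_weight(cfg: SocialSimConfig, k_others: int) -> float:
    """Neighbor-choice weight for a planted partner among ``k_others``
    present harem-mates, such that the symmetrized association probability
    of the planted dyad is ``preference_multiplier`` x the baseline dyad's
    (capped at 0.95)."""
    a, mult = cfg.alone_prob, cfg.preference_multiplier
    if mult == 1.0 or k_others < 2:
        return 1.0  # a single candidate is chosen regardless of weight
    q0 = (1 - a) / k_others                      # per-side baseline pick prob
    p0 = 1 - (1 - q0) ** 2                       # symmetrized baseline
    p1 = min(mult * p0, 0.95)
    q1 = 1 - math.sqrt(1 - p1)                   # per-side target pick prob
    cond = q1 / (1 - a) if a < 1 else 1.0        # conditional on not alone
    if cond >= 1:
        return 1e9
    return cond * (k_others - 1) / (1 - cond)


def simulate_scans(cfg: SocialSimConfig) -> SimulatedScans:
    """Draw scan samples: per period each present individual is alone with
    ``alone_prob``, otherwise names a nearest neighbor among present
    harem-mates, planted partners upweighted by the preference multiplier."""
    ss = np.random.SeedSequence(cfg.seed)
    harem_streams = ss.spawn(cfg.n_harems)
    lo, hi = cfg.harem_size_range
    scans: list[ScanRecord] = []
    roster: list[Individual] = []
    planted: dict[str, list[tuple[str, str]]] = {}

    for h in range(cfg.n_harems):
        rng = np.random.default_rng(harem_streams[h])
        hid = f"H{h:02d}"
        size = int(rng.integers(lo, hi + 1))
        members = [f"{hid}i{k:02d}" for k in range(size)]
        classes = ["stallion"] + [
            ("lactating_female" if k % 2 else "nonlactating_female")
            for k in range(size - 1)
        ]
        for m, c in zip(members, classes):
            roster.append(Individual(id=m, harem_id=hid, age_sex_class=c,
                                     age_months=float(rng.integers(24, 180))))
        pairs: list[tuple[str, str]] = []
        if cfg.planted_dyads_per_harem and size >= 2:
            perm = list(rng.permutation(members))
            for k in range(min(cfg.planted_dyads_per_harem, size // 2)):
                pairs.append((perm[2 * k], perm[2 * k + 1]))
        planted[hid] = pairs
        partner_of = {}
        for a, b in pairs:
            partner_of[a], partner_of[b] = b, a

        for t in range(cfg.n_periods):
            pid = f"P{t:03d}"
            present = [m for m in members if rng.random() < cfg.presence_prob]
            for m in present:
                alone = len(present) < 2 or rng.random() < cfg.alone_prob
                if alone:
                    neighbor = NONE_NEIGHBOR
                else:
                    others = [o for o in present if o != m]
                    partner = partner_of.get(m)
                    w = np.array([
                        _choice_weight(cfg, len(others)) if o == partner else 1.0
                        for o in others
                    ])
                    neighbor = others[rng.choice(len(others), p=w / w.sum())]
                scans.append(
                    ScanRecord(
                        harem_id=hid, period_id=pid, individual_id=m,
                        behavior_code=str(rng.choice(_BEHAVIORS)),
                        neighbor_id=neighbor,
                    )
                )
    return SimulatedScans(scans=scans, roster=roster, planted_dyads=planted, config=cfg)


# ---------------------------------------------------------------------------
# multimodal interactions
# ---------------------------------------------------------------------------


@dataclass
class CommSimConfig:
    """Generator settings for coded multimodal interactions.

    The component inventory comprises multi-state morphological groups
    (``group_sizes``, mutually exclusive within a posture) plus
    ``n_singleton_components`` free components.  Components are assigned to
    ``n_modules`` planted context modules; each interaction draws a latent
    context, and a component appears in a posture with probability
    sqrt(p_within) when its module is active and sqrt(p_between) otherwise,
    so that two active-module components co-occur with probability
    ~``p_within`` and two inactive ones with ~``p_between``.

    ``base_rates`` multiplies per-component inclusion probabilities (rarity
    control for the cleaning filter); ``lost_components`` are masked to zero
    (simulating signals lost in a period); ``force_rare`` maps a component
    code to an exact number of interactions in which it is injected.
    """

    group_sizes: tuple[int, ...] = (4, 3, 3, 2, 2)
    n_singleton_components: int = 10
    n_modules: int = 3
    p_within: float = 0.4
    p_between: float = 0.02
    n_interactions: int = 60
    postures_per_interaction: tuple[int, int] = (3, 6)
    base_rates: Mapping[str, float] = dfield(default_factory=dict)
    lost_components: frozenset[str] = frozenset()
    force_rare: Mapping[str, int] = dfield(default_factory=dict)
    n_neutral: int = 0
    seed: int | None = None

    def __post_init__(self):
        for p in (self.p_within, self.p_between):
            if not 0 <= p <= 1:
                raise ValueError("co-occurrence probabilities must be in [0, 1]")
        if not self.group_sizes and not self.n_singleton_components:
            raise ValueError("empty component inventory")


@dataclass
class SimulatedInteractions:
    interactions: list[InteractionRecord]
    ethogram: Ethogram
    modules: dict[str, int]  # planted module label per component
    config: CommSimConfig


def make_inventory(cfg: CommSimConfig, rng: np.random.Generator) -> tuple[Ethogram, dict[str, int]]:
    """Build the component inventory and planted module assignment."""
    modalities = ("visual", "acoustic", "tactile", "chemical")
    comps: list[Component] = []
    for gi, gsize in enumerate(cfg.group_sizes):
        for s in range(gsize):
            comps.append(
                Component(code=f"g{gi}s{s}", group_id=f"grp{gi}",
                          modality=modalities[gi % len(modalities)])
            )
    for k in range(cfg.n_singleton_components):
        comps.append(
            Component(code=f"c{k:02d}", group_id=f"solo{k}",
                      modality=modalities[k % len(modalities)])
        )
    for j in range(cfg.n_neutral):
        comps.append(
            Component(code=f"n{j}", group_id=f"neutral{j}", modality="visual",
                      neutral=True)
        )
    ethogram = Ethogram(comps)
    signal_codes = [c.code for c in comps if not c.neutral]
    order = rng.permutation(len(signal_codes))
    modules = {signal_codes[i]: int(i_rank % cfg.n_modules)
               for i_rank, i in enumerate(order)}
    return ethogram, modules


def simulate_interactions(cfg: CommSimConfig,
                          period_label: str = "pre") -> SimulatedInteractions:
    ss = np.random.SeedSequence(cfg.seed)
    rng_inv, rng_draw = (np.random.default_rng(s) for s in ss.spawn(2))
    ethogram, modules = make_inventory(cfg, rng_inv)
    p_in = math.sqrt(cfg.p_within)
    p_out = math.sqrt(cfg.p_between)
    signal = [c for c in ethogram.components if not c.neutral]
    neutral = [c for c in ethogram.components if c.neutral]
    lo, hi = cfg.postures_per_interaction

    interactions: list[InteractionRecord] = []
    for i in range(cfg.n_interactions):
        context = int(rng_draw.integers(cfg.n_modules))
        postures: list[Posture] = []
        n_post = int(rng_draw.integers(lo, hi + 1))
        for _ in range(n_post):
            chosen: dict[str, str] = {}  # group -> code
            for c in signal:
                if c.code in cfg.lost_components:
                    continue
                p = (p_in if modules[c.code] == context else p_out)
                p *= cfg.base_rates.get(c.code, 1.0)
                if rng_draw.random() < p:
                    g = c.group_id
                    if g in chosen and rng_draw.random() < 0.5:
                        continue  # keep the earlier pick for this exclusive group
                    chosen[g] = c.code
            for c in neutral:
                if c.code not in cfg.lost_components and rng_draw.random() < 0.9:
                    chosen[c.group_id] = c.code
            if not chosen:
                pool = [c for c in signal
                        if modules[c.code] == context
                        and c.code not in cfg.lost_components]
                if not pool:
                    pool = [c for c in signal if c.code not in cfg.lost_components]
                pick = pool[rng_draw.integers(len(pool))]
                chosen[pick.group_id] = pick.code
            postures.append(Posture(frozenset(chosen.values())))
        interactions.append(
            InteractionRecord(
                interaction_id=f"{period_label}-I{i:04d}",
                period_label=period_label,
                focal_id=f"F{int(rng_draw.integers(20)):02d}",
                postures=postures,
                context_tag=f"ctx{context}",
            )
        )

    for code, k in cfg.force_rare.items():
        _inject_exact(interactions, ethogram, code, k, rng_draw)
        interactions = [r for r in interactions if r.postures]
    return SimulatedInteractions(interactions=interactions, ethogram=ethogram,
                                 modules=modules, config=cfg)


def _inject_exact(interactions, ethogram, code: str, k: int,
                  rng: np.random.Generator) -> None:
    """Force ``code`` to appear in exactly ``k`` distinct interactions by
    scrubbing it everywhere and re-adding it to one group-compatible posture
    in each of k interactions."""
    group = ethogram.group_of(code)
    for rec in interactions:
        rec.postures = [
            Posture(p.components - {code})
            for p in rec.postures
            if p.components != {code}
        ]
    order = rng.permutation(len(interactions))
    injected = 0
    for idx in order:
        if injected >= k:
            break
        rec = interactions[idx]
        for pi, p in enumerate(rec.postures):
            if all(ethogram.group_of(c) != group for c in p.components):
                rec.postures[pi] = Posture(p.components | {code})
                injected += 1
                break
    if injected < k:
        raise ValueError(f"could not inject {code!r} into {k} interactions")


# ---------------------------------------------------------------------------
# activity budgets
# ---------------------------------------------------------------------------


@dataclass
class BudgetSimConfig:
    """Target activity-budget proportions recovered up to rounding.

    Within each 5-min subsample window, window seconds are allocated to
    categories by largest-remainder apportionment of the target proportions,
    with optional per-focal Dirichlet jitter (``concentration``; None means
    exact targets)."""

    target_proportions: Mapping[str, float] = dfield(
        default_factory=lambda: {"grazing": 0.54, "resting": 0.2,
                                 "standing": 0.1, "vigilant": 0.06,
                                 "social_grazing": 0.06, "affiliation": 0.04}
    )
    n_focals: int = 12
    n_windows: int = 3
    window_s: float = 300.0
    concentration: float | None = None
    steps_per_min: float = 8.0
    period_label: str = "pre"
    seed: int | None = None

    def __post_init__(self):
        vals = list(self.target_proportions.values())
        if any(v < 0 for v in vals):
            raise ValueError("negative target proportion")
        if abs(sum(vals) - 1) > 1e-9:
            raise ValueError("target proportions must sum to 1")
        if self.window_s <= 0:
            raise ValueError("degenerate zero-duration window")


def _apportion(total: float, props: Sequence[float]) -> list[float]:
    """Largest-remainder apportionment of ``total`` seconds (integer-second
    resolution) across categories."""
    raw = [total * p for p in props]
    floors = [math.floor(r) for r in raw]
    rem = int(round(total)) - sum(floors)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - floors[i], reverse=True)
    for i in order[:rem]:
        floors[i] += 1
    return [float(f) for f in floors]


def simulate_budgets(cfg: BudgetSimConfig):
    """Generate activity intervals plus a steps table.

    Returns ``(intervals, steps_df, truth)`` where truth holds the per-focal
    realized proportions.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed)
    cats = sorted(cfg.target_proportions)
    windows = ["w5_10", "w15_20", "w25_30"][: cfg.n_windows]
    intervals: list[ActivityInterval] = []
    steps_rows = []
    truth: dict[str, dict[str, float]] = {}
    for f in range(cfg.n_focals):
        focal = f"F{f:02d}"
        if cfg.concentration is None:
            props = [cfg.target_proportions[c] for c in cats]
        else:
            alpha = np.array([cfg.target_proportions[c] for c in cats]) * cfg.concentration
            props = list(rng.dirichlet(np.maximum(alpha, 1e-6)))
        realized: dict[str, float] = {c: 0.0 for c in cats}
        for w in windows:
            durs = _apportion(cfg.window_s, props)
            t = 0.0
            order = rng.permutation(len(cats))
            for i in order:
                if durs[i] <= 0:
                    continue
                intervals.append(
                    ActivityInterval(
                        focal_id=focal, period_label=cfg.period_label,
                        behavior_category=cats[i], start_s=t, end_s=t + durs[i],
                        subsample_window=w,
                    )
                )
                realized[cats[i]] += durs[i]
                t += durs[i]
        total = sum(realized.values())
        truth[focal] = {c: realized[c] / total for c in cats}
        minutes = cfg.n_windows * cfg.window_s / 60.0
        steps_rows.append(
            {"focal_id": focal, "period_label": cfg.period_label,
             "steps": int(rng.poisson(cfg.steps_per_min * minutes)),
             "minutes": minutes}
        )
    return intervals, pd.DataFrame(steps_rows), truth
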