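"""Scan/focal activity budgets, step rates, and active-interaction rates.

Budgets are proportions of coded time per behavior category within the
5-minute subsample windows of each focal follow.  The taxonomy distinguishes
self-maintenance behaviors, passive social behaviors (proximity-based, done
concurrently with maintenance: social grazing, social rest) and active
social behaviors (dedicated interactions: affiliation, aggression, greeting,
harem maintenance, sex, play).  Interaction rates count *active* social
interactions per 30-minute observation block.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import pandas as pd

from .ingest import ActivityInterval, ValidationError

#: category -> broad class
DEFAULT_TAXONOMY: dict[str, str] = {
    "drinking": "self_maintenance",
    "grazing": "self_maintenance",
    "geophagy": "self_maintenance",
    "elimination": "self_maintenance",
    "olfactory_inspection": "self_maintenance",
    "traveling": "self_maintenance",
    "vigilant": "self_maintenance",
    "resting": "self_maintenance",
    "hygiene": "self_maintenance",
    "standing": "self_maintenance",
    "other": "self_maintenance",
    "social_grazing": "passive_social",
    "social_rest": "passive_social",
    "affiliation": "active_social",
    "aggression": "active_social",
    "greeting": "active_social",
    "harem_maintenance": "active_social",
    "sex": "active_social",
    "play": "active_social",
}

ACTIVE_SOCIAL = frozenset(c for c, k in DEFAULT_TAXONOMY.items() if k == "active_social")


def _check_overlaps(intervals: Sequence[ActivityInterval]) -> None:
    by_key: dict[tuple, list[ActivityInterval]] = {}
    for iv in intervals:
        by_key.setdefault((iv.focal_id, iv.period_label, iv.subsample_window), []).append(iv)
    for (focal, _, window), ivs in by_key.items():
        ivs = sorted(ivs, key=lambda i: (i.start_s, i.end_s))
        for a, b in zip(ivs, ivs[1:]):
            if b.start_s < a.end_s:
                raise ValidationError(
                    f"overlapping intervals for focal {focal!r} in window {window!r}: "
                    f"[{a.start_s}, {a.end_s}) and [{b.start_s}, {b.end_s})"
                )


def compute_budget(intervals: Sequence[ActivityInterval],
                   steps: pd.DataFrame | None = None,
                   taxonomy: Mapping[str, str] = DEFAULT_TAXONOMY) -> pd.DataFrame:
    """Per focal x period activity budget.

    Proportion of a category = its summed interval duration / total coded
    duration for that focal and period (uncoded time is excluded from the
    denominator).  ``steps``, if given, is a table with columns focal_id,
    period_label, steps, minutes, merged in as steps_per_min.

    Returns a long-format frame with one row per focal x period x category,
    plus the total coded seconds; proportions within a focal x period sum
    to 1.
    """
    unknown = sorted({iv.behavior_category for iv in intervals} - set(taxonomy))
    if unknown:
        raise ValidationError(f"behavior categories not in taxonomy: {unknown}")
    _check_overlaps(intervals)
    acc: dict[tuple, dict[str, float]] = {}
    for iv in intervals:
        key = (iv.focal_id, iv.period_label)
        acc.setdefault(key, {})
        acc[key][iv.behavior_category] = acc[key].get(iv.behavior_category, 0.0) + iv.duration_s
    rows = []
    for (focal, period), cats in sorted(acc.items()):
        total = sum(cats.values())
        for cat in sorted(taxonomy):
            dur = cats.get(cat, 0.0)
            rows.append(
                {"focal_id": focal, "period_label": period, "behavior_category": cat,
                 "behavior_class": taxonomy[cat], "duration_s": dur,
                 "proportion": dur / total if total > 0 else float("nan"),
                 "total_coded_s": total}
            )
    df = pd.DataFrame(rows)
    if steps is not None and len(df):
        sp = steps.copy()
        sp["steps_per_min"] = sp["steps"] / sp["minutes"]
        df = df.merge(sp[["focal_id", "period_label", "steps_per_min"]],
                      on=["focal_id", "period_label"], how="left")
    return df


def aggregate_budget(budget: pd.DataFrame,
                     roster: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean proportion per period x (age/sex class x) category, weighting
    each focal equally — reproducible as a weighted mean of the per-focal
    rows."""
    df = budget
    keys = ["period_label", "behavior_category"]
    if roster is not None:
        df = df.merge(roster[["id", "age_sex_class"]].rename(columns={"id": "focal_id"}),
                      on="focal_id", how="left")
        keys = ["period_label", "age_sex_class", "behavior_category"]
    return df.groupby(keys, as_index=False)["proportion"].mean()


def interaction_rate(interactions: pd.DataFrame,
                     blocks: pd.DataFrame) -> pd.DataFrame:
    """Active social interactions per 30-min observation block.

    ``interactions`` needs columns focal_id, period_label, active (bool);
    ``blocks`` needs focal_id, period_label, n_blocks.  Focals with zero
    blocks get a missing rate.
    """
    active = interactions[interactions["active"].astype(bool)]
    counts = active.groupby(["focal_id", "period_label"]).size().rename("n_active")
    out = blocks.merge(counts, on=["focal_id", "period_label"], how="left")
    out["n_active"] = out["n_active"].fillna(0).astype(int)
    out["interactions_per_30min"] = out.apply(
        lambda r: r["n_active"] / r["n_blocks"] if r["n_blocks"] > 0 else float("nan"),
        axis=1,
    )
    if (out["n_blocks"] <= 0).any():
        warnings.warn("focals with zero observation blocks have missing rates",
                      stacklevel=2)
    return out[["focal_id", "period_label", "n_active", "n_blocks",
                "interactions_per_30min"]]


def partner_shift_table(interactions: pd.DataFrame,
                        pedigree: Mapping[str, str]) -> pd.DataFrame:
    """2x2 contingency table of juvenile interaction partners: period x
    {mother, non-maternal}.

    ``interactions`` needs columns focal_id (a juvenile), period_label,
    partner_id; ``pedigree`` maps juvenile -> mother.  Interactions of
    juveniles with unknown mothers are excluded with a warning.  The
    chi-square test itself is left to standard routines.
    """
    known = interactions["focal_id"].map(lambda f: f in pedigree)
    if not known.all():
        excluded = sorted(interactions.loc[~known, "focal_id"].unique())
        warnings.warn(f"excluding juveniles with unknown mothers: {excluded}",
                      stacklevel=2)
    df = interactions[known].copy()
    df["partner_type"] = [
        "mother" if pedigree[f] == p else "non_maternal"
        for f, p in zip(df["focal_id"], df["partner_id"])
    ]
    table = (
        df.groupby(["period_label", "partner_type"]).size().unstack(fill_value=0)
    )
    for col in ("mother", "non_maternal"):
        if col not in table.columns:
            table[col] = 0
    table = table[["mother", "non_maternal"]]
    table["prop_non_maternal"] = table["non_maternal"] / (
        table["mother"] + table["non_maternal"]
    )
    return table.reset_index()
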