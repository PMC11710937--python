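"""Tabular ingest and the canonical in-memory data model.

Field datasets arrive as delimited tables whose column names vary between
projects, so every reader takes a small schema config (a dict, usually loaded
from YAML) mapping canonical field names to the columns actually present.
Validation is strict: rows violating an invariant are rejected with
row-numbered diagnostics rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

#: Token marking an individual scanned with no harem member within one body
#: length.  An explicit token (not an empty cell) so that "observed alone"
#: is distinguishable from a data-entry gap.
NONE_NEIGHBOR = "NONE"

AGE_SEX_CLASSES = ("stallion", "lactating_female", "nonlactating_female", "juvenile")
MODALITIES = ("visual", "acoustic", "tactile", "chemical")


class ValidationError(ValueError):
    """Raised when an input table violates a data-model invariant."""


@dataclass(frozen=True)
class Individual:
    id: str
    harem_id: str
    age_sex_class: str = "nonlactating_female"
    age_months: float | None = None

    def __post_init__(self):
        if self.age_sex_class not in AGE_SEX_CLASSES:
            raise ValidationError(
                f"unknown age/sex class {self.age_sex_class!r} for {self.id!r}; "
                f"expected one of {AGE_SEX_CLASSES}"
            )
        if self.age_months is not None and self.age_months < 0:
            raise ValidationError(f"negative age for {self.id!r}")


@dataclass(frozen=True)
class ScanRecord:
    """One individual's behavior and nearest neighbor at one sampling period."""

    harem_id: str
    period_id: str
    individual_id: str
    behavior_code: str = ""
    neighbor_id: str = NONE_NEIGHBOR

    @property
    def alone(self) -> bool:
        return self.neighbor_id == NONE_NEIGHBOR

    def __post_init__(self):
        if self.neighbor_id == self.individual_id:
            raise ValidationError(
                f"individual {self.individual_id!r} recorded as its own nearest "
                f"neighbor (harem {self.harem_id!r}, period {self.period_id!r})"
            )


@dataclass(frozen=True)
class Component:
    code: str
    group_id: str
    modality: str = "visual"
    label: str = ""
    neutral: bool = False

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValidationError(
                f"component {self.code!r}: modality {self.modality!r} not one of "
                f"{MODALITIES}"
            )


@dataclass
class Ethogram:
    """Signal-component inventory with mutually exclusive morphological groups.

    Groups partition the components: each component belongs to exactly one
    group (e.g. the possible ear positions), and a posture may contain at most
    one component per group.  Neutral components are the baseline states
    ("eyes open", "neck normal", ...) excluded from active-signaling subgraphs.
    """

    components: list[Component]
    _by_code: dict[str, Component] = field(init=False, repr=False)

    def __post_init__(self):
        self._by_code = {}
        for c in self.components:
            if c.code in self._by_code:
                raise ValidationError(f"duplicate component code {c.code!r}")
            self._by_code[c.code] = c

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __getitem__(self, code: str) -> Component:
        return self._by_code[code]

    @property
    def codes(self) -> list[str]:
        return [c.code for c in self.components]

    @property
    def neutral_codes(self) -> set[str]:
        return {c.code for c in self.components if c.neutral}

    def group_of(self, code: str) -> str:
        return self._by_code[code].group_id

    def groups(self, codes: Iterable[str] | None = None) -> dict[str, set[str]]:
        """Group-id -> member codes, optionally restricted to ``codes``."""
        sel = set(codes) if codes is not None else None
        out: dict[str, set[str]] = {}
        for c in self.components:
            if sel is None or c.code in sel:
                out.setdefault(c.group_id, set()).add(c.code)
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "Ethogram":
        comps = [
            Component(
                code=str(c["code"]),
                group_id=str(c.get("group_id", c.get("group", c["code"]))),
                modality=str(c.get("modality", "visual")),
                label=str(c.get("label", "")),
                neutral=bool(c.get("neutral", False)),
            )
            for c in d["components"]
        ]
        return cls(comps)


@dataclass(frozen=True)
class Posture:
    """A set of concurrently produced signal components."""

    components: frozenset[str]

    def __post_init__(self):
        if not self.components:
            raise ValidationError("empty posture")

    def validate_against(self, ethogram: Ethogram) -> None:
        unknown = [c for c in self.components if c not in ethogram]
        if unknown:
            raise ValidationError(f"unknown component code(s) {sorted(unknown)}")
        seen: dict[str, str] = {}
        for c in sorted(self.components):
            g = ethogram.group_of(c)
            if g in seen:
                raise ValidationError(
                    f"components {seen[g]!r} and {c!r} are both from mutually "
                    f"exclusive morphological group {g!r}"
                )
            seen[g] = c


@dataclass
class InteractionRecord:
    interaction_id: str
    period_label: str
    focal_id: str
    postures: list[Posture]
    context_tag: str | None = None

    def __post_init__(self):
        if not self.postures:
            raise ValidationError(f"interaction {self.interaction_id!r} has no postures")


SUBSAMPLE_WINDOWS = ("w5_10", "w15_20", "w25_30")


@dataclass(frozen=True)
class ActivityInterval:
    focal_id: str
    period_label: str
    behavior_category: str
    start_s: float
    end_s: float
    subsample_window: str = "w5_10"

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValidationError(
                f"interval for {self.focal_id!r} has end {self.end_s} <= start {self.start_s}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_SCAN_COLUMNS = {
    "harem_id": "harem_id",
    "period_id": "period_id",
    "individual_id": "individual_id",
    "behavior_code": "behavior_code",
    "neighbor_id": "neighbor_id",
}


def _read_table(path, config: Mapping | None) -> pd.DataFrame:
    config = config or {}
    sep = config.get("delimiter")
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _map_columns(df: pd.DataFrame, defaults: Mapping[str, str], config: Mapping | None,
                 required: Sequence[str]) -> pd.DataFrame:
    mapping = dict(defaults)
    mapping.update((config or {}).get("columns", {}))
    missing = [mapping[f] for f in required if mapping[f] not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s) {missing}; found {list(df.columns)}")
    return df.rename(columns={v: k for k, v in mapping.items()})


def read_roster(path, config: Mapping | None = None) -> list[Individual]:
    df = _read_table(path, config)
    df = _map_columns(
        df,
        {"id": "id", "harem_id": "harem_id", "age_sex_class": "age_sex_class",
         "age_months": "age_months"},
        config,
        required=["id", "harem_id"],
    )
    out, seen = [], set()
    for i, row in df.iterrows():
        if row["id"] in seen:
            raise ValidationError(f"row {i + 2}: duplicate individual id {row['id']!r}")
        seen.add(row["id"])
        age = row.get("age_months", "")
        out.append(
            Individual(
                id=row["id"],
                harem_id=row["harem_id"],
                age_sex_class=row.get("age_sex_class", "") or "nonlactating_female",
                age_months=float(age) if age not in ("", None) else None,
            )
        )
    return out


def read_scan_table(path, config: Mapping | None = None,
                    roster: Sequence[Individual] | None = None) -> list[ScanRecord]:
    """Read nearest-neighbor scan samples.

    Each row is one individual at one sampling period; ``neighbor_id`` is the
    NONE token when no harem member was within one body length.  If a roster
    is supplied, individual and neighbor ids must belong to the stated harem.
    """
    df = _read_table(path, config)
    df = _map_columns(df, _SCAN_COLUMNS, config,
                      required=["harem_id", "period_id", "individual_id", "neighbor_id"])
    none_token = (config or {}).get("none_token", NONE_NEIGHBOR)
    by_id = {ind.id: ind for ind in roster} if roster is not None else None

    records, errors = [], []
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        neighbor = row["neighbor_id"]
        if neighbor in ("", none_token):
            neighbor = NONE_NEIGHBOR
        try:
            rec = ScanRecord(
                harem_id=row["harem_id"],
                period_id=row["period_id"],
                individual_id=row["individual_id"],
                behavior_code=row.get("behavior_code", ""),
                neighbor_id=neighbor,
            )
        except ValidationError as e:
            errors.append(f"row {rowno}: {e}")
            continue
        if by_id is not None:
            for which in ("individual_id", "neighbor_id"):
                iid = getattr(rec, which)
                if iid == NONE_NEIGHBOR:
                    continue
                if iid not in by_id:
                    errors.append(f"row {rowno}: unknown individual id {iid!r}")
                elif by_id[iid].harem_id != rec.harem_id:
                    errors.append(
                        f"row {rowno}: {iid!r} belongs to harem "
                        f"{by_id[iid].harem_id!r}, not {rec.harem_id!r}"
                    )
        records.append(rec)
    if errors:
        raise ValidationError("; ".join(errors))
    return records


def write_scan_table(records: Iterable[ScanRecord], path) -> None:
    pd.DataFrame(
        [
            {"harem_id": r.harem_id, "period_id": r.period_id,
             "individual_id": r.individual_id, "behavior_code": r.behavior_code,
             "neighbor_id": r.neighbor_id}
            for r in records
        ]
    ).to_csv(path, index=False)


def read_interaction_table(path, ethogram: Ethogram,
                           config: Mapping | None = None) -> list[InteractionRecord]:
    """Read coded interactions from long format.

    One row per (interaction, posture, component); postures are ordered by
    ``posture_index`` within each interaction.  Every component code must
    exist in the ethogram and postures must respect group exclusivity.
    """
    df = _read_table(path, config)
    df = _map_columns(
        df,
        {"interaction_id": "interaction_id", "period_label": "period_label",
         "focal_id": "focal_id", "posture_index": "posture_index",
         "component_code": "component_code", "context_tag": "context_tag"},
        config,
        required=["interaction_id", "posture_index", "component_code"],
    )
    records = []
    for iid, sub in df.groupby("interaction_id", sort=False):
        postures = []
        for _, psub in sub.groupby(sub["posture_index"].astype(int), sort=True):
            p = Posture(frozenset(psub["component_code"]))
            try:
                p.validate_against(ethogram)
            except ValidationError as e:
                raise ValidationError(f"interaction {iid!r}: {e}") from None
            postures.append(p)
        first = sub.iloc[0]
        records.append(
            InteractionRecord(
                interaction_id=str(iid),
                period_label=first.get("period_label", ""),
                focal_id=first.get("focal_id", ""),
                postures=postures,
                context_tag=first.get("context_tag") or None,
            )
        )
    return records


def write_interaction_table(records: Iterable[InteractionRecord], path) -> None:
    rows = []
    for r in records:
        for pi, p in enumerate(r.postures):
            for code in sorted(p.components):
                rows.append(
                    {"interaction_id": r.interaction_id, "period_label": r.period_label,
                     "focal_id": r.focal_id, "posture_index": pi,
                     "component_code": code, "context_tag": r.context_tag or ""}
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ethogram(path) -> Ethogram:
    """Read a YAML/JSON ethogram config (YAML is a JSON superset)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return Ethogram.from_dict(data)


def write_ethogram(ethogram: Ethogram, path) -> None:
    data = {
        "components": [
            {"code": c.code, "label": c.label, "modality": c.modality,
             "group_id": c.group_id, "neutral": c.neutral}
            for c in ethogram.components
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_activity_table(path, config: Mapping | None = None) -> list[ActivityInterval]:
    df = _read_table(path, config)
    df = _map_columns(
        df,
        {"focal_id": "focal_id", "period_label": "period_label",
         "behavior_category": "behavior_category", "start_s": "start_s",
         "end_s": "end_s", "subsample_window": "subsample_window"},
        config,
        required=["focal_id", "behavior_category", "start_s", "end_s"],
    )
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                ActivityInterval(
                    focal_id=row["focal_id"],
                    period_label=row.get("period_label", ""),
                    behavior_category=row["behavior_category"],
                    start_s=float(row["start_s"]),
                    end_s=float(row["end_s"]),
                    subsample_window=row.get("subsample_window", "w5_10") or "w5_10",
                )
            )
        except (ValidationError, ValueError) as e:
            raise ValidationError(f"row {i + 2}: {e}") from None
    return out


def roster_by_harem(roster: Sequence[Individual]) -> dict[str, list[Individual]]:
    out: dict[str, list[Individual]] = {}
    for ind in roster:
        out.setdefault(ind.harem_id, []).append(ind)
    return out
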