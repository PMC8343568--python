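"""Turn raw per-rater action ratings into z-scored action coordinates.

Each rater judges a set of actions on exactly one of the six dimensions.
Raters showing too little response variability (10 or fewer unique rating
values) are excluded, as are raters whose metadata flags indicate
non-native or below-excellent English when those columns are present.
Surviving ratings are averaged per (action, dimension) and z-scored per
dimension across actions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import DIMENSIONS, ActionCoordinates, zscore

__all__ = ["ExclusionReport", "exclude_raters", "aggregate_ratings"]

#: A rater is dropped when their count of unique rating values is at or
#: below this bound ("unique responses" is read as unique rating values;
#: the alternative reading — unique items answered — is noted in the report).
MAX_DEGENERATE_UNIQUE = 10


@dataclass
class ExclusionReport:
    """Which raters were dropped and why."""

    excluded: list[dict] = field(default_factory=list)
    note: str = (
        "low_variability counts unique rating values; an alternative reading "
        "(unique items answered) is not applied"
    )

    def add(self, rater_id: str, reason: str, detail: str = "") -> None:
        self.excluded.append(
            {"rater_id": str(rater_id), "reason": reason, "detail": detail}
        )

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    def to_dict(self) -> dict:
        return {"excluded": self.excluded, "note": self.note}


def _validate(table: pd.DataFrame) -> None:
    required = {"rater_id", "action_id", "dimension", "rating"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"ratings table missing columns: {sorted(missing)}")
    bad_dims = set(table["dimension"].unique()) - set(DIMENSIONS)
    if bad_dims:
        raise ValueError(f"unknown dimensions in ratings table: {sorted(bad_dims)}")
    per_rater = table.groupby("rater_id")["dimension"].nunique()
    multi = per_rater[per_rater > 1]
    if len(multi):
        raise ValueError(
            f"raters assigned to more than one dimension: {list(multi.index)}"
        )


def exclude_raters(raw: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the rater exclusion rules; returns (filtered table, report).

    Rules: (1) raters with <= 10 unique rating values are dropped
    (low variability); (2) when ``native_speaker`` / ``proficiency``
    columns are present, raters with a falsy flag are dropped.  Raises if
    the table is empty or every rater is excluded.
    """
    if raw.empty:
        raise ValueError("ratings table is empty")
    _validate(raw)
    report = ExclusionReport()
    drop: set = set()
    for col, reason in (
        ("native_speaker", "non_native_english"),
        ("proficiency", "below_excellent_english"),
    ):
        if col in raw.columns:
            flags = raw.groupby("rater_id")[col].first()
            for rater, ok in flags.items():
                if not bool(ok) and rater not in drop:
                    drop.add(rater)
                    report.add(rater, reason)
    nunique = raw.groupby("rater_id")["rating"].nunique()
    for rater, n in nunique.items():
        if n <= MAX_DEGENERATE_UNIQUE and rater not in drop:
            drop.add(rater)
            report.add(rater, "low_variability", f"{int(n)} unique rating values")
    filtered = raw[~raw["rater_id"].isin(drop)].copy()
    if filtered.empty:
        raise ValueError("all raters were excluded")
    return filtered, report


def aggregate_ratings(
    filtered: pd.DataFrame, action_ids: list[str]
) -> ActionCoordinates:
    """Mean rating per (action, dimension), then z-score per dimension.

    Every action in ``action_ids`` must have at least one rating on every
    dimension; missing cells raise with the offending pairs named.  Row
    order of the input table is irrelevant; output rows follow
    ``action_ids``.
    """
    _validate(filtered)
    cell = (
        filtered.groupby(["action_id", "dimension"], sort=False)["rating"]
        .mean()
        .unstack("dimension")
    )
    missing_actions = [a for a in action_ids if a not in cell.index]
    missing_pairs = [(a, d) for a in missing_actions for d in DIMENSIONS]
    if not missing_actions:
        sub = cell.reindex(index=action_ids, columns=list(DIMENSIONS))
        rows, cols = np.nonzero(sub.isna().to_numpy())
        missing_pairs = [(action_ids[r], DIMENSIONS[c]) for r, c in zip(rows, cols)]
    if missing_pairs:
        shown = ", ".join(f"({a}, {d})" for a, d in missing_pairs[:10])
        more = "" if len(missing_pairs) <= 10 else f" and {len(missing_pairs) - 10} more"
        raise ValueError(f"no ratings for (action, dimension) pairs: {shown}{more}")
    mat = cell.reindex(index=action_ids, columns=list(DIMENSIONS)).to_numpy(float)
    return ActionCoordinates(list(action_ids), zscore(mat), provenance="rated")
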