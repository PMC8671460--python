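"""Sensitive-line and active-compound calling, and the MOA landscape table.

At the calibrated cutoff (default logFC < -1) a line is "sensitive" to a
compound; a compound with at least ``min_lines`` (default 3) sensitive lines
is "active"; an active compound killing more than 90% of its evaluable lines
is "broadly toxic" rather than selective.  The landscape table tallies, per
annotated mechanism of action, how many compounds were tested, how many are
active, and how many of the actives are broad.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .screenio import DrugResponseMatrix

__all__ = ["ActivityCall", "call_sensitive", "call_active", "call_activity", "moa_landscape"]

BROAD_FRACTION = 0.9


@dataclass
class ActivityCall:
    compound_id: str
    sensitive_lines: set[str]
    n_sensitive: int
    n_evaluable: int
    frac_sensitive: float
    is_active: bool
    is_broad: bool


def call_sensitive(values: pd.DataFrame | DrugResponseMatrix, cutoff: float = -1.0) -> pd.DataFrame:
    """Boolean compounds x lines matrix: True iff logFC strictly < cutoff.

    Missing values are neither sensitive nor evaluable (False here; tracked
    separately via the missing mask by :func:`call_active`).
    """
    if isinstance(values, DrugResponseMatrix):
        values = values.values
    # NaN compares False, so missing entries are never sensitive; a -inf
    # cutoff yields all-False under the strict inequality.
    return values < cutoff


def call_active(
    sensitive: pd.DataFrame,
    evaluable: pd.DataFrame | None = None,
    min_lines: int = 3,
) -> list[ActivityCall]:
    """One :class:`ActivityCall` per compound from a boolean sensitivity matrix.

    ``evaluable`` marks which entries were actually screened (defaults to
    all); a compound is active iff its sensitive count is >= ``min_lines``.
    """
    if min_lines < 1:
        raise ValueError("min_lines must be >= 1")
    if evaluable is None:
        evaluable = pd.DataFrame(True, index=sensitive.index, columns=sensitive.columns)
    calls = []
    for cid in sensitive.index:
        row = sensitive.loc[cid] & evaluable.loc[cid]
        n_eval = int(evaluable.loc[cid].sum())
        hit = set(row.index[row])
        frac = len(hit) / n_eval if n_eval else float("nan")
        calls.append(
            ActivityCall(
                compound_id=str(cid),
                sensitive_lines=hit,
                n_sensitive=len(hit),
                n_evaluable=n_eval,
                frac_sensitive=frac,
                is_active=len(hit) >= min_lines,
                is_broad=bool(n_eval and frac > BROAD_FRACTION),
            )
        )
    return calls


def call_activity(
    matrix: DrugResponseMatrix, cutoff: float = -1.0, min_lines: int = 3
) -> list[ActivityCall]:
    """Convenience: sensitivity calls then activity calls on a screen matrix."""
    sens = call_sensitive(matrix.values, cutoff)
    evaluable = matrix.values.notna()
    return call_active(sens, evaluable, min_lines)


def calls_to_frame(calls: list[ActivityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in calls],
            "n_sensitive": [c.n_sensitive for c in calls],
            "n_evaluable": [c.n_evaluable for c in calls],
            "frac_sensitive": [c.frac_sensitive for c in calls],
            "is_active": [c.is_active for c in calls],
            "is_broad": [c.is_broad for c in calls],
        }
    ).set_index("compound_id")


def _split_moa(label) -> list[str]:
    if label is None or (isinstance(label, float) and np.isnan(label)):
        return ["unknown"]
    if isinstance(label, (list, tuple, set)):
        return [str(m) for m in label] or ["unknown"]
    parts = [p.strip() for p in re.split(r"[;,]", str(label)) if p.strip()]
    return parts or ["unknown"]


def moa_landscape(
    calls: list[ActivityCall],
    compound_info: pd.DataFrame | None,
    min_active_per_moa: int = 5,
) -> pd.DataFrame:
    """Per-MOA activity tally, one row per MOA clearing the display floor.

    Compounds annotated with several MOA labels count once under each label;
    unannotated compounds are grouped as ``"unknown"``.  Rows are sorted by
    active-compound count (descending, then MOA name) and MOAs with fewer
    than ``min_active_per_moa`` active compounds are dropped.
    """
    moa_of: dict[str, list[str]] = {}
    for c in calls:
        label = None
        if compound_info is not None and c.compound_id in compound_info.index:
            label = compound_info.loc[c.compound_id].get("moa")
        moa_of[c.compound_id] = _split_moa(label)

    rows: dict[str, dict[str, int]] = {}
    for c in calls:
        for moa in moa_of[c.compound_id]:
            r = rows.setdefault(moa, {"n_tested": 0, "n_active": 0, "n_broad": 0})
            r["n_tested"] += 1
            if c.is_active:
                r["n_active"] += 1
                if c.is_broad:
                    r["n_broad"] += 1

    table = pd.DataFrame.from_dict(rows, orient="index").rename_axis("moa")
    table = table[table["n_active"] >= min_active_per_moa]
    if table.empty:
        return pd.DataFrame(columns=["n_tested", "n_active", "pct_active", "n_broad"]).rename_axis("moa")
    table["pct_active"] = table["n_active"] / table["n_tested"]
    table = (
        table.reset_index()
        .sort_values(["n_active", "moa"], ascending=[False, True])
        .set_index("moa")
    )
    return table[["n_tested", "n_active", "pct_active", "n_broad"]]
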