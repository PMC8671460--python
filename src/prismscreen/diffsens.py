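"""Differential killing activity between two cohorts of cell lines.

Each compound's logFC values in the in-group (e.g. one cancer type) are
compared against the out-group (all other screened lines) with Welch's
unequal-variance t-test; a hit requires p below ``alpha`` *and* a negative
effect size (the in-group is killed more).  Hits from independent screens
are then intersected on compound name.  A two-tailed Mann-Whitney test is
provided for small ad-hoc group comparisons, exact by enumeration for small
samples without ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .screenio import DrugResponseMatrix

__all__ = [
    "DifferentialHit",
    "two_class_compare",
    "hits_to_frame",
    "intersect_screens",
    "mannwhitney_compare",
]


@dataclass
class DifferentialHit:
    compound_id: str
    effect_size: float  # mean(in) - mean(out) logFC; negative = more killing in-group
    p_value: float
    neg_log10_p: float
    significant: bool


def two_class_compare(
    matrix: DrugResponseMatrix | pd.DataFrame,
    in_ids: list[str],
    out_ids: list[str],
    alpha: float = 0.01,
) -> list[DifferentialHit]:
    """Per-compound Welch t-test of in-group vs out-group killing.

    Compounds with fewer than two non-missing values in either group are
    skipped with a warning.  Significance requires ``p < alpha`` and a
    negative effect size.
    """
    values = matrix.values if isinstance(matrix, DrugResponseMatrix) else matrix
    in_ids, out_ids = list(in_ids), list(out_ids)
    if set(in_ids) & set(out_ids):
        raise ValueError("in-group and out-group overlap")
    missing = (set(in_ids) | set(out_ids)) - set(values.columns)
    if missing:
        raise KeyError(f"unknown line id(s): {sorted(missing)}")

    a = values[in_ids].to_numpy(dtype=float)
    b = values[out_ids].to_numpy(dtype=float)
    n_a = (~np.isnan(a)).sum(axis=1)
    n_b = (~np.isnan(b)).sum(axis=1)
    ok = (n_a >= 2) & (n_b >= 2)
    if (~ok).any():
        warnings.warn(
            f"skipping {int((~ok).sum())} compound(s) with <2 values in a group",
            stacklevel=2,
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
        mean_a = np.nanmean(a, axis=1)
        mean_b = np.nanmean(b, axis=1)
    effect = mean_a - mean_b
    pvals = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: p is NaN; identical means -> no evidence
    degenerate = np.isnan(pvals)
    pvals[degenerate & (effect == 0)] = 1.0
    pvals[degenerate & (effect != 0)] = 0.0

    hits = []
    for i, cid in enumerate(values.index):
        if not ok[i]:
            continue
        p = float(pvals[i])
        hits.append(
            DifferentialHit(
                compound_id=str(cid),
                effect_size=float(effect[i]),
                p_value=p,
                neg_log10_p=float(-np.log10(p)) if p > 0 else np.inf,
                significant=bool(p < alpha and effect[i] < 0),
            )
        )
    return hits


def hits_to_frame(hits: list[DifferentialHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "compound_id": [h.compound_id for h in hits],
            "effect_size": [h.effect_size for h in hits],
            "p_value": [h.p_value for h in hits],
            "neg_log10_p": [h.neg_log10_p for h in hits],
            "significant": [h.significant for h in hits],
        }
    ).set_index("compound_id")


def intersect_screens(primary_hits, secondary_hits) -> set[str]:
    """Intersect two screens' hits on unique compound names.

    Accepts iterables of names or of :class:`DifferentialHit` (only
    significant hits are kept in that case); duplicate entries collapse
    before intersecting.
    """

    def names(hits) -> set[str]:
        out = set()
        for h in hits:
            if isinstance(h, DifferentialHit):
                if h.significant:
                    out.add(h.compound_id)
            else:
                out.add(str(h))
        return out

    return names(primary_hits) & names(secondary_hits)


def mannwhitney_compare(group_a, group_b) -> tuple[float, float]:
    """Two-tailed unpaired Mann-Whitney test: (U of group A, two-sided p).

    Uses exact enumeration when the sample product n*m <= 400 and there are
    no ties, and the tie-corrected normal approximation otherwise.  When
    every value across both groups is identical the statistic carries no
    information and p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
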