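"""Expression-based biomarker discovery for a drug class.

The workflow: rank cell lines by their mean response over a compound set and
take the extreme responders as groups; find differentially expressed genes
between them with an empirical-Bayes moderated t-test (per-gene variances
shrunk toward a prior estimated from all genes); test candidate pathways by
hypergeometric over-representation; shortlist single-gene biomarkers by
Pearson correlation of expression with response; and score multi-gene
signatures as the per-line mean of gene-wise Z-scores.

The moderated t follows the standard empirical-Bayes formulation: with
per-gene pooled variance ``s_g^2`` on ``d_g`` residual degrees of freedom and
a scaled inverse-chi-square prior (``d_0``, ``s_0^2``) fitted to the ensemble
of variances by moment-matching on the log scale, the posterior variance is
``(d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g)`` and the t-statistic gains
``d_0`` degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .screenio import DrugResponseMatrix

__all__ = [
    "EBParams",
    "DEGRecord",
    "CorrelationHit",
    "rank_lines_by_mean_response",
    "fit_eb_params",
    "moderated_t_test",
    "degs_to_frame",
    "overrepresentation",
    "correlate_expression",
    "signature_score",
]


@dataclass
class EBParams:
    """Prior degrees of freedom and prior variance of the variance model."""

    d0: float  # np.inf = all variances shrunk fully to s0_sq
    s0_sq: float


@dataclass
class DEGRecord:
    gene: str
    mean_diff: float  # log2 expression difference, group A - group B
    moderated_t: float
    p_value: float
    q_value: float
    direction: str  # "up" iff mean_diff > 0


@dataclass
class CorrelationHit:
    gene: str
    r: float
    p_value: float
    shortlisted: bool  # p < 0.05


def rank_lines_by_mean_response(
    matrix: DrugResponseMatrix | pd.DataFrame,
    compound_set: list[str],
    n_extreme: int,
) -> tuple[list[str], list[str]]:
    """Extreme responder groups by mean logFC over a compound set.

    Lines are ordered by their mean logFC across ``compound_set`` (missing
    values excluded; ties broken lexicographically by line id); the lowest
    ``n_extreme`` are the sensitive group, the highest the resistant group.
    """
    values = matrix.values if isinstance(matrix, DrugResponseMatrix) else matrix
    compound_set = list(compound_set)
    if not compound_set:
        raise ValueError("compound_set is empty")
    missing = set(compound_set) - set(values.index)
    if missing:
        raise KeyError(f"unknown compound id(s): {sorted(missing)}")
    if 2 * n_extreme > values.shape[1]:
        raise ValueError("2 * n_extreme exceeds the number of lines")
    means = values.loc[compound_set].mean(axis=0, skipna=True)
    order = sorted(means.index, key=lambda l: (means[l], l))
    sensitive = list(order[:n_extreme])
    resistant = list(order[len(order) - n_extreme :]) if n_extreme else []
    return sensitive, resistant


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_eb_params(sample_variances, residual_df: float) -> EBParams:
    """Moment-match the scaled inverse-chi-square prior to observed variances.

    Works on the log scale: for variances drawn from the model,
    ``log s^2 - digamma(d/2) + log(d/2)`` has mean ``log s0^2 +
    digamma(d0/2) - log(d0/2)`` and excess variance ``trigamma(d0/2)``
    beyond the sampling term ``trigamma(d/2)``; ``d0`` comes from inverting
    the trigamma, ``s0^2`` from the mean.  Zero excess spread flags
    ``d0 = inf`` (complete shrinkage).
    """
    s2 = np.asarray(sample_variances, dtype=float)
    if s2.size < 10:
        raise ValueError("need at least 10 genes to estimate the variance prior")
    if (s2 < 0).any():
        raise ValueError("sample variances must be >= 0")
    if (s2 == 0).any():
        warnings.warn("dropping zero sample variances from the prior fit", stacklevel=2)
        s2 = s2[s2 > 0]
        if s2.size < 10:
            raise ValueError("fewer than 10 positive variances")
    d = float(residual_df)
    z = np.log(s2)
    e = z - float(special.digamma(d / 2)) + np.log(d / 2)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2))
    if evar <= 0:
        return EBParams(d0=np.inf, s0_sq=float(np.exp(np.mean(e))))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return EBParams(d0=d0, s0_sq=s0_sq)


def moderated_t_test(
    expr: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    eb: EBParams | None = None,
    q_cutoff: float = 0.05,
) -> list[DEGRecord]:
    """Empirical-Bayes moderated two-sample t-test per gene (A vs B).

    ``eb=None`` fits the prior from this matrix's pooled variances;
    ``EBParams(0, s0)`` reduces to the ordinary pooled t.  Genes with zero
    variance in both groups and zero mean difference get t = 0, p = 1.
    q-values are Benjamini-Hochberg over all tested genes.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 lines")
    a = expr[group_a].to_numpy(dtype=float)
    b = expr[group_b].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    dg = na + nb - 2
    diff = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / dg

    if eb is None:
        eb = fit_eb_params(s2, dg)
    if np.isinf(eb.d0):
        post_var = np.full_like(s2, eb.s0_sq)
        df = np.inf
    elif eb.d0 == 0:
        post_var = s2
        df = dg
    else:
        post_var = (eb.d0 * eb.s0_sq + dg * s2) / (eb.d0 + dg)
        df = eb.d0 + dg

    scale = np.sqrt(post_var * (1.0 / na + 1.0 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(scale > 0, diff / np.where(scale > 0, scale, 1.0), np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
        if np.isinf(df):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, 0.0, 1.0)
    q = multipletests(p, method="fdr_bh")[1]

    return [
        DEGRecord(
            gene=str(g),
            mean_diff=float(diff[i]),
            moderated_t=float(t[i]),
            p_value=float(p[i]),
            q_value=float(q[i]),
            direction="up" if diff[i] > 0 else "down",
        )
        for i, g in enumerate(expr.index)
    ]


def degs_to_frame(records: list[DEGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "mean_diff": [r.mean_diff for r in records],
            "moderated_t": [r.moderated_t for r in records],
            "p_value": [r.p_value for r in records],
            "q_value": [r.q_value for r in records],
            "direction": [r.direction for r in records],
        }
    ).set_index("gene")


def overrepresentation(
    hit_genes, universe_genes, gene_sets: dict[str, list[str]]
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of hits in each gene set.

    Returns a DataFrame (set name -> overlap, set_size, p_value, q_value)
    ordered by p.  ``hit_genes`` must be contained in ``universe_genes``.
    """
    universe = set(universe_genes)
    hits = set(hit_genes)
    if not universe:
        raise ValueError("empty universe")
    if not hits <= universe:
        raise ValueError("hit_genes must be a subset of universe_genes")
    N, n = len(universe), len(hits)
    rows = []
    for name, genes in gene_sets.items():
        members = set(genes) & universe
        K = len(members)
        k = len(members & hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, k, K, min(p, 1.0)))
    frame = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p_value"]).set_index("set")
    frame["q_value"] = multipletests(frame["p_value"].to_numpy(), method="fdr_bh")[1] if len(frame) else []
    return frame.sort_values(["p_value", "set"], kind="stable")


def correlate_expression(
    expr: pd.DataFrame,
    response: pd.Series,
    genes: list[str] | None = None,
    alpha: float = 0.05,
) -> list[CorrelationHit]:
    """Pearson-correlate each gene's expression with a per-line drug response.

    Two-sided p from the t transform on n-2 df; genes shortlisted at
    ``p < alpha``.  Zero-variance genes (or pairs with < 3 shared lines) are
    excluded with a warning.
    """
    genes = list(genes) if genes is not None else list(expr.index)
    missing = [g for g in genes if g not in expr.index]
    if missing:
        warnings.warn(f"gene(s) absent from matrix, skipped: {missing[:5]}", stacklevel=2)
        genes = [g for g in genes if g in expr.index]
    shared = [l for l in expr.columns if l in response.index and np.isfinite(response[l])]
    hits: list[CorrelationHit] = []
    dropped = []
    for g in genes:
        x = expr.loc[g, shared].to_numpy(dtype=float)
        y = response[shared].to_numpy(dtype=float)
        mask = np.isfinite(x) & np.isfinite(y)
        if mask.sum() < 3:
            dropped.append(g)
            continue
        xv, yv = x[mask], y[mask]
        if np.std(xv) == 0 or np.std(yv) == 0:
            dropped.append(g)
            continue
        r, p = stats.pearsonr(xv, yv)
        hits.append(CorrelationHit(str(g), float(r), float(p), bool(p < alpha)))
    if dropped:
        warnings.warn(
            f"excluded {len(dropped)} gene(s) with undefined correlation", stacklevel=2
        )
    return hits


def signature_score(expr: pd.DataFrame, gene_list: list[str]) -> pd.Series:
    """Per-line signature score: mean across genes of gene-wise Z-scores.

    Each gene is standardized across lines (mean 0, sd 1) before averaging,
    so genes on different expression scales contribute equally.  Genes
    absent from the matrix (or with zero variance) are skipped with a
    warning; an empty signature is an error.
    """
    present = [g for g in gene_list if g in expr.index]
    absent = [g for g in gene_list if g not in expr.index]
    if absent:
        warnings.warn(f"signature gene(s) absent, skipped: {absent}", stacklevel=2)
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    sub = expr.loc[present].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    keep = sd.ravel() > 0
    if not keep.all():
        warnings.warn("dropping zero-variance signature gene(s)", stacklevel=2)
        sub, mu, sd = sub[keep], mu[keep], sd[keep]
        if sub.size == 0:
            raise ValueError("all signature genes have zero variance")
    z = (sub - mu) / sd
    return pd.Series(z.mean(axis=0), index=expr.columns, name="signature_score")
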