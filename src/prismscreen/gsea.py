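"""Gene set enrichment analysis: weighted-KS score with permutation testing.

Genes are ranked by the signal-to-noise ratio (muA - muB)/(sigmaA + sigmaB),
each class standard deviation floored at max(0.2 * |class mean|, 0.2).  The
enrichment score (ES) of a gene set is the signed maximum deviation of a
running sum that walks the ranked list, incrementing at set members by their
|metric|^p share and decrementing at non-members by 1/(N - N_hits); the walk
ends exactly at zero.  Significance comes from permutations — phenotype
relabelling (recomputing the ranking) or random same-size gene sets — with
the normalized enrichment score (NES) scaling ES by the mean same-sign
permuted |ES| of that set, a same-sign tail nominal p, and the standard
pooled-NES ratio false-discovery estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "signal_to_noise_rank",
    "enrichment_score",
    "permutation_significance",
    "results_to_frame",
    "compare_enriched_sets",
]

SD_FLOOR = 0.2


@dataclass
class RankedList:
    """Genes ordered by metric, descending; ties broken by gene name."""

    genes: list[str]
    metric: np.ndarray

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    n_genes_in_list: int
    leading_edge: list[str]


def _s2n_metric(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Signal-to-noise per gene with the floored class standard deviations."""
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    sd_a, sd_b = a.std(axis=1, ddof=1), b.std(axis=1, ddof=1)
    sd_a = np.maximum(sd_a, np.maximum(SD_FLOOR * np.abs(mu_a), SD_FLOOR))
    sd_b = np.maximum(sd_b, np.maximum(SD_FLOOR * np.abs(mu_b), SD_FLOOR))
    return (mu_a - mu_b) / (sd_a + sd_b)


def signal_to_noise_rank(
    expr: pd.DataFrame, class_a: list[str], class_b: list[str]
) -> RankedList:
    """Rank all genes by the signal-to-noise ratio between two classes."""
    class_a, class_b = list(class_a), list(class_b)
    if len(class_a) < 2 or len(class_b) < 2:
        raise ValueError("each class needs >= 2 samples")
    metric = _s2n_metric(
        expr[class_a].to_numpy(dtype=float), expr[class_b].to_numpy(dtype=float)
    )
    order = sorted(range(len(expr.index)), key=lambda i: (-metric[i], str(expr.index[i])))
    return RankedList([str(expr.index[i]) for i in order], metric[order])


def enrichment_score(
    ranked: RankedList, gene_set, weight_p: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted-KS enrichment score and the full running sum.

    Set genes absent from the ranked list are dropped; a set with no gene in
    the list is an error.  ``weight_p = 0`` recovers the classic unweighted
    KS statistic.
    """
    members = set(gene_set) & set(ranked.genes)
    if not members:
        raise ValueError("no gene of the set appears in the ranked list")
    n = len(ranked)
    hit = np.fromiter((g in members for g in ranked.genes), dtype=bool, count=n)
    n_hits = int(hit.sum())
    weights = np.abs(ranked.metric) ** weight_p
    hit_total = weights[hit].sum()
    if hit_total == 0:  # all hit metrics zero: fall back to equal hit weights
        increments = np.where(hit, 1.0 / n_hits, 0.0)
    else:
        increments = np.where(hit, weights / hit_total, 0.0)
    if n > n_hits:
        increments = increments - np.where(hit, 0.0, 1.0 / (n - n_hits))
    running = np.cumsum(increments)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _es_only(order_weights: np.ndarray, hit_mask: np.ndarray) -> float:
    """ES of one ranked arrangement (no running-sum output; used in permutation loops)."""
    n = hit_mask.size
    n_hits = int(hit_mask.sum())
    hit_total = order_weights[hit_mask].sum()
    if hit_total == 0:
        inc = np.where(hit_mask, 1.0 / n_hits, 0.0)
    else:
        inc = np.where(hit_mask, order_weights / hit_total, 0.0)
    if n > n_hits:
        inc = inc - np.where(hit_mask, 0.0, 1.0 / (n - n_hits))
    running = np.cumsum(inc)
    return float(running[np.argmax(np.abs(running))])


def _leading_edge(ranked: RankedList, gene_set, weight_p: float) -> list[str]:
    es, running = enrichment_score(ranked, gene_set, weight_p)
    members = set(gene_set)
    peak = int(np.argmax(np.abs(running)))
    if es >= 0:
        return [g for g in ranked.genes[: peak + 1] if g in members]
    return [g for g in ranked.genes[peak:] if g in members]


def permutation_significance(
    expr: pd.DataFrame,
    class_a: list[str],
    class_b: list[str],
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    mode: str | None = None,
    weight_p: float = 1.0,
    seed: int = 0,
    size_bounds: tuple[int, int] = (15, 500),
) -> list[EnrichmentResult]:
    """Permutation-based NES, nominal p and FDR q for each gene set.

    ``mode`` is ``"phenotype"`` (relabel samples, recompute the ranking) or
    ``"gene_set"`` (random same-size sets on the fixed ranking); the default
    picks phenotype when both classes have >= 7 samples, following the usual
    small-sample guidance.  Sets outside ``size_bounds`` after restriction
    to genes in the matrix are dropped with a warning.  Deterministic given
    ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    class_a, class_b = list(class_a), list(class_b)
    if mode is None:
        mode = "phenotype" if min(len(class_a), len(class_b)) >= 7 else "gene_set"
    if mode not in ("phenotype", "gene_set"):
        raise ValueError("mode must be 'phenotype' or 'gene_set'")
    if mode == "phenotype" and min(len(class_a), len(class_b)) < 3:
        raise ValueError("phenotype permutation needs >= 3 samples per class")

    rng = np.random.default_rng(seed)
    ranked = signal_to_noise_rank(expr, class_a, class_b)
    gene_names = [str(g) for g in expr.index]
    row_of = {g: i for i, g in enumerate(gene_names)}
    n = len(ranked)

    # membership masks in expression-row order; re-ranked per permutation
    kept: dict[str, np.ndarray] = {}
    for name, genes in gene_sets.items():
        rows = sorted({row_of[g] for g in genes if g in row_of})
        if not size_bounds[0] <= len(rows) <= size_bounds[1]:
            warnings.warn(
                f"dropping gene set {name!r}: {len(rows)} genes in list, outside "
                f"{size_bounds}",
                stacklevel=2,
            )
            continue
        member = np.zeros(n, dtype=bool)
        member[rows] = True
        kept[name] = member
    names = list(kept)
    if not names:
        return []

    obs_order = np.array([row_of[g] for g in ranked.genes], dtype=int)
    obs_weights = np.abs(ranked.metric) ** weight_p
    obs_es = np.array(
        [_es_only(obs_weights, kept[name][obs_order]) for name in names]
    )

    perm_es = np.empty((len(names), n_perm))
    if mode == "phenotype":
        cols = class_a + class_b
        data = expr[cols].to_numpy(dtype=float)
        na = len(class_a)
        for p in range(n_perm):
            perm = rng.permutation(len(cols))
            metric = _s2n_metric(data[:, perm[:na]], data[:, perm[na:]])
            order = np.argsort(-metric, kind="stable")
            w = np.abs(metric[order]) ** weight_p
            for j, name in enumerate(names):
                perm_es[j, p] = _es_only(w, kept[name][order])
    else:
        for j, name in enumerate(names):
            size = int(kept[name].sum())
            for p in range(n_perm):
                mask = np.zeros(n, dtype=bool)
                mask[rng.choice(n, size=size, replace=False)] = True
                perm_es[j, p] = _es_only(obs_weights, mask)

    # per-set same-sign normalization
    nes = np.empty(len(names))
    nominal_p = np.empty(len(names))
    norm_perm = np.empty_like(perm_es)
    for j in range(len(names)):
        pes = perm_es[j]
        pos = pes[pes > 0]
        neg = -pes[pes < 0]
        mean_pos = pos.mean() if pos.size else np.abs(pes).mean() or 1.0
        mean_neg = neg.mean() if neg.size else np.abs(pes).mean() or 1.0
        norm_perm[j] = np.where(pes >= 0, pes / mean_pos, pes / mean_neg)
        if obs_es[j] >= 0:
            nes[j] = obs_es[j] / mean_pos
            nominal_p[j] = (pos >= obs_es[j]).sum() / max(pos.size, 1)
        else:
            nes[j] = obs_es[j] / mean_neg
            nominal_p[j] = (neg >= -obs_es[j]).sum() / max(neg.size, 1)

    pooled = norm_perm.ravel()
    fdr = np.empty(len(names))
    for j in range(len(names)):
        v = nes[j]
        if v >= 0:
            num_tail = (pooled >= v).sum() / max((pooled >= 0).sum(), 1)
            den_tail = (nes >= v).sum() / max((nes >= 0).sum(), 1)
        else:
            num_tail = (pooled <= v).sum() / max((pooled < 0).sum(), 1)
            den_tail = (nes <= v).sum() / max((nes < 0).sum(), 1)
        fdr[j] = min(1.0, max(0.0, num_tail / den_tail)) if den_tail > 0 else 1.0

    results = [
        EnrichmentResult(
            set_name=name,
            es=float(obs_es[j]),
            nes=float(nes[j]),
            nominal_p=float(nominal_p[j]),
            fdr_q=float(fdr[j]),
            n_genes_in_list=int(kept[name].sum()),
            leading_edge=_leading_edge(ranked, gene_sets[name], weight_p),
        )
        for j, name in enumerate(names)
    ]
    results.sort(key=lambda r: -r.nes)
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "nominal_p": [r.nominal_p for r in results],
            "fdr_q": [r.fdr_q for r in results],
            "n_genes": [r.n_genes_in_list for r in results],
        }
    ).set_index("set")


def compare_enriched_sets(
    results_by_dataset: dict[str, list[EnrichmentResult]],
    fdr_cut: float = 0.25,
    direction: str = "positive",
) -> dict:
    """Intersect enriched set names across datasets at an FDR cut.

    Keeps, per dataset, the sets enriched in the requested direction
    (``"positive"``: NES > 0, ``"negative"``: NES < 0) with fdr_q < fdr_cut,
    and reports the all-datasets intersection plus pairwise overlap counts.
    """
    if len(results_by_dataset) < 2:
        raise ValueError("need results from at least two datasets")
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    sign = 1 if direction == "positive" else -1
    enriched = {
        ds: {r.set_name for r in results if sign * r.nes > 0 and r.fdr_q < fdr_cut}
        for ds, results in results_by_dataset.items()
    }
    datasets = list(enriched)
    common = set.intersection(*enriched.values())
    pairwise = {
        (d1, d2): len(enriched[d1] & enriched[d2])
        for i, d1 in enumerate(datasets)
        for d2 in datasets[i + 1 :]
    }
    return {"per_dataset": enriched, "intersection": common, "pairwise_counts": pairwise}
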