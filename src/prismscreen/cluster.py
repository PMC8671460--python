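"""Rank-correlation distances, hierarchical clustering, repeated t-SNE runs
and the all-runs consistency rule for assigning putative MOAs.

Drug-response profiles are compared with the metric 1 - Spearman rho
(pairwise-complete over shared non-missing entries) and clustered with
complete linkage.  Because t-SNE is stochastic, mechanism inference for an
unannotated compound demands *consistency*: across every one of ``n_runs``
independent embeddings, the compound's k nearest annotated neighbours must
vote the same mechanism with a unique plurality at or above ``min_frac``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .screenio import DrugResponseMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "EmbeddingSet",
    "ProximityAssignment",
    "spearman_distance",
    "hcluster",
    "cut_tree",
    "to_newick",
    "tsne_runs",
    "consistent_proximity",
]


@dataclass
class DistanceMatrix:
    """Symmetric 1 - Spearman distance matrix over item profiles."""

    values: pd.DataFrame  # square, d[i, i] = 0, d in [0, 2]; NaN = not estimable

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class Dendrogram:
    """Agglomerative merge tree: scipy linkage matrix plus leaf ids."""

    linkage: np.ndarray
    ids: list[str]


@dataclass
class EmbeddingSet:
    """Per-run 2-D coordinates (columns T1, T2) over an identical item set."""

    runs: list[pd.DataFrame]
    perplexity: float
    learning_rate: float
    seeds: list[int]

    @property
    def n_runs(self) -> int:
        return len(self.runs)


@dataclass
class ProximityAssignment:
    query_id: str
    assigned_moa: str | None
    supporting_runs: int
    neighbor_fraction: list[float]  # top-vote fraction per run


def _rank_rows(data: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(rankdata, 1, data)


def spearman_distance(
    matrix: DrugResponseMatrix | pd.DataFrame, axis: str = "compounds", min_shared: int = 3
) -> DistanceMatrix:
    """Pairwise 1 - Spearman distance between rows (compounds) or columns (lines).

    Missing values are handled pairwise-complete: each pair is correlated
    over its shared non-missing observations, with average ranks for ties.
    Pairs sharing fewer than ``min_shared`` observations get a missing
    distance and a warning.
    """
    values = matrix.values if isinstance(matrix, DrugResponseMatrix) else matrix
    if axis not in ("compounds", "lines"):
        raise ValueError("axis must be 'compounds' or 'lines'")
    data = values if axis == "compounds" else values.T
    ids = list(data.index)
    arr = data.to_numpy(dtype=float)
    n = len(ids)

    if not np.isnan(arr).any():
        ranks = _rank_rows(arr)
        ranks -= ranks.mean(axis=1, keepdims=True)
        norm = np.sqrt((ranks**2).sum(axis=1))
        norm[norm == 0] = np.nan  # constant profile: rho undefined
        rho = (ranks @ ranks.T) / np.outer(norm, norm)
        d = 1.0 - rho
    else:
        d = np.full((n, n), np.nan)
        n_dropped = 0
        for i in range(n):
            d[i, i] = 0.0
            for j in range(i + 1, n):
                shared = ~np.isnan(arr[i]) & ~np.isnan(arr[j])
                if shared.sum() < min_shared:
                    n_dropped += 1
                    continue
                xi = rankdata(arr[i, shared])
                xj = rankdata(arr[j, shared])
                xi -= xi.mean()
                xj -= xj.mean()
                denom = np.sqrt((xi**2).sum() * (xj**2).sum())
                if denom == 0:
                    continue
                d[i, j] = d[j, i] = 1.0 - float(xi @ xj) / denom
        if n_dropped:
            warnings.warn(
                f"{n_dropped} pair(s) share fewer than {min_shared} observations; "
                "distance left missing",
                stacklevel=2,
            )
    np.fill_diagonal(d, 0.0)
    frame = pd.DataFrame(d, index=ids, columns=ids)
    return DistanceMatrix(frame)


def hcluster(dist: DistanceMatrix, method: str = "complete") -> Dendrogram:
    """Agglomerative clustering on a precomputed distance matrix."""
    d = dist.values.to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValueError(
            "distance matrix contains missing entries; filter items or impute before clustering"
        )
    condensed = squareform(np.clip(d, 0.0, None), checks=False)
    Z = hierarchy.linkage(condensed, method=method)
    return Dendrogram(Z, dist.ids)


def cut_tree(dendro: Dendrogram, k: int) -> dict[str, int]:
    """Cut the merge tree into ``k`` clusters (removing the k-1 tallest merges)."""
    n = len(dendro.ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    labels = hierarchy.cut_tree(dendro.linkage, n_clusters=k).ravel()
    return {i: int(c) for i, c in zip(dendro.ids, labels)}


def to_newick(dendro: Dendrogram) -> str:
    """Export the dendrogram in Newick format (leaf names preserved)."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(dendro.linkage, dendro.ids)
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def tsne_runs(
    dist: DistanceMatrix,
    perplexity: float = 30.0,
    learning_rate: float = 100.0,
    n_runs: int = 10,
    seeds: list[int] | None = None,
    max_iter: int = 500,
) -> EmbeddingSet:
    """Run t-SNE ``n_runs`` times on the precomputed distance matrix.

    Seeds default to 1..n_runs so the all-runs consistency criterion is
    reproducible; each run is an independent random initialization.
    """
    from sklearn.manifold import TSNE

    d = dist.values.to_numpy(dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("non-finite distances; clean the matrix before embedding")
    n = d.shape[0]
    if n <= 3 * perplexity:
        warnings.warn(
            f"{n} items with perplexity {perplexity}: fewer than the recommended "
            "3x perplexity; consider lowering perplexity",
            stacklevel=2,
        )
    if seeds is None:
        seeds = list(range(1, n_runs + 1))
    if len(seeds) != n_runs:
        raise ValueError("seeds must have length n_runs")
    runs = []
    for seed in seeds:
        tsne = TSNE(
            n_components=2,
            metric="precomputed",
            init="random",
            perplexity=perplexity,
            learning_rate=learning_rate,
            random_state=seed,
            max_iter=max_iter,
        )
        coords = tsne.fit_transform(d)
        runs.append(pd.DataFrame(coords, index=dist.ids, columns=["T1", "T2"]))
    return EmbeddingSet(runs, perplexity, learning_rate, list(seeds))


def _moa_scales(coords: pd.DataFrame, reference_moa: dict[str, str]) -> dict[str, float]:
    """Median pairwise embedded distance among each MOA's reference members."""
    scales: dict[str, float] = {}
    by_moa: dict[str, list[str]] = {}
    for r, m in reference_moa.items():
        if r in coords.index:
            by_moa.setdefault(m, []).append(r)
    for m, members in by_moa.items():
        if len(members) < 2:
            scales[m] = np.inf  # no intra-cluster scale: gate cannot apply
            continue
        xy = coords.loc[members, ["T1", "T2"]].to_numpy(dtype=float)
        d = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(axis=-1))
        scales[m] = float(np.median(d[np.triu_indices(len(members), 1)]))
    return scales


def _run_vote(
    coords: pd.DataFrame,
    query: str,
    reference_moa: dict[str, str],
    k: int,
    min_frac: float,
    max_dist_ratio: float | None,
    scales: dict[str, float],
) -> tuple[str | None, float]:
    """kNN vote of one query in one run: (supported MOA or None, top fraction)."""
    refs = [r for r in coords.index if r in reference_moa and r != query]
    q = coords.loc[query, ["T1", "T2"]].to_numpy(dtype=float)
    ref_xy = coords.loc[refs, ["T1", "T2"]].to_numpy(dtype=float)
    dist = np.sqrt(((ref_xy - q) ** 2).sum(axis=1))
    order = np.lexsort((np.array(refs, dtype=object), dist))  # distance, then id
    nearest = order[:k]
    votes: dict[str, int] = {}
    for i in nearest:
        m = reference_moa[refs[i]]
        votes[m] = votes.get(m, 0) + 1
    top = max(votes.values())
    winners = [m for m, c in votes.items() if c == top]
    frac = top / k
    if len(winners) != 1 or frac < min_frac:
        return None, frac
    winner = winners[0]
    if max_dist_ratio is not None:
        scale = scales.get(winner, np.inf)
        if np.isfinite(scale) and scale > 0:
            query_med = float(np.median(dist[nearest]))
            if query_med > max_dist_ratio * scale:
                return None, frac  # close in rank but far in distance: parked outside
    return winner, frac


def consistent_proximity(
    emb: EmbeddingSet,
    query_ids: list[str],
    reference_moa: dict[str, str],
    k: int = 10,
    min_frac: float = 0.5,
    max_dist_ratio: float | None = 1.3,
) -> list[ProximityAssignment]:
    """Assign a putative MOA to each query only if every run agrees.

    Per run, the query's ``k`` nearest reference items (Euclidean in the 2-D
    embedding) vote; a run supports mechanism *m* when *m* is the unique
    plurality, its vote fraction is >= ``min_frac``, and the query actually
    sits within the winning cluster: its median distance to the ``k``
    neighbours may not exceed ``max_dist_ratio`` times the winning MOA's own
    median pairwise member distance (rank-nearest is not enough — a point
    far outside every cluster still has *some* nearest cluster).  The
    assignment is made only when the same *m* is supported in every run;
    ``max_dist_ratio=None`` disables the distance gate.
    """
    refs = [r for r in reference_moa if r in set(emb.runs[0].index)]
    if not refs:
        raise ValueError("empty reference set")
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    if k > len(refs):
        raise ValueError(f"k={k} exceeds the {len(refs)} reference items")

    run_scales = [_moa_scales(coords, reference_moa) for coords in emb.runs]
    out = []
    for query in query_ids:
        per_run: list[str | None] = []
        fracs: list[float] = []
        for coords, scales in zip(emb.runs, run_scales):
            moa, frac = _run_vote(
                coords, query, reference_moa, k, min_frac, max_dist_ratio, scales
            )
            per_run.append(moa)
            fracs.append(frac)
        first = per_run[0]
        if first is not None and all(m == first for m in per_run):
            out.append(ProximityAssignment(query, first, len(per_run), fracs))
        else:
            supporting = max(
                (sum(1 for m in per_run if m == cand) for cand in set(per_run) if cand),
                default=0,
            )
            out.append(ProximityAssignment(query, None, supporting, fracs))
    return out
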