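"""Feature-resampled consensus clustering over PAM (k-medoids).

Each iteration draws a random fraction of the essential-gene panel (default
0.95, without replacement), recomputes sample-sample distances on that gene
subset (default 1 - Pearson), and partitions the samples with PAM.  The
consensus matrix entry for a sample pair is the fraction of iterations in
which they co-clustered; final per-k labels come from average-linkage
hierarchical clustering of 1 - consensus.  The number of clusters is chosen
from the consensus CDF: the largest k whose relative increase in area under
the CDF is still appreciable, unless k is pinned.  With feature-only
resampling at a high fraction the base clustering is nearly deterministic,
so splitting a stable cluster of proportion q inflates the CDF area by up
to ~q^2/2 relative even when the split is spurious (< 0.2 for q <= 0.5);
the default threshold 0.2 sits above that arithmetic floor.

PAM is the classic BUILD (greedy medoid seeding) + SWAP (steepest-descent
medoid exchange) algorithm; ties break toward the lowest index so runs are
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .io_formats import ExpressionMatrix

logger = logging.getLogger("luadstrat")


@dataclass
class PamSolution:
    medoids: np.ndarray  # indices into the distance matrix
    labels: np.ndarray  # medoid index each point is assigned to, then compacted 0..k-1
    cost: float


def _assign(dist: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    sub = dist[:, medoids]  # (n, k)
    nearest = np.argmin(sub, axis=1)  # lowest index wins ties (argmin contract)
    cost = float(sub[np.arange(len(dist)), nearest].sum())
    return nearest, cost


def _build(dist: np.ndarray, k: int) -> np.ndarray:
    """BUILD seeding: first medoid minimises total distance, then greedy
    additions maximising the cost reduction."""
    totals = dist.sum(axis=1)
    medoids = [int(np.argmin(totals))]
    nearest_dist = dist[:, medoids[0]].copy()
    for _ in range(1, k):
        gains = np.maximum(nearest_dist[:, None] - dist, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        nearest_dist = np.minimum(nearest_dist, dist[:, c])
    return np.array(sorted(medoids))


def pam(
    dist: np.ndarray,
    k: int,
    seed: int = 0,
    n_starts: int | None = None,
    max_swaps: int = 1000,
) -> PamSolution:
    """Partitioning around medoids on a precomputed distance matrix.

    BUILD greedily seeds the medoids; SWAP then repeatedly applies the
    single best cost-reducing (medoid, non-medoid) exchange until none
    remains.  SWAP is a local search, so the solution is re-run from
    additional seeded random starts and the cheapest solution kept —
    by default 10 starts for small instances (n <= 50), where local optima
    hurt most and restarts are nearly free, and the single BUILD start at
    cohort scale.  Deterministic for a given matrix, seed and tie rule
    (lowest index wins).
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("dist must be a square matrix")
    if np.isnan(dist).any():
        raise ValueError("dist contains NaN")
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise ValueError("dist must be symmetric")
    if (dist < -1e-12).any():
        raise ValueError("dist must be non-negative")
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")

    if n_starts is None:
        n_starts = 10 if n <= 50 else 1
    rng = np.random.default_rng(seed)
    best: PamSolution | None = None
    for start in range(n_starts):
        if start == 0:
            medoids = _build(dist, k)
        else:
            medoids = np.sort(rng.choice(n, size=k, replace=False))
        sol = _swap_descent(dist, medoids, k, max_swaps)
        if best is None or sol.cost < best.cost - 1e-12:
            best = sol
    return best


def _swap_descent(
    dist: np.ndarray, medoids: np.ndarray, k: int, max_swaps: int
) -> PamSolution:
    """Steepest-descent SWAP phase from a given medoid set."""
    n = dist.shape[0]
    _, cost = _assign(dist, medoids)
    for _ in range(max_swaps):
        sub = dist[:, medoids]
        order = np.argsort(sub, axis=1, kind="stable")
        near_i = order[:, 0]
        d_near = sub[np.arange(n), near_i]
        d_second = sub[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)

        best_delta = -1e-12
        best_swap = None
        candidates = np.setdiff1d(np.arange(n), medoids)
        if candidates.size == 0:
            break
        d_cand = dist[:, candidates]  # (n, m)
        for mi in range(k):
            # if medoid mi is removed, points whose nearest it was fall back
            alt = np.where(near_i == mi, d_second, d_near)  # (n,)
            new_costs = np.minimum(d_cand, alt[:, None]).sum(axis=0)  # (m,)
            deltas = new_costs - cost
            j = int(np.argmin(deltas))
            if deltas[j] < best_delta:
                best_delta = float(deltas[j])
                best_swap = (mi, int(candidates[j]))
        if best_swap is None:
            break
        mi, c = best_swap
        medoids[mi] = c
        medoids = np.sort(medoids)
        _, cost = _assign(dist, medoids)
    else:  # pragma: no cover
        logger.warning("PAM swap phase hit iteration cap")

    nearest, cost = _assign(dist, medoids)
    return PamSolution(medoids=medoids, labels=nearest, cost=cost)


def pearson_distance(x: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between columns (samples) of ``x``."""
    d = 1.0 - np.corrcoef(x, rowvar=False)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def euclidean_distance(x: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist

    return squareform(pdist(x.T, metric="euclidean"))


_DISTANCES = {"one_minus_pearson": pearson_distance, "euclidean": euclidean_distance}


@dataclass
class ConsensusResult:
    consensus: dict[int, pd.DataFrame]  # k -> samples x samples matrix
    labels: dict[int, pd.Series]  # k -> per-sample labels 1..k
    cdf: dict[int, tuple[np.ndarray, np.ndarray]]  # k -> (grid, cdf values)
    area: dict[int, float]
    delta_area: dict[int, float]
    chosen_k: int
    n_iter: int
    feature_fraction: float
    seed: int


def _consensus_cdf(m: np.ndarray, grid_size: int = 101) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(m.shape[0], k=1)
    vals = m[iu]
    grid = np.linspace(0.0, 1.0, grid_size)
    cdf = np.searchsorted(np.sort(vals), grid, side="right") / vals.size
    return grid, cdf


def consensus_cluster(
    expr: ExpressionMatrix,
    panel: list[str],
    k_range: list[int] | range = range(2, 7),
    n_iter: int = 1000,
    feature_fraction: float = 0.95,
    distance: str = "one_minus_pearson",
    seed: int = 0,
    fixed_k: int | None = None,
    delta_min: float = 0.2,
    resample_samples: bool = False,
    sample_fraction: float = 0.8,
    center_genes: bool = True,
) -> ConsensusResult:
    """Consensus-cluster samples on the essential-gene panel.

    Features (genes) are resampled each iteration; optional sample
    resampling is off by default.  All samples take part in every iteration
    when only genes are resampled, so the co-clustering denominator is
    ``n_iter``.  Panel genes are median-centered across samples first
    (``center_genes``), the usual preprocessing for consensus clustering of
    expression, so that between-gene baseline differences do not drown the
    between-sample structure.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if distance not in _DISTANCES:
        raise ValueError(f"distance must be one of {sorted(_DISTANCES)}")
    sub = expr.subset_genes(panel)  # raises on absent panel genes
    x = sub.values
    if center_genes:
        x = x - np.nanmedian(x, axis=1, keepdims=True)
    n = x.shape[1]
    if n < max(k_range):
        raise ValueError(f"only {n} samples but k_range reaches {max(k_range)}")
    dist_fn = _DISTANCES[distance]
    rng = np.random.default_rng(seed)
    n_feat = int(np.ceil(feature_fraction * len(panel)))

    co = {k: np.zeros((n, n)) for k in k_range}
    denom = {k: np.zeros((n, n)) for k in k_range} if resample_samples else None
    for _ in range(n_iter):
        feat_idx = rng.choice(len(panel), size=n_feat, replace=False)
        if resample_samples:
            samp_idx = np.sort(
                rng.choice(n, size=int(np.ceil(sample_fraction * n)), replace=False)
            )
        else:
            samp_idx = np.arange(n)
        d = dist_fn(x[np.ix_(feat_idx, samp_idx)])
        for k in k_range:
            sol = pam(d, k)
            same = sol.labels[:, None] == sol.labels[None, :]
            co[k][np.ix_(samp_idx, samp_idx)] += same
            if resample_samples:
                denom[k][np.ix_(samp_idx, samp_idx)] += 1.0

    samples = sub.sample_ids
    consensus, labels, cdfs, areas = {}, {}, {}, {}
    for k in k_range:
        if resample_samples:
            with np.errstate(invalid="ignore", divide="ignore"):
                m = np.where(denom[k] > 0, co[k] / np.maximum(denom[k], 1), 0.0)
        else:
            m = co[k] / n_iter
        np.fill_diagonal(m, 1.0)
        consensus[k] = pd.DataFrame(m, index=samples, columns=samples)
        # consolidate: average-linkage hierarchical clustering of 1 - M
        condensed = squareform(1.0 - m, checks=False)
        lab = fcluster(average(condensed), t=k, criterion="maxclust")
        labels[k] = pd.Series(lab, index=samples, name="cluster")
        grid, cdf = _consensus_cdf(m)
        cdfs[k] = (grid, cdf)
        areas[k] = float(np.trapezoid(cdf, grid))

    delta = {}
    prev = None
    for k in k_range:
        if prev is None:
            delta[k] = areas[k]
        else:
            delta[k] = (areas[k] - areas[prev]) / areas[prev] if areas[prev] > 0 else 0.0
        prev = k

    if fixed_k is not None:
        chosen = int(fixed_k)
    else:
        passing = [k for k in k_range if delta[k] >= delta_min]
        chosen = max(passing) if passing else k_range[0]

    return ConsensusResult(
        consensus=consensus,
        labels=labels,
        cdf=cdfs,
        area=areas,
        delta_area=delta,
        chosen_k=chosen,
        n_iter=n_iter,
        feature_fraction=feature_fraction,
        seed=seed,
    )


def canonical_order(
    labels: pd.Series, expr: ExpressionMatrix, panel: list[str]
) -> pd.Series:
    """Renumber clusters so cluster 1 has the highest mean panel expression.

    Ties in mean expression break by cluster size (larger first).
    """
    sub = expr.subset_genes(panel)
    clusters = sorted(labels.unique())
    means, sizes = {}, {}
    for c in clusters:
        members = labels.index[labels == c]
        if len(members) == 0:
            raise ValueError(f"cluster {c} is empty")
        means[c] = float(sub.data[members].to_numpy().mean())
        sizes[c] = len(members)
    ranked = sorted(clusters, key=lambda c: (-means[c], -sizes[c], c))
    if len({round(means[c], 12) for c in clusters}) < len(clusters):
        logger.info("tie in cluster panel means; broke by cluster size")
    mapping = {old: new for new, old in enumerate(ranked, start=1)}
    return labels.map(mapping).rename("cluster")
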