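"""Genetic structure: PCA and K-means/BIC assignment of genetic groups.

Individuals are placed in PCA space computed from the dosage matrix
(missing dosages mean-imputed per site), then clustered with K-means over
a range of K using many random centroid restarts.  Model fit per K is
scored with BIC = n * log(WSS / n) + K * log(n) on the retained component
space, and the K minimising BIC is selected — the criterion family used
by the standard find.clusters-style workflow for SNP data.  Clusters are
then named by the majority of known region labels among their members,
which yields the genetic groups consumed by the demographic analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap

log = logging.getLogger(__name__)

__all__ = ["PcaResult", "ClusterSolution", "pca", "kmeans_bic", "assign_groups"]


@dataclass
class PcaResult:
    """Sample scores, explained-variance fractions, and site loadings."""

    scores: np.ndarray  # (n_samples, n_components)
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # (n_sites, n_components)
    samples: list[str]


@dataclass
class ClusterSolution:
    """Chosen K, per-sample assignments, and the BIC curve over candidates."""

    k: int
    assignments: np.ndarray  # cluster index per sample
    bic: dict[int, float]
    samples: list[str]
    seed: int


def mean_impute(calls: np.ndarray) -> np.ndarray:
    """Replace missing dosages with the per-site mean of observed calls.

    Sites with no observed calls impute to 0.
    """
    x = calls.astype(np.float64)
    miss = calls == MISSING
    x[miss] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        site_mean = np.nanmean(x, axis=0)
    site_mean = np.where(np.isnan(site_mean), 0.0, site_mean)
    return np.where(miss, site_mean[None, :], x)


def pca(gm: GenotypeMatrix, n_components: int = 10, scale: bool = False) -> PcaResult:
    """Centered principal component analysis of the dosage matrix.

    Deterministic up to component sign.  If ``n_components`` exceeds the
    matrix rank bound it is truncated with a warning.
    """
    x = mean_impute(gm.calls)
    if scale:
        sd = x.std(axis=0)
        x = x / np.where(sd == 0.0, 1.0, sd)
    max_rank = min(gm.n_samples, gm.n_sites)
    if n_components > max_rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank bound {max_rank}; truncating"
        )
        n_components = max_rank
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    return PcaResult(
        scores=scores,
        explained_variance_ratio=model.explained_variance_ratio_,
        loadings=model.components_.T,
        samples=list(gm.samples),
    )


def kmeans_bic(
    scores: np.ndarray,
    samples: list[str],
    k_range: range = range(2, 16),
    n_restarts: int = 100,
    seed: int = 0,
) -> ClusterSolution:
    """Best-of-restarts K-means over a K range, selected by BIC.

    For each K the best of ``n_restarts`` random-centroid runs (by
    within-cluster sum of squares, WSS) is kept, scored with
    BIC = n log(WSS/n) + K log(n), and the argmin-K solution returned.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise ValueError("PCA scores must be finite")
    n = scores.shape[0]
    if max(k_range) >= n:
        raise ValueError(f"k_range max {max(k_range)} must be < n_samples {n}")
    bic: dict[int, float] = {}
    best_assign: dict[int, np.ndarray] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(scores)
        wss = km.inertia_
        bic[k] = n * np.log(max(wss, 1e-300) / n) + k * np.log(n)
        best_assign[k] = labels
    k_best = min(bic, key=lambda k: (bic[k], k))
    log.info("kmeans_bic: chose K=%d (BIC %.2f)", k_best, bic[k_best])
    return ClusterSolution(
        k=k_best,
        assignments=best_assign[k_best],
        bic=bic,
        samples=list(samples),
        seed=seed,
    )


def assign_groups(
    solution: ClusterSolution,
    labels: dict[str, str] | None = None,
) -> PopulationMap:
    """Name clusters by majority region label and emit a population map.

    ``labels`` maps sample -> region label (e.g. a coarse geographic
    assignment); each cluster takes the most common label among its
    members, with ties broken lexicographically (a warning is emitted).
    Without labels, clusters are named ``K0..K{k-1}``.
    """
    entries: dict[str, tuple[str, str]] = {}
    cluster_name: dict[int, str] = {}
    for c in range(solution.k):
        members = [
            s for s, a in zip(solution.samples, solution.assignments) if a == c
        ]
        if labels is None:
            cluster_name[c] = f"K{c}"
            continue
        counts: dict[str, int] = {}
        for s in members:
            lab = labels.get(s, "OTHER")
            counts[lab] = counts.get(lab, 0) + 1
        if not counts:
            cluster_name[c] = f"K{c}"
            continue
        top = max(counts.values())
        winners = sorted(lab for lab, cnt in counts.items() if cnt == top)
        if len(winners) > 1:
            warnings.warn(
                f"cluster {c}: majority-label tie {winners}; "
                f"using {winners[0]} (lexicographic)"
            )
        cluster_name[c] = winners[0]
    for s, a in zip(solution.samples, solution.assignments):
        entries[s] = (cluster_name[int(a)], cluster_name[int(a)])
    return PopulationMap(entries)
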