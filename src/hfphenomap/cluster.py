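"""Clustering of latent coordinates and objective model selection.

Hierarchical (Ward) and k-means++ backends; the number of clusters k and the
latent dimension d are chosen jointly by maximising the gap statistic, which
compares the log within-cluster dispersion of the data to its expectation
under a structureless reference distribution (uniform on the
principal-axis-aligned bounding box).  Internal quality indices (silhouette,
Calinski-Harabasz, Davies-Bouldin) are reported for the winning model but
never used for selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .embed import Embedding, EmbeddingPipeline
from .prep import FEATURE_SCHEMA, FeatureMatrix

__all__ = [
    "ClusterSolution",
    "GapResult",
    "hclust",
    "kmeanspp",
    "within_dispersion",
    "gap_statistic",
    "gap_curve",
    "select_model",
    "cluster_profile",
    "canonicalise_by_risk",
]


@dataclass
class ClusterSolution:
    method: str  # "hierarchical" | "kmeanspp"
    k: int
    labels: np.ndarray  # ids 0..k-1, length n
    centroids: np.ndarray  # k x d latent means
    d: int
    W_k: float
    gap: float | None = None
    gap_se: float | None = None
    internal_indices: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = np.bincount(self.labels, minlength=self.k)
        if len(np.unique(self.labels)) != self.k or (counts[: self.k] == 0).any():
            raise ValueError("labels must use exactly k non-empty clusters")
        if self.W_k < 0:
            raise ValueError("W_k must be non-negative")


@dataclass
class GapResult:
    k_grid: list[int]
    d_grid: list[int]
    gap_matrix: np.ndarray  # len(d_grid) x len(k_grid)
    se_matrix: np.ndarray
    B: int
    reference_model: str
    best: tuple[int, int]  # (d*, k*)
    weak_structure: bool = False

    def best_gap(self) -> float:
        i = self.d_grid.index(self.best[0])
        j = self.k_grid.index(self.best[1])
        return float(self.gap_matrix[i, j])


def _centroids(coords: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    return np.vstack([coords[labels == r].mean(axis=0) for r in range(k)])


def within_dispersion(coords: np.ndarray, labels: np.ndarray) -> float:
    """Gap-statistic pooled within-cluster dispersion.

    W_k = sum_r (1 / (2 n_r)) * sum over ordered pairs (i, i') in cluster r of
    ||x_i - x_i'||^2, which equals the within-cluster sum of squares about the
    centroids.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    total = 0.0
    for r in np.unique(labels):
        block = coords[labels == r]
        if len(block) == 0:
            raise ValueError(f"cluster {r} is empty")
        mu = block.mean(axis=0)
        total += float(np.sum((block - mu) ** 2))
    return total


def _coords_of(emb) -> np.ndarray:
    return emb.coords if isinstance(emb, Embedding) else np.asarray(emb, float)


def hclust(emb, k: int) -> ClusterSolution:
    """Agglomerative Ward clustering on Euclidean distances, cut at k."""
    coords = _coords_of(emb)
    n = len(coords)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    Z = linkage(coords, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust") - 1
    labels = _stable_relabel(raw)
    return ClusterSolution(
        method="hierarchical",
        k=k,
        labels=labels,
        centroids=_centroids(coords, labels, k),
        d=coords.shape[1],
        W_k=within_dispersion(coords, labels),
    )


def ward_tree(coords: np.ndarray) -> np.ndarray:
    """Ward linkage matrix; cut once, reuse for every k via :func:`cut_tree_k`."""
    return linkage(np.asarray(coords, dtype=float), method="ward")


def cut_tree_k(Z: np.ndarray, k: int) -> np.ndarray:
    return _stable_relabel(fcluster(Z, t=k, criterion="maxclust") - 1)


def kmeanspp(emb, k: int, seed: int = 0, n_init: int = 10) -> ClusterSolution:
    """k-means with D^2-weighted seeding, best of ``n_init`` restarts."""
    coords = _coords_of(emb)
    if k > len(coords):
        raise ValueError(f"k={k} exceeds n={len(coords)}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                random_state=seed & 0x7FFFFFFF)
    raw = km.fit_predict(coords)
    labels = _stable_relabel(raw)
    return ClusterSolution(
        method="kmeanspp",
        k=k,
        labels=labels,
        centroids=_centroids(coords, labels, k),
        d=coords.shape[1],
        W_k=within_dispersion(coords, labels),
    )


def _stable_relabel(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first appearance (row-order stable)."""
    labels = np.asarray(labels)
    _, first = np.unique(labels, return_index=True)
    order = labels[np.sort(first)]
    mapping = {old: new for new, old in enumerate(order)}
    return np.array([mapping[x] for x in labels], dtype=int)


# ------------------------------------------------------------------ gap

def _reference_sampler(coords: np.ndarray):
    """Uniform sampler over the principal-axis-aligned bounding box."""
    coords = np.asarray(coords, dtype=float)
    mean = coords.mean(axis=0)
    Xc = coords - mean
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    proj = Xc @ Vt.T
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    if np.any(hi - lo <= 0):
        raise ValueError("degenerate (zero-volume) reference bounding box")

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        u = rng.uniform(lo, hi, size=(n, len(lo)))
        return u @ Vt + mean

    return sample


def gap_curve(
    emb,
    k_grid: Sequence[int],
    method: str = "hierarchical",
    B: int = 50,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gap(k) and its standard error over a grid of k, sharing the B
    reference datasets (and, for Ward, one linkage tree per dataset) across
    the whole grid.

    Returns ``(gaps, ses, logW)`` aligned with ``k_grid``.
    """
    coords = _coords_of(emb)
    k_grid = list(k_grid)
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    sample = _reference_sampler(coords)
    n = len(coords)

    def labels_for(data: np.ndarray) -> dict[int, np.ndarray]:
        if method == "hierarchical":
            Z = ward_tree(data)
            return {k: cut_tree_k(Z, k) for k in k_grid}
        out = {}
        for k in k_grid:
            km = KMeans(n_clusters=k, init="k-means++", n_init=5,
                        random_state=int(rng.integers(2**31 - 1)))
            out[k] = km.fit_predict(data)
        return out

    logW = np.array(
        [np.log(max(within_dispersion(coords, lab), 1e-300))
         for lab in labels_for(coords).values()]
    )
    ref_logW = np.empty((B, len(k_grid)))
    for b in range(B):
        ref = sample(rng, n)
        labs = labels_for(ref)
        for j, k in enumerate(k_grid):
            ref_logW[b, j] = np.log(max(within_dispersion(ref, labs[k]), 1e-300))
    gaps = ref_logW.mean(axis=0) - logW
    ses = ref_logW.std(axis=0, ddof=1) * np.sqrt(1.0 + 1.0 / B)
    return gaps, ses, logW


def gap_statistic(
    emb,
    cluster_fn: Callable[[np.ndarray, int], np.ndarray] | None,
    k: int,
    B: int = 50,
    seed: int = 0,
    method: str = "hierarchical",
) -> tuple[float, float]:
    """Gap statistic for a single k.

    ``cluster_fn(data, k) -> labels`` may be supplied directly; otherwise the
    named backend is used.
    """
    if B < 10:
        raise ValueError("B must be >= 10")
    if cluster_fn is not None:
        coords = _coords_of(emb)
        rng = np.random.default_rng(seed)
        sample = _reference_sampler(coords)
        logW = np.log(within_dispersion(coords, cluster_fn(coords, k)))
        ref = np.array(
            [
                np.log(within_dispersion(x, cluster_fn(x, k)))
                for x in (sample(rng, len(coords)) for _ in range(B))
            ]
        )
        return float(ref.mean() - logW), float(ref.std(ddof=1) * np.sqrt(1 + 1 / B))
    gaps, ses, _ = gap_curve(emb, [k], method=method, B=B, seed=seed)
    return float(gaps[0]), float(ses[0])


def _internal_indices(coords: np.ndarray, labels: np.ndarray) -> dict:
    if len(np.unique(labels)) < 2 or len(coords) <= len(np.unique(labels)):
        return {"silhouette": float("nan"), "calinski_harabasz": float("nan"),
                "davies_bouldin": float("nan")}
    return {
        "silhouette": float(silhouette_score(coords, labels)),
        "calinski_harabasz": float(calinski_harabasz_score(coords, labels)),
        "davies_bouldin": float(davies_bouldin_score(coords, labels)),
    }


def select_model(
    X: FeatureMatrix,
    d_grid: Sequence[int],
    k_grid: Sequence[int],
    method: str = "hierarchical",
    B: int = 50,
    seed: int = 0,
    embedding: EmbeddingPipeline | str = "vae",
) -> tuple[GapResult, ClusterSolution, EmbeddingPipeline, Embedding]:
    """Sweep (d, k), maximise the gap statistic, return the winning model.

    Ties in the argmax break toward smaller k, then smaller d (parsimony).
    Also returns the fitted embedding pipeline and Embedding at d* so callers
    can reuse them (bootstrap, LOTO, prediction).
    """
    d_grid, k_grid = list(d_grid), list(k_grid)
    if not d_grid or not k_grid:
        raise ValueError("grids must be non-empty")
    template = (
        EmbeddingPipeline(source=embedding) if isinstance(embedding, str)
        else embedding
    )
    rng = np.random.default_rng(seed)
    gap_matrix = np.empty((len(d_grid), len(k_grid)))
    se_matrix = np.empty_like(gap_matrix)
    fitted: dict[int, tuple[EmbeddingPipeline, Embedding]] = {}
    for i, d in enumerate(d_grid):
        pipe = template.clone(d=d)
        emb = pipe.fit(X, seed=int(rng.integers(2**31 - 1)))
        fitted[d] = (pipe, emb)
        gaps, ses, _ = gap_curve(
            emb, k_grid, method=method, B=B, seed=int(rng.integers(2**31 - 1))
        )
        gap_matrix[i] = gaps
        se_matrix[i] = ses

    best_d, best_k, best_gap = None, None, -np.inf
    for j, k in enumerate(k_grid):  # k-major: ties go to smaller k first
        for i, d in enumerate(d_grid):
            if gap_matrix[i, j] > best_gap:
                best_d, best_k, best_gap = d, k, float(gap_matrix[i, j])

    # weak-structure flag: max gap within 2 SE of the smallest-k gap
    j0 = int(np.argmin(k_grid))
    weak = bool(
        best_gap - float(gap_matrix[:, j0].max())
        <= 2.0 * float(se_matrix[d_grid.index(best_d), k_grid.index(best_k)])
    )

    gap_result = GapResult(
        k_grid=k_grid,
        d_grid=d_grid,
        gap_matrix=gap_matrix,
        se_matrix=se_matrix,
        B=B,
        reference_model="uniform over principal-axis-aligned bounding box",
        best=(best_d, best_k),
        weak_structure=weak,
    )
    pipe, emb = fitted[best_d]
    if method == "hierarchical":
        solution = hclust(emb, best_k)
    else:
        solution = kmeanspp(emb, best_k, seed=seed)
    solution.gap = best_gap
    solution.gap_se = float(
        se_matrix[d_grid.index(best_d), k_grid.index(best_k)]
    )
    solution.internal_indices = _internal_indices(emb.coords, solution.labels)
    return gap_result, solution, pipe, emb


# ------------------------------------------------------------------ profiles

def cluster_profile(
    table: pd.DataFrame, labels: np.ndarray, variables=None
) -> pd.DataFrame:
    """Per-cluster variable profiles for radar plots.

    Continuous variables: cluster median divided by cohort median (missing if
    the cohort median is zero).  Binary variables: cluster proportion, with
    the cohort proportion alongside for the reference ring.
    """
    from .prep import _derive_feature_columns

    df = _derive_feature_columns(table)
    schema = dict(FEATURE_SCHEMA)
    if variables is None:
        variables = list(df.columns)
    rows = []
    labels = np.asarray(labels)
    for cl in np.unique(labels):
        sub = df[labels == cl]
        for v in variables:
            kind = schema[v]
            if kind == "continuous":
                cohort_med = float(df[v].median())
                value = (
                    float(sub[v].median()) / cohort_med if cohort_med != 0
                    else np.nan
                )
                ref = 1.0 if cohort_med != 0 else np.nan
            else:
                value = float(sub[v].mean())
                ref = float(df[v].mean())
            rows.append(
                {"cluster": cl, "variable": v, "kind": kind,
                 "value": value, "cohort_reference": ref}
            )
    return pd.DataFrame(rows)


def canonicalise_by_risk(
    labels: np.ndarray, death: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Renumber clusters 0..k-1 by ascending mean mortality.

    Returns (new_labels, permutation) where ``permutation[new] = old``.
    Stabilises cluster numbering across runs so that cluster 1 is always the
    lowest-risk phenotype.
    """
    labels = np.asarray(labels)
    death = np.asarray(death, dtype=float)
    ids = np.unique(labels)
    risk = np.array([death[labels == c].mean() for c in ids])
    order = ids[np.argsort(risk, kind="stable")]
    mapping = {old: new for new, old in enumerate(order)}
    return np.array([mapping[x] for x in labels], dtype=int), order
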