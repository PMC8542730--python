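"""Cluster stability under resampling, versus a random-assignment null.

The protocol: repeatedly re-embed and re-cluster random subsets of the data
at the selected (d*, k*), score each replicate against the reference
partition with the weighted Jaccard score, and compare that score
distribution with one obtained from random labels that preserve the
reference cluster-size proportions, using the two-sample Kolmogorov-Smirnov
test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cluster import cut_tree_k, ward_tree
from .embed import EmbeddingPipeline
from .prep import FeatureMatrix

__all__ = ["StabilityResult", "weighted_jaccard", "bootstrap_stability",
           "ks_compare"]


@dataclass
class StabilityResult:
    jaccard_scores: np.ndarray
    random_scores: np.ndarray
    ks_statistic: float
    ks_p: float

    @property
    def mean(self) -> float:
        return float(self.jaccard_scores.mean())

    @property
    def sd(self) -> float:
        return float(self.jaccard_scores.std(ddof=1))

    @property
    def random_mean(self) -> float:
        return float(self.random_scores.mean())

    @property
    def random_sd(self) -> float:
        return float(self.random_scores.std(ddof=1))


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    M = np.zeros((len(ua), len(ub)), dtype=np.int64)
    np.add.at(M, (ia, ib), 1)
    return M


def weighted_jaccard(
    labels_a, labels_b, *, symmetric: bool = False
) -> float:
    """Cluster-size-weighted mean of best-match Jaccard overlaps.

    Each cluster of A is matched to the cluster of B maximising
    ``|intersection| / |union|`` of member sets; the best overlaps are then
    averaged with weights ``n_a / n``.  Invariant to label renaming; 1.0 for
    identical partitions.  ``symmetric=True`` returns the mean of the A->B
    and B->A scores.
    """
    a, b = _align(labels_a, labels_b)
    score = _wj_directed(a, b)
    if symmetric:
        score = 0.5 * (score + _wj_directed(b, a))
    return float(score)


def _align(labels_a, labels_b) -> tuple[np.ndarray, np.ndarray]:
    import pandas as pd

    if isinstance(labels_a, pd.Series) and isinstance(labels_b, pd.Series):
        common = labels_a.index.intersection(labels_b.index)
        if len(common) == 0:
            raise ValueError("label index sets are disjoint")
        return labels_a.loc[common].to_numpy(), labels_b.loc[common].to_numpy()
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError("label vectors must cover the same patients")
    if len(a) == 0:
        raise ValueError("empty label vectors")
    return a, b


def _wj_directed(a: np.ndarray, b: np.ndarray) -> float:
    M = _contingency(a, b)
    na = M.sum(axis=1)
    nb = M.sum(axis=0)
    union = na[:, None] + nb[None, :] - M
    J = M / union
    best = J.max(axis=1)
    return float(np.sum(na / na.sum() * best))


def ks_compare(obs, null) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic two-sided p."""
    obs = np.asarray(obs, dtype=float)
    null = np.asarray(null, dtype=float)
    if len(obs) == 0 or len(null) == 0:
        raise ValueError("score vectors must be non-empty")
    if np.array_equal(np.sort(obs), np.sort(null)):
        return 0.0, 1.0
    res = stats.ks_2samp(obs, null, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def bootstrap_stability(
    X: FeatureMatrix,
    reference_labels: np.ndarray,
    *,
    d: int,
    k: int,
    method: str = "hierarchical",
    embedding: EmbeddingPipeline | None = None,
    fitted_pipeline: EmbeddingPipeline | None = None,
    n_boot: int = 100,
    frac: float = 0.8,
    seed: int = 0,
    refit_embedding: bool = True,
    null: str = "proportional",
) -> StabilityResult:
    """Bootstrap the clustering at a fixed (d*, k*) and score stability.

    For each of ``n_boot`` replicates a random subset (fraction ``frac``,
    without replacement) is re-embedded (unless ``refit_embedding`` is False,
    in which case the fitted reference pipeline projects the subset) and
    re-clustered; the weighted Jaccard score against the reference labels on
    the subset is recorded.  ``random_scores`` replace the re-clustered
    labels with draws that preserve the reference cluster-size proportions
    (``null="uniform"`` draws uniformly over the k clusters instead).
    """
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must be in (0, 1]")
    reference_labels = np.asarray(reference_labels)
    n = X.n
    if len(reference_labels) != n:
        raise ValueError("reference labels must cover every row of X")
    m = max(int(round(frac * n)), 1)
    if m < k:
        raise ValueError(f"subset size {m} smaller than k={k}")
    if not refit_embedding and fitted_pipeline is None:
        raise ValueError("frozen embedding requires fitted_pipeline")
    template = embedding or EmbeddingPipeline(source="vae", d=d)

    rng = np.random.default_rng(seed)
    ref_ids, ref_counts = np.unique(reference_labels, return_counts=True)
    props = ref_counts / ref_counts.sum()

    jacc = np.empty(n_boot)
    rand = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.choice(n, size=m, replace=False)
        sub = FeatureMatrix(
            values=X.values[idx],
            schema=X.schema,
            scaling_params=X.scaling_params,
            index=X.index[idx],
        )
        if refit_embedding:
            pipe = template.clone(d=d)
            coords = pipe.fit(sub, seed=int(rng.integers(2**31 - 1))).coords
        else:
            coords = fitted_pipeline.transform(sub)
        if method == "hierarchical":
            new_labels = cut_tree_k(ward_tree(coords), k)
        else:
            from .cluster import kmeanspp

            new_labels = kmeanspp(coords, k,
                                  seed=int(rng.integers(2**31 - 1))).labels
        ref_sub = reference_labels[idx]
        jacc[b] = weighted_jaccard(new_labels, ref_sub)
        if null == "proportional":
            rand_labels = rng.choice(ref_ids, size=m, p=props)
        else:
            rand_labels = rng.choice(ref_ids, size=m)
        rand[b] = weighted_jaccard(rand_labels, ref_sub)

    D, p = ks_compare(jacc, rand)
    return StabilityResult(jaccard_scores=jacc, random_scores=rand,
                           ks_statistic=D, ks_p=p)
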