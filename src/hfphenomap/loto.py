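"""Leave-one-trial-out (LOTO) external validation.

Each pooled trial in turn is held out; the embedding and clustering are
refitted on the remaining trials at the full-data (d*, k*); agreement of the
refitted partition with the full-data partition is scored with the Adjusted
Rand Index (ARI) on the shared patients, and cluster membership for the
held-out trial is predicted by encoding its patients with the fold's
embedder and assigning each to the nearest fold centroid.  Observed mean
ARIs are compared with a label-permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import comb

from .cluster import cut_tree_k, kmeanspp, ward_tree, _centroids
from .embed import EmbeddingPipeline
from .prep import encode_features

__all__ = ["LotoResult", "adjusted_rand_index", "predict_membership",
           "leave_one_trial_out"]


@dataclass
class LotoResult:
    per_trial: pd.DataFrame  # trial_id, n, ari_iteration, ari_prediction
    mean_ari_iteration: float
    sd_ari_iteration: float
    mean_ari_prediction: float
    sd_ari_prediction: float
    permutation_p: float
    n_perm: int
    skipped_trials: list = field(default_factory=list)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected pairwise agreement between two partitions.

    ARI = (Index - E[Index]) / (MaxIndex - E[Index]) over the pair-counting
    contingency table; 1 for identical partitions, expectation 0 under random
    permutation of labels.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError("partitions must cover the same patients")
    if len(a) < 2:
        raise ValueError("ARI undefined for fewer than 2 elements")
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    M = np.zeros((len(ua), len(ub)), dtype=np.int64)
    np.add.at(M, (ia, ib), 1)
    n = len(a)
    sum_comb = comb(M, 2).sum()
    sum_a = comb(M.sum(axis=1), 2).sum()
    sum_b = comb(M.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0  # both partitions trivial (all-singletons or one block)
    return float((sum_comb - expected) / (max_index - expected))


def predict_membership(
    pipeline: EmbeddingPipeline, centroids: np.ndarray, X_new
) -> np.ndarray:
    """Assign new patients to reference clusters.

    Encodes ``X_new`` (a FeatureMatrix scaled with the reference stratum's
    scaling parameters) with the fitted embedder and assigns each point to
    the nearest centroid in latent space; equidistant ties go to the lowest
    canonical label (argmin first-occurrence rule).
    """
    coords = pipeline.transform(X_new)
    dists = cdist(coords, centroids)
    return np.argmin(dists, axis=1)


def leave_one_trial_out(
    table: pd.DataFrame,
    *,
    d: int,
    k: int,
    method: str = "hierarchical",
    embedding: EmbeddingPipeline | None = None,
    full_labels: np.ndarray | None = None,
    seed: int = 0,
    n_perm: int = 1000,
) -> LotoResult:
    """Run the LOTO protocol on a prepared single-stratum patient table.

    ``table`` must already be exclusion-filtered, complete-case and restricted
    to one rhythm stratum.  (d*, k*) are frozen at the full-data selection.
    If ``full_labels`` is None the full-data model is fitted here first.
    """
    trials = table["trial_id"].unique()
    if len(trials) < 3:
        raise ValueError("LOTO needs at least 3 trials")
    rng = np.random.default_rng(seed)
    template = embedding or EmbeddingPipeline(source="vae", d=d)

    X_full = encode_features(table)

    def cluster_coords(coords: np.ndarray) -> np.ndarray:
        if method == "hierarchical":
            return cut_tree_k(ward_tree(coords), k)
        return kmeanspp(coords, k, seed=int(rng.integers(2**31 - 1))).labels

    if full_labels is None:
        pipe = template.clone(d=d)
        emb = pipe.fit(X_full, seed=int(rng.integers(2**31 - 1)))
        full_labels = cluster_coords(emb.coords)
    full_labels = np.asarray(full_labels)
    full_series = pd.Series(full_labels, index=table.index)

    rows = []
    skipped = []
    pred_pairs: list[tuple[np.ndarray, np.ndarray]] = []
    for t in trials:
        held = table["trial_id"] == t
        train = table[~held]
        test = table[held]
        if len(test) < k or len(train) < k:
            warnings.warn(f"trial {t!r} too small for k={k}; skipped",
                          stacklevel=2)
            skipped.append(t)
            continue
        X_train = encode_features(train)
        pipe = template.clone(d=d)
        emb = pipe.fit(X_train, seed=int(rng.integers(2**31 - 1)))
        fold_labels = cluster_coords(emb.coords)
        ari_iter = adjusted_rand_index(
            fold_labels, full_series.loc[train.index].to_numpy()
        )
        # project the held-out trial with the fold's scaling and embedder
        X_test = encode_features(test, scaling_params=X_train.scaling_params)
        centroids = _centroids(emb.coords, fold_labels, k)
        pred = predict_membership(pipe, centroids, X_test)
        truth = full_series.loc[test.index].to_numpy()
        ari_pred = adjusted_rand_index(pred, truth)
        pred_pairs.append((pred, truth))
        rows.append(
            {"trial_id": t, "n": int(held.sum()),
             "ari_iteration": ari_iter, "ari_prediction": ari_pred}
        )
    if not rows:
        raise ValueError("every trial was skipped")
    per_trial = pd.DataFrame(rows)

    obs_mean = float(per_trial["ari_prediction"].mean())
    null_means = np.empty(n_perm)
    for i in range(n_perm):
        vals = [
            adjusted_rand_index(rng.permutation(pred), truth)
            for pred, truth in pred_pairs
        ]
        null_means[i] = np.mean(vals)
    permutation_p = float((1 + np.sum(null_means >= obs_mean)) / (n_perm + 1))

    return LotoResult(
        per_trial=per_trial,
        mean_ari_iteration=float(per_trial["ari_iteration"].mean()),
        sd_ari_iteration=float(per_trial["ari_iteration"].std(ddof=1)),
        mean_ari_prediction=obs_mean,
        sd_ari_prediction=float(per_trial["ari_prediction"].std(ddof=1)),
        permutation_p=permutation_p,
        n_perm=n_perm,
        skipped_trials=skipped,
    )
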