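"""Clustering backends, dispersion, gap statistic and model selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hfphenomap.cluster import (
    canonicalise_by_risk,
    cluster_profile,
    cut_tree_k,
    gap_curve,
    gap_statistic,
    hclust,
    kmeanspp,
    select_model,
    ward_tree,
    within_dispersion,
)
from hfphenomap.embed import EmbeddingPipeline
from hfphenomap.prep import FeatureMatrix, FEATURE_SCHEMA
from conftest import toy_patient_table


def three_blobs(n_per=40, sep=8.0, seed=0, d=2):
    rng = np.random.default_rng(seed)
    centers = np.zeros((3, d))
    centers[1, 0] = sep
    centers[2, 1] = sep
    pts = np.vstack([c + rng.normal(0, 1, (n_per, d)) for c in centers])
    labels = np.repeat(np.arange(3), n_per)
    return pts, labels


# ---------------------------------------------------------------- dispersion

def test_within_dispersion_hand_cases():
    # two points at distance 1 in one cluster: SSQ about centroid = 0.5,
    # equal to (1/(2*2)) * sum over ordered pairs of squared distances
    pts = np.array([[0.0, 0.0], [1.0, 0.0]])
    assert within_dispersion(pts, np.zeros(2, int)) == pytest.approx(0.5)
    # singletons -> 0
    assert within_dispersion(pts, np.array([0, 1])) == 0.0


def test_within_dispersion_matches_pairwise_bruteforce():
    rng = np.random.default_rng(3)
    pts = rng.normal(0, 1, (30, 3))
    labels = rng.integers(0, 3, 30)
    while len(np.unique(labels)) < 3:
        labels = rng.integers(0, 3, 30)
    brute = 0.0
    for r in range(3):
        block = pts[labels == r]
        acc = sum(
            np.sum((x - y) ** 2) for x in block for y in block
        )
        brute += acc / (2 * len(block))
    assert within_dispersion(pts, labels) == pytest.approx(brute, rel=1e-12)


def test_within_dispersion_label_permutation_invariant():
    rng = np.random.default_rng(1)
    pts = rng.normal(0, 1, (20, 2))
    labels = rng.integers(0, 4, 20)
    relabelled = (labels + 2) % 4
    assert within_dispersion(pts, labels) == pytest.approx(
        within_dispersion(pts, relabelled)
    )


# ----------------------------------------------------------------- backends

def test_hclust_recovers_planted_blobs_and_matches_bruteforce():
    """6-point 3-blob toy: Ward labels equal the exhaustive minimum-SSQ
    3-partition."""
    pts = np.array(
        [[0.0, 0.0], [0.3, 0.1], [10.0, 0.0], [10.2, 0.2], [0.0, 10.0],
         [0.1, 10.3]]
    )
    sol = hclust(pts, 3)
    # brute force: all assignments of 6 points to 3 non-empty groups
    best, best_cost = None, np.inf
    for assign in itertools.product(range(3), repeat=6):
        if len(set(assign)) < 3:
            continue
        cost = within_dispersion(pts, np.array(assign))
        if cost < best_cost:
            best, best_cost = np.array(assign), cost
    # compare as partitions
    from hfphenomap.loto import adjusted_rand_index

    assert adjusted_rand_index(sol.labels, best) == 1.0
    assert sol.W_k == pytest.approx(best_cost)


def test_hclust_singletons_at_k_equals_n():
    pts = np.random.default_rng(0).normal(0, 1, (7, 2))
    sol = hclust(pts, 7)
    assert sol.k == 7 and sol.W_k == 0.0
    with pytest.raises(ValueError):
        hclust(pts, 8)


def test_kmeanspp_exact_recovery_and_determinism():
    pts, labels = three_blobs(seed=2)
    s1 = kmeanspp(pts, 3, seed=5)
    s2 = kmeanspp(pts, 3, seed=5)
    np.testing.assert_array_equal(s1.labels, s2.labels)
    from hfphenomap.loto import adjusted_rand_index

    assert adjusted_rand_index(s1.labels, labels) == 1.0


def test_kmeans_objective_matches_exhaustive_search():
    """At n=12, k=3 the k-means++ solution attains the global optimum found
    by brute force over all 3^12 assignments."""
    rng = np.random.default_rng(4)
    pts = np.vstack(
        [c + rng.normal(0, 0.5, (4, 2)) for c in ([0, 0], [5, 0], [0, 5])]
    )
    sol = kmeanspp(pts, 3, seed=0, n_init=10)
    best_cost = np.inf
    for assign in itertools.product(range(3), repeat=12):
        if len(set(assign)) < 3:
            continue
        a = np.array(assign)
        cost = within_dispersion(pts, a)
        best_cost = min(best_cost, cost)
    assert sol.W_k == pytest.approx(best_cost, rel=1e-9)


def test_kmeanspp_beats_random_seeding():
    rng = np.random.default_rng(0)
    from sklearn.cluster import KMeans

    wins = 0
    trials = 20
    for i in range(trials):
        pts, _ = three_blobs(n_per=25, sep=6.0, seed=i, d=4)
        pp = KMeans(3, init="k-means++", n_init=1, random_state=i).fit(pts)
        rand = KMeans(3, init="random", n_init=1, random_state=i).fit(pts)
        wins += pp.inertia_ <= rand.inertia_ + 1e-9
    assert wins >= int(0.75 * trials)


def test_ward_W_k_nonincreasing_in_k():
    pts, _ = three_blobs(seed=6)
    Z = ward_tree(pts)
    ws = [within_dispersion(pts, cut_tree_k(Z, k)) for k in range(1, 8)]
    assert all(a >= b - 1e-9 for a, b in zip(ws, ws[1:]))


# --------------------------------------------------------------------- gap

def test_gap_near_zero_on_uniform_box():
    # elongated box so the principal axes are identifiable and the
    # reference distribution matches the data's support
    rng = np.random.default_rng(0)
    pts = rng.uniform(0, 1, (300, 2)) * np.array([3.0, 1.0])
    gap, se = gap_statistic(pts, None, k=3, B=20, seed=1)
    assert abs(gap) < 3 * se + 0.1


def test_gap_argmax_recovers_three_blobs():
    pts, _ = three_blobs(n_per=100, sep=8.0, seed=3)
    gaps, ses, _ = gap_curve(pts, range(1, 7), B=20, seed=0)
    assert list(range(1, 7))[int(np.argmax(gaps))] == 3


def test_gap_stable_when_B_doubled():
    pts, _ = three_blobs(n_per=60, seed=8)
    g1, se1 = gap_statistic(pts, None, k=3, B=25, seed=4)
    g2, _ = gap_statistic(pts, None, k=3, B=50, seed=9)
    assert abs(g1 - g2) < 3 * se1


def test_gap_rotation_invariant_with_principal_axis_reference():
    pts, _ = three_blobs(n_per=60, seed=10)
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    g1, se1 = gap_statistic(pts, None, k=3, B=40, seed=2)
    g2, se2 = gap_statistic(pts @ R.T, None, k=3, B=40, seed=2)
    assert abs(g1 - g2) < 3 * max(se1, se2)


def test_gap_degenerate_box_rejected():
    pts = np.zeros((20, 2))
    with pytest.raises(ValueError):
        gap_statistic(pts, None, k=2, B=10, seed=0)


# ------------------------------------------------------------ select_model

def _matrix_from_coords(pts):
    # embed raw coordinates as a continuous-only FeatureMatrix
    schema = tuple((f"v{i}", "continuous") for i in range(pts.shape[1]))
    return FeatureMatrix(pts, schema, {}, pd.RangeIndex(len(pts)))


def test_select_model_grid_of_one_cell():
    pts, _ = three_blobs(n_per=30, seed=5, d=3)
    X = _matrix_from_coords(pts)
    gap, sol, pipe, emb = select_model(
        X, [2], [3], method="hierarchical", B=15, seed=0, embedding="pca"
    )
    assert gap.best == (2, 3)
    assert sol.k == 3 and sol.d == 2
    assert set(sol.internal_indices) == {
        "silhouette", "calinski_harabasz", "davies_bouldin"
    }


def test_select_model_flags_weak_structure_on_single_cloud():
    rng = np.random.default_rng(2)
    X = _matrix_from_coords(rng.normal(0, 1, (300, 5)))
    gap, sol, _, _ = select_model(
        X, [2, 3], [2, 3, 4], method="hierarchical", B=15, seed=1,
        embedding="pca",
    )
    assert gap.weak_structure


def test_select_model_deterministic_under_fixed_seed():
    pts, _ = three_blobs(n_per=25, seed=7, d=4)
    X = _matrix_from_coords(pts)
    out1 = select_model(X, [2, 3], [2, 3, 4], B=12, seed=3, embedding="pca")
    out2 = select_model(X, [2, 3], [2, 3, 4], B=12, seed=3, embedding="pca")
    assert out1[0].best == out2[0].best
    np.testing.assert_array_equal(out1[1].labels, out2[1].labels)
    np.testing.assert_allclose(out1[0].gap_matrix, out2[0].gap_matrix)


# ----------------------------------------------------------------- profiles

def test_cluster_profile_ratios_and_proportions():
    df = toy_patient_table(9, seed=11)
    df["age"] = [60.0, 70, 80, 65, 65, 65, 65, 65, 65]
    labels = np.array([0, 0, 0, 1, 1, 1, 1, 1, 1])
    prof = cluster_profile(df, labels, variables=["age", "prior_mi"])
    row = prof[(prof.cluster == 0) & (prof.variable == "age")].iloc[0]
    assert row["value"] == pytest.approx(70.0 / 65.0)
    p1 = prof[(prof.cluster == 1) & (prof.variable == "prior_mi")].iloc[0]
    assert p1["value"] == pytest.approx(df["prior_mi"][labels == 1].mean())
    assert p1["cohort_reference"] == pytest.approx(df["prior_mi"].mean())


def test_cluster_profile_identity_cluster_is_all_ones():
    df = toy_patient_table(8, seed=12)
    prof = cluster_profile(df, np.zeros(8, int))
    cont = prof[prof.kind == "continuous"]
    assert np.allclose(cont["value"], 1.0)
    binr = prof[prof.kind == "binary"]
    assert np.allclose(binr["value"], binr["cohort_reference"])


def test_canonicalise_by_risk_orders_by_mortality():
    labels = np.array([0, 0, 1, 1, 2, 2])
    death = np.array([1, 1, 0, 0, 1, 0])
    new, order = canonicalise_by_risk(labels, death)
    # cluster 1 (0% death) -> 0, cluster 2 (50%) -> 1, cluster 0 (100%) -> 2
    np.testing.assert_array_equal(new, [2, 2, 0, 0, 1, 1])
    np.testing.assert_array_equal(order, [1, 2, 0])
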