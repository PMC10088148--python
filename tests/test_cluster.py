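"""Subgroup discovery: block recovery, CV hygiene, survival separation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from mdswgs.cluster import (
    FeatureMatrix,
    SupervisedConfig,
    build_recurrent_cyto_features,
    evaluate_subgroups,
    split_common_rare,
    supervised_cluster_cv,
    unsupervised_subgroups,
)
from mdswgs.simulate import RECURRENT_GENES, SimulationConfig, simulate_cohort

from conftest import truth_matrix

FOUR_BLOCKS = [
    (("DNMT3A", "STAG2", "ASXL1"), 0.30, 0.20),
    (("TET2",), 0.25, 0.00),
    (("RUNX1",), 0.25, 0.25),
    (("TP53", "del5q"), 0.20, 0.90),
]


def four_block_features(seed=0, n=400):
    cfg = SimulationConfig(
        n_patients=n, n_genes=30, n_windows=5, carrier_freq=0.05,
        subgroup_spec=FOUR_BLOCKS, signature_noise=0.05, seed=seed,
    )
    clinical, _, outcomes, truth = simulate_cohort(cfg)
    fm = build_recurrent_cyto_features(truth_matrix(truth), clinical, RECURRENT_GENES)
    return fm, np.array(truth["subgroup"]), outcomes


def test_four_signature_blocks_recovered():
    """Silhouette picks k=4 and the partition matches the planted blocks."""
    fm, truth_sub, _ = four_block_features(seed=0)
    frame, k, sil = unsupervised_subgroups(fm, range(2, 7), seed=0)
    assert k == 4
    assert adjusted_rand_score(truth_sub, frame["subgroup_label"]) >= 0.9


def test_two_perfect_blocks_ari_one():
    vals = np.zeros((40, 4), dtype=np.int8)
    vals[:20, :2] = 1
    vals[20:, 2:] = 1
    fm = FeatureMatrix([f"P{i}" for i in range(40)], list("abcd"), vals, "recurrent_cyto")
    frame, k, _ = unsupervised_subgroups(fm, [2], seed=0)
    truth = np.array([0] * 20 + [1] * 20)
    assert adjusted_rand_score(truth, frame["subgroup_label"]) == 1.0


def test_patient_order_permutation_preserves_partition():
    fm, _, _ = four_block_features(seed=1)
    frame, _, _ = unsupervised_subgroups(fm, [4], seed=0)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(fm.patients))
    fm_perm = FeatureMatrix(
        [fm.patients[i] for i in perm], fm.feature_names, fm.values[perm], fm.feature_class
    )
    frame_perm, _, _ = unsupervised_subgroups(fm_perm, [4], seed=0)
    merged = frame.merge(frame_perm, on="patient_id", suffixes=("_a", "_b"))
    assert adjusted_rand_score(merged["subgroup_label_a"], merged["subgroup_label_b"]) == 1.0


def test_degenerate_matrix_rejected():
    vals = np.ones((30, 3), dtype=np.int8)
    fm = FeatureMatrix([f"P{i}" for i in range(30)], list("abc"), vals, "recurrent_cyto")
    with pytest.raises(ValueError, match="identical"):
        unsupervised_subgroups(fm, [2], seed=0)


def test_split_common_rare_partition_and_monotonicity():
    rng = np.random.default_rng(2)
    freqs = [0.009, 0.02, 0.3, 0.005]
    vals = np.column_stack([rng.binomial(1, f, 1000) for f in freqs]).astype(np.int8)
    fm = FeatureMatrix([f"P{i}" for i in range(1000)], list("abcd"), vals, "common")
    common, rare = split_common_rare(fm, 0.01)
    assert set(common.feature_names) | set(rare.feature_names) == set("abcd")
    assert set(common.feature_names) & set(rare.feature_names) == set()
    assert "a" in rare.feature_names  # 0.009 < 0.01 -> rare
    # raising the threshold can only move features common -> rare
    common_hi, _ = split_common_rare(fm, 0.05)
    assert set(common_hi.feature_names) <= set(common.feature_names)
    with pytest.raises(ValueError, match="freq_threshold"):
        split_common_rare(fm, 0.7)


@pytest.fixture(scope="module")
def supervised_planted():
    """Two survival subgroups carried by 10 of 300 features."""
    rng = np.random.default_rng(12)
    n, m, k_signal = 400, 300, 10
    group = rng.binomial(1, 0.5, n)
    X = rng.binomial(1, 0.1, (n, m)).astype(np.int8)
    for j in range(k_signal):
        X[:, j] = np.where(rng.random(n) < 0.9, group, 1 - group)
    t = rng.exponential(np.exp(-1.2 * group))
    e = rng.random(n) < 0.85
    fm = FeatureMatrix([f"P{i}" for i in range(n)], [f"F{j}" for j in range(m)], X, "common")
    return fm, t, e, group


def test_supervised_cv_recovers_planted_features(supervised_planted):
    fm, t, e, group = supervised_planted
    cfg = SupervisedConfig(k_clusters=2, n_top_features=10, n_folds=5, seed=3)
    frame, diag = supervised_cluster_cv(fm, t, e, cfg)
    assert diag["oof_logrank_p"] < 0.01
    planted = {f"F{j}" for j in range(10)}
    # planted features dominate selection in every fold
    for fold in diag["folds"]:
        assert len(planted & set(fold["selected_features"])) >= 7
    # out-of-fold labels recover the planted grouping
    assert adjusted_rand_score(group, frame["subgroup_label"]) > 0.5


def test_supervised_cv_no_leakage_bookkeeping(supervised_planted):
    fm, t, e, _ = supervised_planted
    cfg = SupervisedConfig(k_clusters=2, n_top_features=5, n_folds=4, seed=0)
    frame, diag = supervised_cluster_cv(fm, t, e, cfg)
    # every patient labelled exactly once, with its fold recorded
    assert sorted(frame["patient_id"]) == sorted(fm.patients)
    assert frame["patient_id"].is_unique
    assert set(frame["fold_id"]) == set(range(4))
    assert set(frame["subgroup_label"]) <= {1, 2}


def test_leave_one_out_boundary_runs():
    rng = np.random.default_rng(1)
    n = 12
    X = rng.binomial(1, 0.4, (n, 6)).astype(np.int8)
    fm = FeatureMatrix([f"P{i}" for i in range(n)], [f"F{j}" for j in range(6)], X, "common")
    t = rng.exponential(1, n)
    e = np.ones(n, bool)
    cfg = SupervisedConfig(k_clusters=2, n_top_features=3, n_folds=n, seed=0)
    frame, _ = supervised_cluster_cv(fm, t, e, cfg)
    assert len(frame) == n


def test_all_folds_skipped_is_an_error():
    rng = np.random.default_rng(1)
    n = 20
    X = rng.binomial(1, 0.4, (n, 4)).astype(np.int8)
    fm = FeatureMatrix([f"P{i}" for i in range(n)], list("abcd"), X, "common")
    with pytest.raises(ValueError, match="folds"):
        supervised_cluster_cv(
            fm, rng.exponential(1, n), np.zeros(n, bool),
            SupervisedConfig(k_clusters=2, n_top_features=2, n_folds=2, seed=0),
        )


def test_identical_subgroups_show_no_separation():
    rng = np.random.default_rng(6)
    n = 600
    labels = np.repeat([1, 2], n // 2)
    t = rng.exponential(1.0, n)
    e = rng.random(n) < 0.8
    frame = pd.DataFrame({"patient_id": range(n), "subgroup_label": labels})
    rep = evaluate_subgroups(frame, t, e)
    row = rep["cox_subgroups"].iloc[0]
    assert abs(np.log(row["hr"])) < 3 * (np.log(row["ci_high"]) - np.log(row["hr"])) / 1.96
    assert rep["logrank_p"] > 0.001


def test_planted_subgroup_hazard_recovered():
    rng = np.random.default_rng(13)
    n = 800
    labels = np.repeat([1, 2], n // 2)
    t = rng.exponential(np.exp(-1.0 * (labels == 2)))
    e = np.ones(n, bool)
    frame = pd.DataFrame({"patient_id": range(n), "subgroup_label": labels})
    rep = evaluate_subgroups(frame, t, e, reference_label=1)
    row = rep["cox_subgroups"].set_index("subgroup").loc[2]
    se = (np.log(row["ci_high"]) - np.log(row["hr"])) / 1.96
    assert abs(np.log(row["hr"]) - 1.0) < 3 * se
    assert rep["logrank_p"] < 1e-10


def test_km_without_censoring_equals_empirical_survival():
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    e = np.ones(6, bool)
    labels = np.array([1, 1, 1, 2, 2, 2])
    frame = pd.DataFrame({"patient_id": range(6), "subgroup_label": labels})
    rep = evaluate_subgroups(frame, t, e)
    tab = rep["km_tables"][1].set_index("time")["survival"]
    np.testing.assert_allclose(tab.loc[[1.0, 2.0, 3.0]], [2 / 3, 1 / 3, 0.0])


def test_missing_reference_label_is_an_error():
    t = np.arange(1.0, 7.0)
    e = np.ones(6, bool)
    frame = pd.DataFrame({"patient_id": range(6), "subgroup_label": [1, 1, 1, 2, 2, 2]})
    with pytest.raises(ValueError, match="reference"):
        evaluate_subgroups(frame, t, e, reference_label=9)
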