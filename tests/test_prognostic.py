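"""Random-survival-forest ladder: OOB honesty, VIMP semantics, ladder structure."""

import numpy as np
import pandas as pd
import pytest

from mdswgs.metrics import concordance_index
from mdswgs.prognostic import (
    RSFConfig,
    build_ladder_features,
    evaluate_ladder,
    fit_rsf,
    oob_risk,
    permutation_importance,
)

FAST = RSFConfig(n_trees=100, n_bootstrap_ci=50, n_vimp_repeats=3, seed=0)


def toy_features(n, rng, signal=True):
    x = rng.normal(size=n)
    t = rng.exponential(np.exp(-1.5 * x)) if signal else rng.exponential(1.0, n)
    feats = pd.DataFrame({"x": x, "noise": rng.normal(size=n)})
    return feats, t, np.ones(n, bool)


def test_same_seed_reproduces_predictions():
    rng = np.random.default_rng(0)
    feats, t, e = toy_features(80, rng)
    f1 = fit_rsf(feats, t, e, FAST)
    f2 = fit_rsf(feats, t, e, FAST)
    X = feats.to_numpy(float)
    np.testing.assert_array_equal(f1.predict(X), f2.predict(X))
    np.testing.assert_array_equal(oob_risk(f1, X), oob_risk(f2, X))


def test_zero_events_rejected_and_constant_feature_warned():
    rng = np.random.default_rng(1)
    feats, t, _ = toy_features(40, rng)
    with pytest.raises(ValueError, match="zero events"):
        fit_rsf(feats, t, np.zeros(40, bool), FAST)
    feats["const"] = 1.0
    with pytest.warns(UserWarning, match="constant"):
        fit_rsf(feats, t, np.ones(40, bool), FAST)


def test_perfect_predictor_oob_concordance_near_one():
    rng = np.random.default_rng(2)
    n = 150
    x = rng.normal(size=n)
    t = np.exp(-x) + 0.001 * rng.random(n)  # feature orders event times exactly
    feats = pd.DataFrame({"x": x})
    cfg = RSFConfig(n_trees=300, min_node_size=3, seed=0)
    forest = fit_rsf(feats, t, np.ones(n, bool), cfg)
    c = concordance_index(oob_risk(forest, feats.to_numpy(float)), t, np.ones(n, bool))
    assert c > 0.95


def test_pure_noise_oob_concordance_near_half():
    rng = np.random.default_rng(3)
    n = 200
    feats = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
    t = rng.exponential(1.0, n)
    forest = fit_rsf(feats, t, np.ones(n, bool), FAST)
    c = concordance_index(oob_risk(forest, feats.to_numpy(float)), t, np.ones(n, bool))
    assert abs(c - 0.5) < 0.08


def test_vimp_ranks_sole_predictor_first_and_constant_exactly_zero():
    rng = np.random.default_rng(4)
    n = 150
    x = rng.normal(size=n)
    feats = pd.DataFrame({"signal": x, "noise": rng.normal(size=n), "const": np.ones(n)})
    t = rng.exponential(np.exp(-1.5 * x))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        forest = fit_rsf(feats, t, np.ones(n, bool), FAST)
    vimp = permutation_importance(forest, feats, t, np.ones(n, bool), seed=0, n_repeats=3)
    assert vimp["const"] == 0.0
    assert vimp["signal"] == max(vimp.values())
    assert vimp["signal"] > 0.1


def test_ladder_feature_sets_are_nested(base_cohort):
    clin = base_cohort["clinical"]
    rng = np.random.default_rng(0)
    n = len(clin)
    frames = build_ladder_features(
        clin,
        candidate_counts=rng.integers(0, 4, n),
        supervised_labels=rng.integers(1, 4, n),
        unsupervised_labels=rng.integers(1, 5, n),
    )
    base, clinical, genomic, full = (
        frames["base"], frames["clinical"], frames["genomic"], frames["full"]
    )
    assert set(base.columns) <= set(clinical.columns) <= set(full.columns)
    assert set(genomic.columns) <= set(full.columns)
    assert set(full.columns) == set(clinical.columns) | set(genomic.columns)
    outcome_like = {"os_time", "os_event", "dfs_time", "dfs_event", "first_event_code"}
    assert not (set(full.columns) & outcome_like)


@pytest.fixture(scope="module")
def ladder_eval(base_cohort):
    clin = base_cohort["clinical"]
    truth = base_cohort["truth"]
    m = base_cohort["matrix"]
    counts = m.values[:, [m.region_ids.index("TP53")]].sum(axis=1)
    frames = build_ladder_features(
        clin, counts, np.array(truth["subgroup"]) + 1, np.array(truth["subgroup"]) + 1
    )
    cfg = RSFConfig(n_trees=80, n_bootstrap_ci=50, n_outer_folds=3, seed=1)
    table, details = evaluate_ladder(
        clin, base_cohort["outcomes"], frames,
        endpoints=("os", "relapse"), strata=("all", "myeloablative"), config=cfg,
    )
    return table, details


def test_ladder_grid_structure(ladder_eval):
    table, details = ladder_eval
    assert set(table["model"]) == {"base", "clinical", "genomic", "full"}
    assert set(table["endpoint"]) == {"os", "relapse"}
    assert set(table["stratum"]) == {"all", "myeloablative"}
    ok = table[table["note"] == ""]
    assert ((ok["ci_low"] <= ok["c_index"]) & (ok["c_index"] <= ok["ci_high"])).all()
    assert ok["c_index"].between(0, 1).all()
    assert ok["integrated_brier"].between(0, 1).all()
    assert ("full", "os") in details["vimp"]


def test_missing_regimen_column_omits_strata(base_cohort):
    clin = base_cohort["clinical"].drop(columns=["conditioning_regimen"])
    frames = build_ladder_features(clin)
    cfg = RSFConfig(n_trees=40, n_bootstrap_ci=20, seed=0)
    table, _ = evaluate_ladder(
        clin, base_cohort["outcomes"], frames, endpoints=("os",),
        strata=("all", "myeloablative"), config=cfg, compute_vimp=(),
    )
    assert set(table["stratum"]) == {"all"}


def test_stratum_without_events_reported_not_evaluable(base_cohort):
    clin = base_cohort["clinical"]
    outcomes = base_cohort["outcomes"].copy()
    mask = (clin["conditioning_regimen"] == "myeloablative").to_numpy()
    outcomes.loc[mask, "os_event"] = 0
    frames = build_ladder_features(clin)
    cfg = RSFConfig(n_trees=40, n_bootstrap_ci=20, seed=0)
    table, _ = evaluate_ladder(
        clin, outcomes, frames, endpoints=("os",),
        strata=("myeloablative",), config=cfg, compute_vimp=(),
    )
    assert (table["note"] == "no events in stratum").all()
    assert table["c_index"].isna().all()
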