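"""Random-survival-forest prognostic model ladder: base / clinical / genomic / full.

The ladder compares nested feature sets for predicting post-transplant
outcomes:

* **base** — IPSS-R risk category alone;
* **clinical** — base + MDS type, hypomethylating-agent exposure,
  chemotherapy exposure;
* **genomic** — per-patient count of carried association-candidate regions
  ("mutational number") + supervised and unsupervised genomic subgroup
  labels;
* **full** — clinical + genomic.

Forests come from ``scikit-survival`` (log-rank splitting on bootstrap
samples). Honest predictions are produced either by outer k-fold
cross-validation (default; supports both C-index and Brier uniformly) or by
out-of-bag aggregation; in-bag predictions are never reported. The C-index,
Brier score and permutation importance are this package's own
implementations (:mod:`mdswgs.metrics`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble._forest import _generate_unsampled_indices
from sksurv.ensemble import RandomSurvivalForest
from sksurv.util import Surv

from .metrics import brier_score, concordance_index, integrated_brier
from .scan import IPSS_R_ORDER

__all__ = [
    "RSFConfig",
    "MODEL_LADDER",
    "fit_rsf",
    "oob_risk",
    "permutation_importance",
    "build_ladder_features",
    "evaluate_ladder",
]

logger = logging.getLogger(__name__)

MODEL_LADDER = ("base", "clinical", "genomic", "full")

ENDPOINTS = {
    # endpoint -> (time column, event extractor) on the outcomes table;
    # relapse/TRM are single-event endpoints with the competing cause censored
    "os": ("os_time", lambda o: o["os_event"].to_numpy(dtype=bool)),
    "dfs": ("dfs_time", lambda o: o["dfs_event"].to_numpy(dtype=bool)),
    "relapse": ("dfs_time", lambda o: (o["first_event_code"] == 1).to_numpy()),
    "trm": ("dfs_time", lambda o: (o["first_event_code"] == 2).to_numpy()),
}


@dataclass
class RSFConfig:
    n_trees: int = 500
    min_node_size: int = 10  # min samples per terminal node (proxy for min events)
    max_features: str = "sqrt"
    evaluation: str = "cv"  # cv | oob
    n_outer_folds: int = 3
    n_bootstrap_ci: int = 1000
    n_vimp_repeats: int = 5
    brier_quantiles: tuple = (0.1, 0.9)
    n_brier_times: int = 15
    seed: int = 0

    def validate(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.evaluation not in ("cv", "oob"):
            raise ValueError(f"evaluation must be 'cv' or 'oob', got {self.evaluation!r}")
        if self.n_outer_folds < 2:
            raise ValueError("n_outer_folds must be >= 2")
        return self


def fit_rsf(features: pd.DataFrame, time, event, config: RSFConfig) -> RandomSurvivalForest:
    """Grow a survival forest (log-rank splits, bootstrap resampling).

    ``features`` must already be numerically encoded. Constant features are
    retained with a warning — the forest simply never splits on them.
    """
    config.validate()
    event = np.asarray(event, dtype=bool)
    if not event.any():
        raise ValueError("cannot fit a survival forest with zero events")
    X = features.to_numpy(dtype=np.float64)
    const = [c for c, v in zip(features.columns, X.std(axis=0) == 0) if v]
    if const:
        warnings.warn(f"constant features retained: {const}", stacklevel=2)
    y = Surv.from_arrays(event, np.asarray(time, dtype=float))
    forest = RandomSurvivalForest(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        min_samples_leaf=config.min_node_size,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    forest.feature_names_ = list(features.columns)
    return forest


def oob_risk(forest: RandomSurvivalForest, X) -> np.ndarray:
    """Per-patient out-of-bag ensemble risk (mean tree mortality).

    For each patient, only trees whose bootstrap sample excluded the patient
    contribute; this reproduces the bootstrap draw of each fitted tree from
    its stored random state.
    """
    X = np.asarray(X, dtype=np.float32)
    n = X.shape[0]
    total = np.zeros(n)
    count = np.zeros(n)
    for tree in forest.estimators_:
        unsampled = _generate_unsampled_indices(tree.random_state, n, n, None)
        if len(unsampled) == 0:
            continue
        total[unsampled] += tree.predict(X[unsampled])
        count[unsampled] += 1
    if (count == 0).any():
        logger.warning("%d patients never out-of-bag; risk from full forest", (count == 0).sum())
        full = forest.predict(X)
        total[count == 0] = full[count == 0]
        count[count == 0] = 1
    return total / count


def permutation_importance(forest, features: pd.DataFrame, time, event, seed: int = 0,
                           n_repeats: int = 5) -> dict:
    """Permutation VIMP: OOB C-index drop after shuffling each feature.

    Averaged over ``n_repeats`` independent permutations; a feature the
    forest never uses (e.g. a constant) scores exactly 0 because its
    permutation cannot change any prediction.
    """
    X = features.to_numpy(dtype=np.float64)
    event = np.asarray(event, dtype=bool)
    base_c = concordance_index(oob_risk(forest, X), time, event)
    rng = np.random.default_rng(seed)
    vimp = {}
    for j, name in enumerate(features.columns):
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            if np.array_equal(Xp[:, j], X[:, j]):
                drops.append(0.0)
                continue
            drops.append(base_c - concordance_index(oob_risk(forest, Xp), time, event))
        vimp[name] = float(np.mean(drops))
    return vimp


def build_ladder_features(
    clinical: pd.DataFrame,
    candidate_counts: np.ndarray | None = None,
    supervised_labels: np.ndarray | None = None,
    unsupervised_labels: np.ndarray | None = None,
) -> dict:
    """Numerically encoded feature frames for each ladder model.

    ``candidate_counts`` is the per-patient number of carried association
    candidate regions; subgroup labels are one-hot encoded. Models whose
    genomic inputs are missing are omitted from the result.
    """
    base = pd.DataFrame(
        {"ipss_r_risk": clinical["ipss_r_risk"].map(
            {lvl: i for i, lvl in enumerate(IPSS_R_ORDER)}
        ).to_numpy(dtype=float)}
    )
    clin = base.copy()
    for lvl in sorted(clinical["mds_type"].unique())[1:]:
        clin[f"mds_type[{lvl}]"] = (clinical["mds_type"] == lvl).to_numpy(dtype=float)
    clin["hma_exposure"] = clinical["hma_exposure"].to_numpy(dtype=float)
    clin["chemo_exposure"] = clinical["chemo_exposure"].to_numpy(dtype=float)

    frames = {"base": base, "clinical": clin}
    genomic_cols = {}
    if candidate_counts is not None:
        genomic_cols["mutational_number"] = np.asarray(candidate_counts, dtype=float)
    for prefix, labels in (("supervised", supervised_labels), ("unsupervised", unsupervised_labels)):
        if labels is None:
            continue
        labels = np.asarray(labels)
        for u in np.unique(labels)[1:]:
            genomic_cols[f"{prefix}_subgroup[{u}]"] = (labels == u).astype(float)
    if genomic_cols:
        genomic = pd.DataFrame(genomic_cols)
        frames["genomic"] = genomic
        frames["full"] = pd.concat([clin, genomic], axis=1)
    return frames


def _cv_predictions(features: pd.DataFrame, time, event, config: RSFConfig):
    """Held-out risk scores and survival curves from outer k-fold CV."""
    n = len(features)
    rng = np.random.default_rng(config.seed)
    folds = np.array_split(rng.permutation(n), config.n_outer_folds)
    risk = np.full(n, np.nan)
    eval_times = _brier_grid(time, event, config)
    surv = np.full((n, len(eval_times)), np.nan)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    for fold_id, test_idx in enumerate(folds):
        train = np.ones(n, dtype=bool)
        train[test_idx] = False
        if not event[train].any():
            raise ValueError(f"outer fold {fold_id}: no training events")
        sub = RSFConfig(**{**vars(config), "seed": config.seed + 1000 + fold_id})
        forest = fit_rsf(features.iloc[train], time[train], event[train], sub)
        Xte = features.iloc[test_idx].to_numpy(dtype=np.float64)
        risk[test_idx] = forest.predict(Xte)
        sf = forest.predict_survival_function(Xte, return_array=True)
        grid = forest.unique_times_
        idx = np.clip(np.searchsorted(grid, eval_times, side="right") - 1, 0, len(grid) - 1)
        step = sf[:, idx]
        step[:, eval_times < grid[0]] = 1.0
        surv[test_idx] = step
    return risk, surv, eval_times


def _brier_grid(time, event, config: RSFConfig):
    t = np.asarray(time, dtype=float)[np.asarray(event, dtype=bool)]
    if len(t) == 0:
        t = np.asarray(time, dtype=float)
    lo, hi = np.quantile(t, config.brier_quantiles)
    hi = min(hi, float(np.asarray(time).max()))
    return np.linspace(lo, hi, config.n_brier_times)


def evaluate_ladder(
    clinical: pd.DataFrame,
    outcomes: pd.DataFrame,
    ladder_features: dict,
    endpoints=("os", "dfs", "relapse", "trm"),
    strata=("all",),
    config: RSFConfig | None = None,
    compute_vimp: tuple = ("full",),
) -> tuple[pd.DataFrame, dict]:
    """Fit and evaluate every ladder model for every endpoint and stratum.

    Relapse and TRM are evaluated as single-event endpoints with the
    competing first event censored at its occurrence time. Strata beyond
    ``"all"`` select conditioning-regimen subsets of the *held-out*
    predictions (the models are fit on the whole cohort). Returns a tidy
    evaluation table plus a details dict with Brier curves and permutation
    importances.
    """
    config = (config or RSFConfig()).validate()
    rows = []
    details = {"brier_curves": {}, "vimp": {}}
    regimen = clinical["conditioning_regimen"] if "conditioning_regimen" in clinical else None
    for endpoint in endpoints:
        if endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {endpoint!r}")
        tcol, getev = ENDPOINTS[endpoint]
        time = outcomes[tcol].to_numpy(dtype=float)
        event = getev(outcomes).astype(bool)
        for model_name in MODEL_LADDER:
            if model_name not in ladder_features:
                continue
            feats = ladder_features[model_name]
            if config.evaluation == "cv":
                risk, surv, eval_times = _cv_predictions(feats, time, event, config)
            else:
                forest = fit_rsf(feats, time, event, config)
                risk = oob_risk(forest, feats.to_numpy(dtype=np.float64))
                surv, eval_times = None, None
            for stratum in strata:
                if stratum == "all":
                    mask = np.ones(len(time), dtype=bool)
                else:
                    if regimen is None:
                        continue  # no regimen column: stratum rows omitted
                    mask = (regimen == stratum).to_numpy()
                if not event[mask].any():
                    rows.append(
                        {
                            "model": model_name, "endpoint": endpoint, "stratum": stratum,
                            "c_index": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                            "integrated_brier": np.nan, "n": int(mask.sum()),
                            "note": "no events in stratum",
                        }
                    )
                    continue
                c, (lo, hi) = concordance_index(
                    risk[mask], time[mask], event[mask],
                    n_bootstrap=config.n_bootstrap_ci, seed=config.seed,
                )
                ib = np.nan
                if surv is not None:
                    tmask = eval_times <= time[mask].max()
                    bs = brier_score(surv[mask][:, tmask], time[mask], event[mask],
                                     eval_times[tmask])
                    ib = integrated_brier(bs, eval_times[tmask])
                    details["brier_curves"][(model_name, endpoint, stratum)] = list(
                        zip(eval_times[tmask].tolist(), bs.tolist())
                    )
                rows.append(
                    {
                        "model": model_name, "endpoint": endpoint, "stratum": stratum,
                        "c_index": c, "ci_low": lo, "ci_high": hi,
                        "integrated_brier": ib, "n": int(mask.sum()), "note": "",
                    }
                )
            if model_name in compute_vimp and endpoint == "os":
                forest = fit_rsf(feats, time, event, config)
                details["vimp"][(model_name, endpoint)] = permutation_importance(
                    forest, feats, time, event, seed=config.seed,
                    n_repeats=config.n_vimp_repeats,
                )
    return pd.DataFrame(rows), details
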