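"""Genomic subgrouping: unsupervised K-means and outcome-guided supervised clustering.

Two complementary routes to molecular subgroups of an MDS transplant cohort:

* **Unsupervised** — K-means on the binary matrix of recurrent driver-gene
  mutations and cytogenetic flags, with the cluster count chosen by mean
  silhouette. This recovers signature blocks such as the classic
  DNMT3A/STAG2/ASXL1, TET2, RUNX1 and TP53+del5q groupings.
* **Supervised** — survival-guided feature selection followed by clustering,
  run under k-fold cross-validation: within each fold, features are scored
  on the *training split only* by univariate Cox association, the top
  features are K-means clustered, and held-out patients are assigned to the
  nearest centroid. Out-of-fold labels are the deliverable, so the survival
  separation they show is honest (the no-leakage contract).

Cluster labels are relabelled 1..k by increasing crude training hazard so
label 1 is always the most favourable group and labels are comparable across
folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .coxph import cox_score_test, fit_cox

__all__ = [
    "FeatureMatrix",
    "SupervisedConfig",
    "build_recurrent_cyto_features",
    "split_common_rare",
    "unsupervised_subgroups",
    "supervised_cluster_cv",
    "evaluate_subgroups",
]

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Binary patients x features matrix for clustering."""

    patients: list
    feature_names: list
    values: np.ndarray = field(repr=False)
    feature_class: str = "common"  # recurrent_cyto | common | rare

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.patients), len(self.feature_names)):
            raise ValueError("feature matrix shape mismatch")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("feature values must be binary")


@dataclass
class SupervisedConfig:
    k_clusters: int = 3
    n_top_features: int = 50
    n_folds: int = 5
    endpoint: str = "os"
    n_restarts: int = 20
    seed: int = 0

    def validate(self):
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.k_clusters < 2:
            raise ValueError(f"k_clusters must be >= 2, got {self.k_clusters}")
        if self.n_top_features < 1:
            raise ValueError("n_top_features must be >= 1")
        return self


def build_recurrent_cyto_features(carrier_matrix, clinical, recurrent_genes, cyto_flags=("del5q",)):
    """Assemble the recurrent-mutation + cytogenetics feature matrix.

    Gene columns come from the carrier matrix; cytogenetic abnormality flags
    (e.g. del5q) come from the clinical table, where they are recorded as
    precomputed binary indicators rather than derived from the VCF.
    """
    ids = carrier_matrix.region_ids
    cols, names = [], []
    for g in recurrent_genes:
        if g in ids:
            cols.append(carrier_matrix.values[:, ids.index(g)])
            names.append(g)
    for f in cyto_flags:
        if f in clinical.columns:
            cols.append(clinical[f].to_numpy(dtype=np.int8))
            names.append(f)
    return FeatureMatrix(
        list(carrier_matrix.patients), names, np.column_stack(cols), "recurrent_cyto"
    )


def split_common_rare(matrix: FeatureMatrix, freq_threshold: float = 0.01):
    """Partition features by cohort carrier frequency (>= threshold -> common)."""
    if not (0.0 < freq_threshold < 0.5):
        raise ValueError(f"freq_threshold must lie in (0, 0.5), got {freq_threshold}")
    freq = matrix.values.mean(axis=0)
    common = freq >= freq_threshold
    mk = lambda mask, cls: FeatureMatrix(
        matrix.patients,
        [f for f, m in zip(matrix.feature_names, mask) if m],
        matrix.values[:, mask],
        cls,
    )
    return mk(common, "common"), mk(~common, "rare")


def stratified_logrank(time, labels, event, strata):
    """Log-rank test of ``labels`` stratified by ``strata``.

    Classical stratified log-rank: observed-minus-expected group scores and
    hypergeometric covariances accumulate within each stratum only, so group
    comparisons never cross stratum boundaries. Used for the pooled
    out-of-fold test in cross-validated clustering, where each fold is a
    stratum: within a fold the labels were produced without that fold's
    outcomes, making the test honest, whereas pooling labels across folds
    (aligned by training risk) is anti-conservative. Returns the p-value.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    labels = np.asarray(labels)
    strata = np.asarray(strata)
    groups = np.unique(labels)
    k = len(groups)
    if k < 2:
        return np.nan
    gidx = {g: i for i, g in enumerate(groups)}
    U = np.zeros(k)
    V = np.zeros((k, k))
    for s in np.unique(strata):
        m = strata == s
        ts, ls, es = time[m], labels[m], event[m]
        for t in np.unique(ts[es]):
            at_risk = ts >= t
            n = at_risk.sum()
            d = (es & (ts == t)).sum()
            if n <= 1:
                continue
            n_g = np.array([(at_risk & (ls == g)).sum() for g in groups], dtype=float)
            d_g = np.array([(es & (ts == t) & (ls == g)).sum() for g in groups], dtype=float)
            p_g = n_g / n
            U += d_g - d * p_g
            V += d * (n - d) / (n - 1) * (np.diag(p_g) - np.outer(p_g, p_g))
    Vsub = V[:-1, :-1]
    Usub = U[:-1]
    try:
        chi2 = float(Usub @ np.linalg.solve(Vsub, Usub))
    except np.linalg.LinAlgError:
        chi2 = float(Usub @ np.linalg.pinv(Vsub) @ Usub)
    return float(stats.chi2.sf(chi2, k - 1))


def _relabel_by_risk(labels, time, event, k):
    """Map raw cluster labels to 1..k ordered by crude hazard (events / person-time)."""
    rates = []
    for c in range(k):
        mask = labels == c
        persontime = float(np.sum(time[mask])) if mask.any() else 0.0
        rates.append((np.sum(event[mask]) / persontime) if persontime > 0 else np.inf)
    order = np.argsort(rates, kind="stable")  # ascending risk
    mapping = {int(old): rank + 1 for rank, old in enumerate(order)}
    return np.array([mapping[int(l)] for l in labels]), mapping


def unsupervised_subgroups(matrix: FeatureMatrix, k_range, seed: int = 0, n_restarts: int = 20):
    """K-means subgroups of the recurrent-mutation/cytogenetics matrix.

    ``k_range`` is an iterable of candidate cluster counts; the k with the
    best mean silhouette wins (a single candidate skips selection). Returns
    ``(assignment_frame, chosen_k, silhouettes)`` where the assignment frame
    has columns ``patient_id, subgroup_label, method``.
    """
    X = matrix.values.astype(float)
    if np.all(X == X[0]):
        raise ValueError("degenerate feature matrix: all patients identical")
    k_range = sorted(set(int(k) for k in k_range))
    if min(k_range) < 2:
        raise ValueError("k must be >= 2")
    if max(k_range) > len(matrix.patients):
        raise ValueError("k exceeds number of patients")
    sil = {}
    fits = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
        fits[k] = km
        sil[k] = (
            silhouette_score(X, km.labels_) if len(np.unique(km.labels_)) > 1 else -1.0
        )
    chosen_k = max(sil, key=lambda k: (sil[k], -k)) if len(k_range) > 1 else k_range[0]
    labels = fits[chosen_k].labels_
    # stable presentation order: relabel by descending cluster size
    sizes = np.bincount(labels, minlength=chosen_k)
    order = np.argsort(-sizes, kind="stable")
    mapping = {int(old): rank + 1 for rank, old in enumerate(order)}
    relabelled = np.array([mapping[int(l)] for l in labels])
    frame = pd.DataFrame(
        {"patient_id": matrix.patients, "subgroup_label": relabelled, "method": "unsupervised"}
    )
    return frame, chosen_k, sil


def supervised_cluster_cv(matrix: FeatureMatrix, time, event, config: SupervisedConfig):
    """Outcome-guided clustering with k-fold cross-validated label assignment.

    Per fold: (1) univariate Cox score-test z for every feature on the
    training split, (2) keep the ``n_top_features`` by \\|z\\|, (3) K-means the
    training split on those features, (4) nearest-centroid assignment of the
    held-out split, (5) held-out log-rank separation recorded. Feature
    scoring and clustering never see held-out outcomes.

    Returns ``(assignment_frame, diagnostics)``; diagnostics include per-fold
    selected features and held-out log-rank p plus the pooled out-of-fold
    log-rank test.
    """
    config.validate()
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    n, m = matrix.values.shape
    if len(time) != n:
        raise ValueError("outcome not aligned with feature matrix")
    if config.n_top_features > m:
        raise ValueError(f"n_top_features ({config.n_top_features}) exceeds feature count ({m})")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, config.n_folds)
    X = matrix.values.astype(float)

    oof_labels = np.zeros(n, dtype=int)
    fold_of = np.full(n, -1, dtype=int)
    diagnostics = []
    n_ok = 0
    for fold_id, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        tr = np.flatnonzero(train_mask)
        if event[tr].sum() == 0 or len(test_idx) == 0:
            logger.warning("fold %d skipped: no training events", fold_id)
            diagnostics.append({"fold_id": fold_id, "skipped": True})
            continue
        _, _, z = cox_score_test(X[tr], time[tr], event[tr])
        top = np.argsort(-np.abs(z), kind="stable")[: config.n_top_features]
        km = KMeans(
            n_clusters=config.k_clusters,
            n_init=config.n_restarts,
            random_state=config.seed + fold_id,
        ).fit(X[np.ix_(tr, top)])
        train_labels, mapping = _relabel_by_risk(km.labels_, time[tr], event[tr], config.k_clusters)
        d2 = ((X[np.ix_(test_idx, top)][:, None, :] - km.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        raw_test = d2.argmin(axis=1)
        test_labels = np.array([mapping[int(l)] for l in raw_test])
        oof_labels[test_idx] = test_labels
        fold_of[test_idx] = fold_id
        # held-out separation (NaN when the fold cannot support a log-rank test)
        p_holdout = np.nan
        if len(np.unique(test_labels)) > 1 and event[test_idx].any():
            p_holdout = float(
                multivariate_logrank_test(time[test_idx], test_labels, event[test_idx]).p_value
            )
        diagnostics.append(
            {
                "fold_id": fold_id,
                "skipped": False,
                "selected_features": [matrix.feature_names[j] for j in top],
                "heldout_logrank_p": p_holdout,
                "n_train_events": int(event[tr].sum()),
            }
        )
        n_ok += 1
    if n_ok == 0:
        raise ValueError("all folds skipped: no usable training events")

    assigned = fold_of >= 0
    pooled_p = np.nan
    if len(np.unique(oof_labels[assigned])) > 1 and event[assigned].any():
        pooled_p = stratified_logrank(
            time[assigned], oof_labels[assigned], event[assigned], fold_of[assigned]
        )
    frame = pd.DataFrame(
        {
            "patient_id": np.asarray(matrix.patients)[assigned],
            "subgroup_label": oof_labels[assigned],
            "method": "supervised",
            "fold_id": fold_of[assigned],
        }
    )
    selection_counts: dict = {}
    for d in diagnostics:
        for f in d.get("selected_features", []):
            selection_counts[f] = selection_counts.get(f, 0) + 1
    summary = {
        "folds": diagnostics,
        "oof_logrank_p": pooled_p,
        "feature_selection_counts": selection_counts,
        "config": vars(config).copy(),
    }
    return frame, summary


def evaluate_subgroups(
    assignment: pd.DataFrame,
    time,
    event,
    clinical: pd.DataFrame | None = None,
    covariates: list | None = None,
    reference_label=None,
):
    """Survival separation report for a subgroup assignment.

    Produces per-subgroup Kaplan-Meier tables, the overall log-rank test and
    a multivariable Cox model with subgroup indicator variables against the
    reference subgroup (default: the subgroup with the longest median OS),
    optionally adjusted for clinical covariates.
    """
    labels = assignment["subgroup_label"].to_numpy()
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    uniq = np.unique(labels)
    with_events = [int(u) for u in uniq if event[labels == u].any()]
    if len(with_events) < 2:
        raise ValueError("need >= 2 subgroups with events")

    km_tables = {}
    medians = {}
    for u in uniq:
        mask = labels == u
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        tab = kmf.survival_function_.reset_index()
        tab.columns = ["time", "survival"]
        tab["n_at_risk"] = [int((time[mask] >= t).sum()) for t in tab["time"]]
        km_tables[int(u)] = tab
        medians[int(u)] = float(kmf.median_survival_time_)

    if reference_label is None:
        reference_label = max(medians, key=lambda u: (medians[u], -u))
    elif reference_label not in set(int(u) for u in uniq):
        raise ValueError(f"reference label {reference_label!r} not among subgroups {list(uniq)}")

    logrank_p = float(multivariate_logrank_test(time, labels, event).p_value)

    others = [int(u) for u in uniq if int(u) != reference_label]
    dummies = np.column_stack([(labels == u).astype(float) for u in others])
    names = [f"subgroup_{u}" for u in others]
    if clinical is not None and covariates:
        from .scan import encode_covariates

        Z, zn = encode_covariates(clinical, covariates)
        Xd = np.column_stack([dummies, Z])
        names += zn
    else:
        Xd = dummies
    fit = fit_cox(Xd, time, event)
    rows = []
    for i, u in enumerate(others):
        b, s = fit.beta[i], fit.se[i]
        rows.append(
            {
                "subgroup": u,
                "hr": float(np.exp(b)),
                "ci_low": float(np.exp(b - 1.96 * s)),
                "ci_high": float(np.exp(b + 1.96 * s)),
                "p": float(2 * stats.norm.sf(abs(b / s))) if s > 0 else np.nan,
            }
        )
    return {
        "km_tables": km_tables,
        "median_survival": medians,
        "logrank_p": logrank_p,
        "reference_label": int(reference_label),
        "cox_subgroups": pd.DataFrame(rows),
        "cox_converged": bool(fit.converged),
    }
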