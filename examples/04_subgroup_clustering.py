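"""Genomic subgrouping: unsupervised K-means blocks and supervised CV clustering.

Generates a cohort whose recurrent-mutation matrix contains four signature
blocks (DNMT3A/STAG2/ASXL1, TET2, RUNX1, TP53+del5q). Unsupervised K-means
with silhouette-based model selection should find k=4 and match the planted
blocks; the outcome-guided supervised route then clusters all gene carriers
with cross-validated, leak-free label assignment and reports the held-out
survival separation.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from mdswgs import (
    FeatureMatrix,
    SimulationConfig,
    SupervisedConfig,
    build_recurrent_cyto_features,
    evaluate_subgroups,
    simulate_cohort,
    supervised_cluster_cv,
    unsupervised_subgroups,
)
from mdswgs.simulate import RECURRENT_GENES
from mdswgs.validation import FOUR_BLOCK_SPEC, truth_carrier_matrix

config = SimulationConfig(
    n_patients=400, n_genes=30, n_windows=5, carrier_freq=0.05,
    subgroup_spec=FOUR_BLOCK_SPEC, signature_noise=0.05, seed=1,
)
clinical, _, outcomes, truth = simulate_cohort(config)
matrix = truth_carrier_matrix(truth)
t = outcomes["os_time"].to_numpy()
e = outcomes["os_event"].to_numpy(bool)

features = build_recurrent_cyto_features(matrix, clinical, RECURRENT_GENES)
assignment, chosen_k, silhouettes = unsupervised_subgroups(features, range(2, 7), seed=1)
ari = adjusted_rand_score(np.array(truth["subgroup"]), assignment["subgroup_label"])
print(f"unsupervised: chosen k = {chosen_k}, ARI vs planted blocks = {ari:.3f}")

report = evaluate_subgroups(assignment, t, e, clinical, ["ipss_r_risk"])
print(f"overall log-rank p = {report['logrank_p']:.2e}, "
      f"reference subgroup = {report['reference_label']}")
print(report["cox_subgroups"].round(3).to_string(index=False))

# The supervised route needs a survival contrast to steer feature selection;
# with the hazard gap between subgroups widened it isolates the prognostic
# blocks and the held-out separation becomes decisive.
from mdswgs.validation import LADDER_SPEC

strong = SimulationConfig(
    n_patients=400, n_genes=30, n_windows=5, carrier_freq=0.05,
    subgroup_spec=LADDER_SPEC, signature_noise=0.05, clinical_effects={}, seed=1,
)
_, _, outcomes2, truth2 = simulate_cohort(strong)
matrix2 = truth_carrier_matrix(truth2)
all_features = FeatureMatrix(matrix2.patients, matrix2.region_ids, matrix2.values, "common")
sup, diag = supervised_cluster_cv(
    all_features,
    outcomes2["os_time"].to_numpy(),
    outcomes2["os_event"].to_numpy(bool),
    SupervisedConfig(k_clusters=3, n_top_features=10, n_folds=5, seed=1),
)
print(f"\nsupervised (strong-contrast cohort): out-of-fold stratified log-rank "
      f"p = {diag['oof_logrank_p']:.2e}")
# Subgroup hazard ratios above are against the best-median-OS reference
# subgroup, adjusted for IPSS-R; the TP53+del5q block carries the largest HR.
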