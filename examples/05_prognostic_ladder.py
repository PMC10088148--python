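"""The four-model random-survival-forest ladder on a genomically driven cohort.

Builds base (IPSS-R), clinical (+MDS type, HMA, chemo), genomic (mutational
number + subgroup labels) and full feature sets, fits survival forests with
honest 3-fold cross-validated predictions, and reports Harrell's C with
bootstrap CI, the integrated IPCW Brier score and permutation feature
importance. On a cohort where genomic subgroups carry the hazard and
clinical covariates carry none, the genomic model should clearly dominate.
"""

from mdswgs.validation import ladder_pattern_study

out = ladder_pattern_study(n_patients=400, seed=3)

print("OS C-index by ladder model (held-out predictions):")
for model in ("base", "clinical", "genomic", "full"):
    print(f"  {model:9s} {out['c_' + model]:.3f}")
print(f"genomic - clinical C gap: {out['genomic_minus_clinical']:.3f}")
print(f"integrated Brier, base model:    {out['integrated_brier_base']:.3f}")
print(f"integrated Brier, genomic model: {out['integrated_brier_genomic']:.3f}")
print(f"most important feature (permutation VIMP): {out['top_vimp_feature']}")
# C = 0.5 is chance; the base/clinical models sit near it by construction,
# while genomic subgroup labels lift C by ~0.2 and cut the Brier score,
# with a subgroup indicator as the top-ranked feature.
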