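# Methods

This note documents the statistical models, default parameters and design
choices behind `mdswgs`, and what the synthetic-cohort validation does and
does not establish.

## Synthetic cohort model

The generator emulates the data structure of a registry WGS study of MDS
patients undergoing alloHCT. Per patient it draws:

* **Carrier status** for `n_genes` gene regions and `n_windows` window
  regions, i.i.d. Bernoulli(`carrier_freq`, default 0.10). Genes occupy
  3 kb intervals spaced 10 kb apart on chromosome 1; windows tile
  chromosome 2 in adjacent 10 kb blocks, so a step-equals-size sliding
  window run reproduces them exactly. Recurrently mutated MDS driver genes
  (TP53, DNMT3A, TET2, ASXL1, RUNX1, STAG2, EZH2, ETV6, JAK2) hold the
  first gene slots; del5q is a cytogenetic flag carried in the clinical
  table, not the VCF.
* **Subgroup membership** from `subgroup_spec`
  (signature regions, prevalence, log HR). Members carry each signature
  region with probability 1 − `signature_noise` (default 0.95),
  non-members with `signature_noise`; prevalences may sum to ≤ 1, the
  remainder forming an unlabelled reference subgroup. The default spec
  plants the four classic blocks — DNMT3A/STAG2/ASXL1, TET2, RUNX1,
  TP53+del5q — with log HRs (0.20, 0, 0.25, 0.90): the TP53+del5q group
  strongly adverse, TET2 neutral, the others adverse but modest.
* **Clinical covariates**: IPSS-R risk (5 ordinal levels), MDS type (5
  categories), HMA exposure, chemotherapy exposure, conditioning regimen
  (myeloablative vs reduced intensity). Their default log-HR contributions
  are ≤ 0.3 in magnitude (0.075 per IPSS-R step, ±0.1 for the binaries) so
  genomic signal can dominate when planted; pass `clinical_effects={}` for
  a clinically null cohort. The linear predictor is centred so
  `baseline_hazard` keeps its marginal interpretation.
* **Outcomes** from cause-specific proportional-hazards models. Latent
  death and relapse times are exponential (Weibull if `weibull_shape` ≠ 1)
  with rates `baseline_hazard × competing_fractions[cause] × exp(lp)`,
  where `planted_effects` act on the death hazard and
  `planted_effects_relapse` on the relapse hazard. Defaults: baseline
  0.02/month, equal cause fractions, censoring exponential 0.008/month
  truncated administratively at 120 months — roughly registry-like
  follow-up with ~70% OS events. OS is death (TRM = death before relapse;
  mortality *after* relapse is not modelled — a simplification that keeps
  `dfs_time ≤ os_time` exact and the cause codes mutually exclusive).
  First-event codes: 0 censored, 1 relapse, 2 TRM.

Each region emits 1–3 VCF sites; every carrier is hit at least once and a
third of gene carriers twice, so gene-level binarisation is exercised by
construction. Gene-region sites are nonsynonymous-coding with probability
0.7 (the `CONSEQ` INFO tag); window sites are "other".

What the generator does **not** emulate: variant allele fractions and
subclonality, germline variation, linkage between regions, missing or
miscoded clinical data, cohort heterogeneity across transplant centres, and
informative censoring. Passing tests therefore demonstrate the *software
and statistics* are correct under the assumed proportional-hazards data
model, not that the scientific findings generalise to real cohorts.

## Cox partial-likelihood machinery

Region tests maximise the Efron-tied partial likelihood by Newton–Raphson
with step-halving; convergence is a score norm below 1e-9 (≤ 100
iterations), and monotone likelihoods (e.g. complete separation) are
detected by coefficient divergence beyond |β| > 10 and flagged, never
raised. Breslow ties are available. The solver is vectorised; unadjusted
scans run all regions simultaneously through a scalar-batch Newton path
that the test suite pins to the per-region fits at 1e-8. Step-halving
accepts a candidate when the log-likelihood does not decrease beyond a
relative 1e-10 tolerance — an absolute tolerance stalls in the Newton tail
where log-likelihood changes fall below float resolution.

Wald p-values are the scan default for effect reporting; the
likelihood-ratio p is exposed and used by the calibration study because
with a few dozen carriers it tracks the nominal level slightly better
(measured sizes at n=500, ~50 carriers, 600k null tests: LRT 0.0503, Wald
0.0508). The univariate score test at β=0 (equal to the log-rank statistic
for a binary covariate without ties) is the feature-screening primitive of
supervised clustering, vectorised across thousands of features.

## Fine–Gray subdistribution model

For cause c, subjects failing from the competing cause remain in the risk
set after their failure with weights G(t−)/G(Tᵢ−), where G is the
Kaplan–Meier estimate of the censoring survivor function; the weighted
partial likelihood (Breslow ties — tied times are measure-zero in the
simulated cohorts) is maximised by the same Newton scheme. Standard errors
are model-based (inverse weighted information), not the robust sandwich;
at n = 300 they differ from `cmprsk::crr`'s robust SEs by ~2% while the
coefficients agree to ~5e-7 (cross-checked in the test suite). With no
competing events the model reduces exactly to Cox.

## Multiplicity

Bonferroni (`p·m` capped at 1) and Benjamini–Hochberg q-values are computed
over the regions actually scanned, after the minimum-carrier filter
(default k_min = 3, applied symmetrically to carriers and non-carriers and
logged). Output labels use BH q < 0.05 by default.

## Clustering

K-means uses Euclidean distance on 0/1 features (equivalent to matching
distance up to constants), 20 restarts, seed-derived state; k is chosen by
mean silhouette over a candidate range (defaults: k=4 for the
recurrent+cytogenetics matrix, k=3 for supervised common variants, matching
the expected block structure; ties prefer smaller k). Unsupervised labels
are presented in decreasing cluster-size order.

The supervised recipe per fold — score features on the training split by
univariate Cox |z|, keep the top m (default 50), K-means the training
split, nearest-centroid assign the held-out split — never exposes held-out
outcomes to selection or clustering. Cluster labels are renumbered 1..k by
increasing crude training hazard (events per person-time), so label 1 is
the most favourable group with consistent semantics across folds. The
pooled out-of-fold separation is reported as a *fold-stratified* log-rank
test, with an important caveat: any pooled test over out-of-fold labels is
mildly anti-conservative, because each fold's labels are trained on the
other folds' outcomes (the classic cross-fold dependence of CV statistics —
measured size ≈ 0.10 at nominal 0.05 in the null study). It is therefore a
descriptive diagnostic. The per-fold held-out log-rank p, from a single
train/test split, is structurally honest, but the asymptotic chi-square
reference is itself slightly liberal at fold-sized samples with unbalanced
clusters (measured size 0.058-0.07). The leakage sentinel study therefore
refers the held-out statistic to its exact within-fold permutation
distribution (999 label shuffles through the vectorised score test), which
is uniform by construction under a leak-free protocol: measured KS
uniformity p = 0.71 over 400 null replicates, with any outcome leakage in
feature selection surfacing as anti-conservatism.

The common/rare split is by cohort carrier frequency, threshold 0.01 by
default (a feature at exactly the threshold is common).

Subgroup evaluation fits Kaplan–Meier curves per subgroup, an overall
log-rank test, and a multivariable Cox model with subgroup indicators
against a reference subgroup — by default the one with the longest median
OS — optionally adjusted for clinical covariates.

## Prognostic ladder

Random survival forests (scikit-survival: log-rank splitting on bootstrap
samples) with defaults of 500 trees, √p candidate features per split and a
minimum terminal-node size of 10 samples (scikit-survival controls node
*samples*, not node *events*; the spec-level "minimum events" intent is
approximated this way). Feature sets are nested by construction: base =
IPSS-R (ordinal 0–4); clinical adds one-hot MDS type and the two binary
exposures; genomic = per-patient count of carried scan-candidate regions
("mutational number", candidates = BH q < 0.10 or the top 10) plus one-hot
supervised and unsupervised subgroup labels; full = clinical ∪ genomic.

Honest predictions come from outer k-fold cross-validation (default k=3),
which supports the C-index and the Brier score uniformly via held-out
survival curves; out-of-bag aggregation (reconstructing each tree's
bootstrap sample from its stored random state) is implemented for risk
scores and permutation importance. In-bag evaluation is never reported.
Relapse and TRM are evaluated as single-event endpoints with the competing
first event censored at its occurrence — the standard RSF practice; the
Fine–Gray scan is the competing-risks-aware sensitivity route. Regimen
strata select subsets of the held-out predictions; a stratum without
events is reported as not evaluable rather than an error.

Harrell's C counts pairs where the earlier failure is identified (ties in
risk score ½); the CI is a percentile bootstrap over patients (default
B = 1000). The Brier score uses Kaplan–Meier IPCW weights — G(Tᵢ−) for
observed failures, G(t) for patients still at risk — on an evaluation grid
spanning the 10th–90th percentile of event times (15 points), integrated by
trapezoid and normalised by the span. Permutation importance is the OOB
C-index drop after permuting one feature, averaged over 5 repeats; a
constant feature scores exactly 0.

## Pipeline and reproducibility

One YAML document with per-stage blocks, schema-validated with defaults
echoed into the run; errors name the path into the config. Per-stage seeds
derive from the single global seed as `SeedSequence([seed, stage_index])`.
`manifest.json` holds the config hash, stage seeds and SHA-256 digests of
every input and output file — and deliberately no wall-clock timestamps
(those go to `run.log`), so identical runs produce byte-identical
manifests. A stage is skipped when its recorded outputs and inputs all
match their digests; the report stage, a cheap aggregation of the others'
outputs, always re-executes. Plots are emitted as data tables (volcano,
KM curves, ladder grid); figure rendering is left to the caller so the
pipeline stays headless.

## Validation studies and problem sizes

`mdswgs.validation` (driven by `scripts/acceptance.py` and
`tests/test_acceptance.py`) uses these study sizes, chosen to give each
check useful Monte-Carlo resolution while completing in minutes on one CPU:

* null-scan calibration: 500 cohorts × 200 regions at n=500 (100k tests);
* planted-gene rank recovery: 100 cohorts at n=500, log HR 0.9;
* Fine–Gray recovery: one cohort at n=1000, planted relapse log HR 0.7;
* subgroup recovery: n=400, four blocks, 5% signature noise;
* leakage sentinel: 200 permutation replicates at n=300 × 400 features;
  planted-signal run at n=600 × 1000 features;
* ladder pattern: n=400, 150 trees, 3-fold outer CV;
* pipeline determinism: two runs of a 150-patient demo config.

## Known limitations

* The Fine–Gray SE is model-based; robust (sandwich) variance is not
  implemented.
* Firth-corrected fits for separated regions are not implemented; such
  regions are flagged and retained.
* The generator's competing-risk model stops at the first event; post-
  relapse mortality and state transitions are out of scope.
* Consequence annotation is read from a VCF INFO tag, never recomputed;
  CNV/SV events enter only as precomputed flags (del5q).
* Silhouette-based k selection is heuristic; well-separated sub-blocks of
  a planted cluster can pull k upward on noisy matrices.
* Pooled out-of-fold survival-separation tests are descriptive (see
  Clustering above); per-fold held-out tests are the valid inferential
  route.
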