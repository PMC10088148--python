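# mdswgs

Whole-genome-sequencing survival analysis for myelodysplastic syndrome (MDS)
patients after allogeneic hematopoietic cell transplantation (alloHCT):
region-level somatic-variant association scanning, genomic subgrouping, and
random-survival-forest prognostic modelling — with a synthetic-cohort
generator that makes every stage testable by parameter recovery, since real
registry cohorts of this kind are access-restricted.

It is written for biostatisticians and computational biologists who analyse
censored post-transplant outcomes against somatic genotypes, either as an
importable Python library or through the `mdswgs` command-line pipeline.

## What it computes

**Carrier burden collapse.** A multi-sample somatic VCF is collapsed to a
binary patients × regions matrix under three schemes: gene-based on
nonsynonymous coding variants, gene-based on all variants, and genome-wide
sliding windows. A patient carries a region iff ≥ 1 qualifying variant with
≥ 1 alternate allele lies inside it.

**Region-level survival scan.** For each region the carrier indicator
enters a proportional-hazards model with clinical adjustment covariates

&nbsp;&nbsp;&nbsp;&nbsp;λ(t | x) = λ₀(t) · exp(β·carrier + γ'z),

fitted by Newton–Raphson on the Efron-tied partial likelihood (tolerance
1e-9 on the score norm, step-halving, separation detection). Wald and
likelihood-ratio p-values are available; Bonferroni and Benjamini–Hochberg
adjustments are computed over the scanned regions. For the competing first
events relapse and transplant-related mortality (TRM), the scan fits the
Fine–Gray subdistribution-hazard model via a weighted partial likelihood
with IPCW-extended risk sets.

**Genomic subgroups.** Unsupervised: K-means on the binary matrix of
recurrent driver mutations (TP53, DNMT3A, TET2, ASXL1, RUNX1, STAG2, …) and
cytogenetic flags (del5q), with k chosen by mean silhouette. Supervised:
per cross-validation fold, features are scored by univariate Cox
association on the training split only, the top-m by |z| are K-means
clustered, and held-out patients are assigned to the nearest centroid —
out-of-fold labels, so the reported survival separation is honest.

**Prognostic ladder.** Four nested random-survival-forest models — base
(IPSS-R), clinical (+ MDS type, HMA and chemotherapy exposure), genomic
(mutational number over scan candidates + both subgroup labels), full
(clinical ∪ genomic) — evaluated on held-out predictions by Harrell's
C-index (with percentile-bootstrap CI), the IPCW Brier score
BS(t) = E[(1{T>t} − Ŝ(t|x))²] with Kaplan–Meier censoring weights, and
permutation variable importance, for OS, DFS, relapse and TRM, optionally
stratified by conditioning regimen.

**Synthetic cohorts.** Exponential (optionally Weibull) event times from
cause-specific proportional-hazards models with planted region effects,
planted subgroup signatures, modest clinical effects, independent
exponential censoring plus an administrative cutoff — serialised as a valid
multi-sample VCF 4.2 plus clinical/outcome TSVs and a `truth.json` of all
planted parameters.

## Worked example

```bash
python examples/01_simulate_cohort.py
python examples/02_genome_scan.py
```

simulates 300 patients with a log hazard ratio of 0.9 planted on TP53
(carrier frequency 0.1), writes the cohort as VCF + TSVs, reads it back,
collapses to gene carriers and scans OS adjusted for IPSS-R and HMA
exposure. It prints:

```
  region_id  n_carriers        hr         p_raw          q_bh
0      TP53          56  4.138396  1.308852e-16  1.308852e-14
1      TET2          60  0.615925  7.045874e-03  3.522937e-01
2  GENE0083          28  0.524897  1.717580e-02  5.725266e-01
...
significant at BH q<0.05: ['TP53']
```

The planted gene tops the table (adjusted hazard ratio 4.1 against a
planted marginal 2.5 ≈ e^0.9 — the fit also absorbs the correlated
TP53+del5q subgroup effect) and is the only hit surviving
false-discovery-rate control; the 200 neutral genes behave like the null.
The remaining examples demonstrate Fine–Gray recovery of a relapse-specific
effect, subgroup discovery (silhouette selects k = 4 with ARI 0.91 against
the planted blocks), the prognostic ladder (genomic model C ≈ 0.72 vs
clinical ≈ 0.50 when the hazard is genomically driven), and the end-to-end
pipeline with its byte-reproducible manifest.

## Command-line pipeline

```bash
mdswgs run --config pipeline.yaml --out results/ --seed 1
```

runs simulate → aggregate → scan → cluster → model → report from one YAML
document; each stage's inputs and outputs are SHA-256-digested into
`manifest.json`, re-runs skip up-to-date stages, and all randomness derives
from the single global seed. Individual stages are available as
`mdswgs simulate|aggregate|scan|report`.

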