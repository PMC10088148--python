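"""Synthetic MDS transplant cohorts with planted genomic survival structure.

The generator emulates the data layout of a registry WGS study of
myelodysplastic syndrome patients undergoing allogeneic hematopoietic cell
transplantation: a multi-sample somatic VCF, a clinical covariate table
(IPSS-R risk, MDS type, pre-transplant therapy exposures, conditioning
regimen), and right-censored overall-survival / disease-free-survival
outcomes with competing first events (relapse vs transplant-related
mortality). Effects are planted on a proportional-hazards scale so every
downstream stage — carrier aggregation, genome scanning, subgrouping,
prognostic modelling — can be validated by parameter recovery without any
restricted patient data.

Genome layout convention: genes live on chromosome ``1`` (3 kb intervals,
10 kb apart), window regions on chromosome ``2`` (adjacent 10 kb tiles), so
a sliding-window tiling of chromosome 2 reproduces the generator's window
regions exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "SimulationConfig",
    "ConfigurationError",
    "simulate_cohort",
    "simulate_competing_risks",
    "write_cohort",
    "RECURRENT_GENES",
    "DEFAULT_SUBGROUP_SPEC",
]

#: recurrently mutated MDS genes given fixed positions at the head of the gene list
RECURRENT_GENES = ["TP53", "DNMT3A", "TET2", "ASXL1", "RUNX1", "STAG2", "EZH2", "ETV6", "JAK2"]

#: cytogenetic abnormality flags (carried in the clinical table, not the VCF)
CYTO_FLAGS = ["del5q"]

#: default four-subgroup molecular signature structure: (signature ids,
#: prevalence, log hazard ratio on OS). The TP53 + del5q subgroup carries the
#: dominant adverse effect; the TET2 subgroup is prognostically neutral.
DEFAULT_SUBGROUP_SPEC = [
    (("DNMT3A", "STAG2", "ASXL1"), 0.20, 0.20),
    (("TET2",), 0.20, 0.00),
    (("RUNX1",), 0.15, 0.25),
    (("TP53", "del5q"), 0.15, 0.90),
]

IPSS_R_LEVELS = ["Very Low", "Low", "Intermediate", "High", "Very High"]
MDS_TYPES = ["MDS-SLD", "MDS-MLD", "MDS-RS", "MDS-EB1", "MDS-EB2"]
REGIMENS = ["myeloablative", "reduced intensity"]

GENE_LEN = 3_000
GENE_GAP = 10_000
WINDOW_LEN = 10_000


class ConfigurationError(ValueError):
    """A simulation configuration field is invalid; the message names it."""


@dataclass
class SimulationConfig:
    """Cohort-level simulation parameters.

    Rates are per month; times are months. ``planted_effects`` act on the
    death (OS/TRM) hazard, ``planted_effects_relapse`` on the relapse
    cause-specific hazard. ``subgroup_spec`` entries are
    ``(signature_region_ids, prevalence, log_hazard_ratio)``; prevalences may
    sum to at most 1, the remainder forming the unlabelled reference
    subgroup. Signature ids may name genes, windows (``W0001``) or
    cytogenetic flags (``del5q``).
    """

    n_patients: int = 300
    n_genes: int = 100
    n_windows: int = 40
    carrier_freq: float = 0.10
    planted_effects: list = field(default_factory=list)
    planted_effects_relapse: list = field(default_factory=list)
    subgroup_spec: list = field(default_factory=list)
    signature_noise: float = 0.05
    baseline_hazard: float = 0.02
    weibull_shape: float = 1.0
    censoring_rate: float = 0.008
    admin_censor_time: float = 120.0
    competing_fractions: dict = field(default_factory=lambda: {"relapse": 1.0, "trm": 1.0})
    clinical_effects: dict = field(
        default_factory=lambda: {
            "ipss_r_risk": 0.075,  # per ordinal step, max 0.3 across the scale
            "hma_exposure": 0.10,
            "chemo_exposure": 0.10,
            "conditioning_regimen": -0.10,  # reduced intensity vs myeloablative
        }
    )
    nonsyn_fraction: float = 0.7
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        for name in ("n_patients", "n_genes", "n_windows"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        for name in ("carrier_freq", "signature_noise", "nonsyn_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v!r}")
        for name in ("baseline_hazard", "censoring_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        if self.weibull_shape <= 0:
            raise ConfigurationError(f"weibull_shape must be > 0, got {self.weibull_shape!r}")
        if self.admin_censor_time <= 0:
            raise ConfigurationError(
                f"admin_censor_time must be > 0, got {self.admin_censor_time!r}"
            )
        for key in ("relapse", "trm"):
            if key not in self.competing_fractions:
                raise ConfigurationError(f"competing_fractions missing key {key!r}")
            if self.competing_fractions[key] < 0:
                raise ConfigurationError(f"competing_fractions[{key!r}] must be >= 0")
        prev = sum(p for _, p, _ in self.subgroup_spec)
        if any(not (0 <= p <= 1) for _, p, _ in self.subgroup_spec) or prev > 1 + 1e-12:
            raise ConfigurationError(
                f"subgroup_spec prevalences must be in [0,1] and sum to <= 1 (sum={prev})"
            )
        for rid, _ in list(self.planted_effects) + list(self.planted_effects_relapse):
            if not isinstance(rid, str):
                raise ConfigurationError(f"planted_effects region id must be str, got {rid!r}")
        return self


def _region_catalog(config: SimulationConfig):
    """Gene and window region ids with their genomic intervals (1-based)."""
    genes = list(RECURRENT_GENES[: config.n_genes])
    genes += [f"GENE{i:04d}" for i in range(len(genes) + 1, config.n_genes + 1)]
    gene_rows = []
    pos = 1
    for g in genes:
        gene_rows.append((g, "1", pos, pos + GENE_LEN - 1))
        pos += GENE_GAP
    window_rows = []
    pos = 1
    for i in range(1, config.n_windows + 1):
        window_rows.append((f"W{i:04d}", "2", pos, pos + WINDOW_LEN - 1))
        pos += WINDOW_LEN
    return gene_rows, window_rows


def simulate_competing_risks(
    lp_death,
    lp_relapse,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw outcome records from cause-specific proportional-hazards models.

    Latent death and relapse times are Weibull (exponential when
    ``weibull_shape`` is 1) with rates ``baseline * fraction * exp(lp)``;
    the observed first event is their minimum against independent
    exponential-plus-administrative censoring. Codes: 0 censored, 1 relapse,
    2 transplant-related mortality (death before relapse).
    """
    lp_death = np.asarray(lp_death, dtype=float)
    lp_relapse = np.asarray(lp_relapse, dtype=float)
    n = lp_death.shape[0]
    h_death = config.baseline_hazard * config.competing_fractions["trm"] * np.exp(lp_death)
    h_rel = config.baseline_hazard * config.competing_fractions["relapse"] * np.exp(lp_relapse)
    if np.all(h_death == 0) and np.all(h_rel == 0):
        raise ConfigurationError("all cause-specific hazards are zero: no events possible")

    def draw(hazard):
        with np.errstate(divide="ignore"):
            t = -np.log(rng.uniform(size=n)) / np.where(hazard > 0, hazard, np.nan)
        t = np.where(hazard > 0, t, np.inf)
        return np.power(t, 1.0 / config.weibull_shape)

    t_death = draw(h_death)
    t_rel = draw(h_rel)
    if config.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / config.censoring_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, config.admin_censor_time)

    t_first = np.minimum(t_rel, t_death)
    observed_first = t_first <= t_cens
    code = np.where(~observed_first, 0, np.where(t_rel < t_death, 1, 2))

    os_time = np.minimum(t_death, t_cens)
    os_event = (t_death <= t_cens).astype(int)
    dfs_time = np.minimum(t_first, t_cens)
    dfs_event = observed_first.astype(int)
    # numerical floor keeps all observed times strictly positive
    eps = 1e-9
    return pd.DataFrame(
        {
            "os_time": np.maximum(os_time, eps),
            "os_event": os_event,
            "dfs_time": np.maximum(dfs_time, eps),
            "dfs_event": dfs_event,
            "relapse_time": np.maximum(dfs_time, eps),
            "first_event_code": code,
        }
    )


def simulate_cohort(config: SimulationConfig):
    """Generate aligned clinical, variant and outcome tables for one cohort.

    Returns ``(clinical, variants, outcomes, truth)``: three DataFrames keyed
    by ``patient_id`` plus a ``truth`` dict holding the planted parameters,
    region intervals, subgroup labels and the exact carrier matrix, for
    recovery tests and VCF round-trip checks.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    patient_ids = [f"P{i:05d}" for i in range(1, n + 1)]
    gene_rows, window_rows = _region_catalog(config)
    region_ids = [r[0] for r in gene_rows + window_rows]
    region_index = {r: i for i, r in enumerate(region_ids)}
    for rid, _ in list(config.planted_effects) + list(config.planted_effects_relapse):
        if rid not in region_index and rid not in CYTO_FLAGS:
            raise ConfigurationError(f"planted_effects names unknown region {rid!r}")

    # ---- subgroup assignment --------------------------------------------
    k = len(config.subgroup_spec)
    prevalences = np.array([p for _, p, _ in config.subgroup_spec])
    probs = np.concatenate([prevalences, [max(0.0, 1.0 - prevalences.sum())]])
    probs = probs / probs.sum()
    subgroup = rng.choice(np.arange(1, k + 2), size=n, p=probs)
    subgroup[subgroup == k + 1] = 0  # 0 = reference (no planted signature)

    # ---- carrier matrix (genes + windows) -------------------------------
    carriers = (rng.uniform(size=(n, len(region_ids))) < config.carrier_freq).astype(np.int8)
    cyto = {
        flag: (rng.uniform(size=n) < config.signature_noise).astype(np.int8)
        for flag in CYTO_FLAGS
    }
    for g, (sig_ids, _, _) in enumerate(config.subgroup_spec, start=1):
        members = subgroup == g
        for rid in sig_ids:
            hit = rng.uniform(size=n) < np.where(
                members, 1.0 - config.signature_noise, config.signature_noise
            )
            if rid in CYTO_FLAGS:
                cyto[rid] = hit.astype(np.int8)
            elif rid in region_index:
                carriers[:, region_index[rid]] = hit.astype(np.int8)
            else:
                raise ConfigurationError(f"subgroup_spec names unknown region {rid!r}")

    # ---- clinical covariates --------------------------------------------
    ipss = rng.choice(len(IPSS_R_LEVELS), size=n, p=[0.10, 0.25, 0.30, 0.22, 0.13])
    mds_type = rng.choice(len(MDS_TYPES), size=n, p=[0.15, 0.30, 0.10, 0.25, 0.20])
    hma = rng.binomial(1, 0.55, size=n)
    chemo = rng.binomial(1, 0.30, size=n)
    regimen = rng.binomial(1, 0.45, size=n)  # 1 = reduced intensity
    clinical = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "ipss_r_risk": [IPSS_R_LEVELS[i] for i in ipss],
            "mds_type": [MDS_TYPES[i] for i in mds_type],
            "hma_exposure": hma,
            "chemo_exposure": chemo,
            "conditioning_regimen": [REGIMENS[i] for i in regimen],
        }
    )
    for flag, vals in cyto.items():
        clinical[flag] = vals

    eff = config.clinical_effects
    lp_clin = (
        eff.get("ipss_r_risk", 0.0) * ipss
        + eff.get("hma_exposure", 0.0) * hma
        + eff.get("chemo_exposure", 0.0) * chemo
        + eff.get("conditioning_regimen", 0.0) * regimen
    )
    lp_clin = lp_clin - lp_clin.mean()  # centre: keeps baseline_hazard interpretable

    # ---- linear predictors ----------------------------------------------
    def planted_lp(effects):
        lp = np.zeros(n)
        for rid, beta in effects:
            if rid in CYTO_FLAGS:
                lp += beta * cyto[rid]
            else:
                lp += beta * carriers[:, region_index[rid]]
        return lp

    sub_beta = np.array([0.0] + [b for _, _, b in config.subgroup_spec])
    lp_sub = sub_beta[subgroup]
    lp_death = planted_lp(config.planted_effects) + lp_sub + lp_clin
    lp_relapse = planted_lp(config.planted_effects_relapse) + lp_sub + lp_clin

    outcomes = simulate_competing_risks(lp_death, lp_relapse, config, rng)
    outcomes.insert(0, "patient_id", patient_ids)

    # ---- variant records ------------------------------------------------
    # Each region emits 1-3 sites; every carrier is assigned >= 1 site and a
    # third of gene carriers get a second hit, so gene-level binarisation is
    # exercised by construction.
    variant_rows = []
    all_regions = gene_rows + window_rows
    bases = np.array(list("ACGT"))
    for rid, chrom, start, end in all_regions:
        carrier_idx = np.flatnonzero(carriers[:, region_index[rid]])
        n_sites = int(rng.integers(1, 4))
        positions = np.sort(rng.choice(np.arange(start, end + 1), size=n_sites, replace=False))
        is_gene = chrom == "1"
        site_conseq = [
            "nonsynonymous_coding"
            if is_gene and rng.uniform() < config.nonsyn_fraction
            else "other"
            for _ in range(n_sites)
        ]
        site_carriers = [set() for _ in range(n_sites)]
        for pi in carrier_idx:
            s = int(rng.integers(n_sites))
            site_carriers[s].add(pi)
            if is_gene and n_sites > 1 and rng.uniform() < 0.33:
                site_carriers[(s + 1) % n_sites].add(pi)
        for s in range(n_sites):
            if not site_carriers[s]:
                continue
            ref = str(rng.choice(bases))
            alt = str(rng.choice(bases[bases != ref]))
            variant_rows.append(
                {
                    "chrom": chrom,
                    "pos": int(positions[s]),
                    "ref": ref,
                    "alt": alt,
                    "consequence": site_conseq[s],
                    "region_id": rid,
                    "carrier_ids": sorted(patient_ids[i] for i in site_carriers[s]),
                }
            )
    variants = pd.DataFrame(variant_rows).sort_values(["chrom", "pos"]).reset_index(drop=True)

    nonsyn = np.zeros_like(carriers)
    for _, row in variants.iterrows():
        if row["consequence"] == "nonsynonymous_coding":
            j = region_index[row["region_id"]]
            for pid in row["carrier_ids"]:
                nonsyn[int(pid[1:]) - 1, j] = 1

    truth = {
        "config": _config_to_jsonable(config),
        "patient_ids": patient_ids,
        "region_ids": region_ids,
        "regions": [
            {"region_id": r, "chrom": c, "start": s, "end": e} for r, c, s, e in all_regions
        ],
        "subgroup": subgroup.tolist(),
        "carrier_matrix": {
            rid: np.flatnonzero(carriers[:, j]).tolist() for rid, j in region_index.items()
        },
        "carrier_matrix_nonsyn": {
            rid: np.flatnonzero(nonsyn[:, j]).tolist() for rid, j in region_index.items()
        },
        "cyto_flags": {flag: vals.tolist() for flag, vals in cyto.items()},
        "lp_death": lp_death.tolist(),
        "lp_relapse": lp_relapse.tolist(),
    }
    return clinical, variants, outcomes, truth


def _config_to_jsonable(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["planted_effects"] = [[r, float(b)] for r, b in d["planted_effects"]]
    d["planted_effects_relapse"] = [[r, float(b)] for r, b in d["planted_effects_relapse"]]
    d["subgroup_spec"] = [[list(s), float(p), float(b)] for s, p, b in d["subgroup_spec"]]
    return d


def write_cohort(clinical, variants, outcomes, truth, out_dir) -> dict:
    """Serialise a simulated cohort: multi-sample VCF + TSV tables + truth JSON.

    The VCF is version 4.2, GT-only, coordinate-sorted, with the variant
    consequence in the ``CONSEQ`` INFO tag. Returns a dict of written paths.
    """
    if len(clinical) == 0:
        raise ValueError("refusing to write an empty cohort (0 patients)")
    if not (
        set(clinical["patient_id"]) == set(outcomes["patient_id"])
    ):
        raise ValueError("clinical and outcome tables disagree on patient_id")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patient_ids = list(clinical["patient_id"])

    vcf_path = out / "cohort.vcf"
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    chrom_max = variants.groupby("chrom")["pos"].max() if len(variants) else {}
    for chrom in sorted(set(variants["chrom"])) if len(variants) else []:
        header.contigs.add(chrom, length=int(chrom_max[chrom]) + WINDOW_LEN)
    header.add_line(
        '##INFO=<ID=CONSEQ,Number=1,Type=String,Description='
        '"Functional consequence: nonsynonymous_coding or other">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for pid in patient_ids:
        header.add_sample(pid)
    with pysam.VariantFile(str(vcf_path), "w", header=header) as vcf:
        for _, row in variants.sort_values(["chrom", "pos"]).iterrows():
            rec = vcf.new_record(
                contig=row["chrom"],
                start=int(row["pos"]) - 1,  # pysam is 0-based internally
                stop=int(row["pos"]),
                alleles=(row["ref"], row["alt"]),
            )
            rec.info["CONSEQ"] = row["consequence"]
            carrier_set = set(row["carrier_ids"])
            for pid in patient_ids:
                rec.samples[pid]["GT"] = (0, 1) if pid in carrier_set else (0, 0)
            vcf.write(rec)

    clin_path = out / "clinical.tsv"
    clinical.to_csv(clin_path, sep="\t", index=False)
    out_path = out / "outcomes.tsv"
    outcomes.to_csv(out_path, sep="\t", index=False)
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))

    regions_path = out / "regions.bed"
    with open(regions_path, "w") as fh:
        for r in truth["regions"]:
            # BED is 0-based half-open
            fh.write(f"{r['chrom']}\t{r['start'] - 1}\t{r['end']}\t{r['region_id']}\n")
    layout_path = out / "genome.tsv"
    with open(layout_path, "w") as fh:
        fh.write("chrom\tlength\n")
        for chrom in sorted({r["chrom"] for r in truth["regions"]}):
            length = max(r["end"] for r in truth["regions"] if r["chrom"] == chrom)
            fh.write(f"{chrom}\t{length}\n")
    return {
        "vcf": vcf_path,
        "clinical": clin_path,
        "outcomes": out_path,
        "truth": truth_path,
        "regions_bed": regions_path,
        "genome_layout": layout_path,
    }
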