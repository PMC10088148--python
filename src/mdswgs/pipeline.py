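"""End-to-end pipeline: simulate -> aggregate -> scan -> cluster -> model -> report.

One YAML/JSON config document with per-stage blocks drives the whole run; a
``manifest.json`` records the config hash, per-stage seeds and the SHA-256
digest of every input and output file, so a re-run from the same config and
seed is verifiable byte-for-byte. Stages are skipped when their recorded
outputs already exist with matching digests (make-style incremental
execution). Wall-clock timestamps go to ``run.log``, never into the
manifest, so manifests of identical runs are identical files.

Per-stage randomness derives from the single global seed as
``SeedSequence([global_seed, stage_index])``; the derived integers are
echoed into the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregate as agg
from . import cluster as clu
from . import prognostic as prog
from . import scan as scanmod
from . import simulate as sim

__all__ = ["load_config", "run_pipeline", "render_report", "stage_seed", "PipelineError"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "aggregate", "scan", "cluster", "model", "report")

DEFAULTS = {
    "simulate": {
        "n_patients": 300,
        "n_genes": 100,
        "n_windows": 40,
        "carrier_freq": 0.10,
        "planted_effects": [],
        "planted_effects_relapse": [],
        "subgroup_spec": [[list(s), p, b] for s, p, b in sim.DEFAULT_SUBGROUP_SPEC],
        "signature_noise": 0.05,
        "baseline_hazard": 0.02,
        "censoring_rate": 0.008,
        "admin_censor_time": 120.0,
    },
    "aggregate": {
        "schemes": ["gene_all", "gene_nonsyn", "window"],
        "window_size": 10000,
        "step": 5000,
        "min_carriers": 3,
        "consequence_tag": "CONSEQ",
    },
    "scan": {"endpoint": "os", "test": "cox", "adjust": [], "scheme": "gene_all"},
    "cluster": {
        "k_range": [2, 6],
        "supervised_k": 3,
        "n_top_features": 50,
        "n_folds": 5,
        "freq_threshold": 0.01,
        "endpoint": "os",
    },
    "model": {
        "n_trees": 300,
        "min_node_size": 10,
        "endpoints": ["os", "dfs", "relapse", "trm"],
        "strata": ["all"],
        "candidate_q": 0.10,
        "candidate_top_n": 10,
        "n_bootstrap_ci": 200,
        "n_outer_folds": 3,
    },
    "report": {},
}


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stage seed from the global seed (documented, reproducible)."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([int(global_seed), idx]).generate_state(1)[0] % (2**31))


def load_config(path) -> dict:
    """Parse and schema-validate a pipeline config, filling defaults.

    Validation errors name the offending path into the document.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise PipelineError("config root must be a mapping")
    cfg = {"seed": raw.get("seed", 0), "stages": raw.get("stages", list(STAGES))}
    if not isinstance(cfg["seed"], int):
        raise PipelineError("config error at 'seed': must be an integer")
    for stage in STAGES:
        block = raw.get(stage, {})
        if block is None:
            block = {}
        if not isinstance(block, dict):
            raise PipelineError(f"config error at '{stage}': must be a mapping")
        merged = {**DEFAULTS[stage], **block}
        unknown = set(block) - set(DEFAULTS[stage])
        if unknown:
            raise PipelineError(
                f"config error at '{stage}.{sorted(unknown)[0]}': unknown key"
            )
        cfg[stage] = merged
    for st in cfg["stages"]:
        if st not in STAGES:
            raise PipelineError(f"config error at 'stages': unknown stage {st!r}")
    # cheap structural checks that fail before any computation
    simblock = cfg["simulate"]
    for key in ("n_patients", "n_genes", "n_windows"):
        if not isinstance(simblock[key], int) or simblock[key] <= 0:
            raise PipelineError(f"config error at 'simulate.{key}': positive integer required")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def _stage_uptodate(entry, out_dir: Path) -> bool:
    if entry is None:
        return False
    for rel, digest in entry["outputs"].items():
        p = out_dir / rel
        if not p.exists() or _sha256(p) != digest:
            return False
    return True


def run_pipeline(config_path, out_dir, seed: int | None = None) -> dict:
    """Execute the pipeline stages in order; returns the manifest dict."""
    cfg = load_config(config_path)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("mdswgs")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)

    manifest_path = out / "manifest.json"
    previous = {}
    if manifest_path.exists():
        try:
            old = json.loads(manifest_path.read_text())
            if old.get("config_hash") == _config_hash(cfg):
                previous = {e["stage"]: e for e in old.get("stages", [])}
        except (json.JSONDecodeError, KeyError):
            previous = {}

    manifest = {
        "tool": "mdswgs 0.1.0",
        "config_hash": _config_hash(cfg),
        "global_seed": cfg["seed"],
        "stages": [],
    }
    state: dict = {}
    try:
        for stage in STAGES:
            if stage not in cfg["stages"]:
                continue
            entry = previous.get(stage)
            runner = _RUNNERS[stage]
            # report is a cheap pure aggregation of other stages' outputs: always rebuilt
            if stage != "report" and _stage_uptodate(entry, out) and not _inputs_stale(entry, out):
                logger.info("stage %s: up to date, skipped", stage)
                runner(cfg, out, state, load_only=True)
                entry = dict(entry)
                entry["skipped"] = True
                manifest["stages"].append(entry)
                continue
            t0 = _time.time()
            inputs, outputs = runner(cfg, out, state, load_only=False)
            logger.info("stage %s: done in %.1fs", stage, _time.time() - t0)
            manifest["stages"].append(
                {
                    "stage": stage,
                    "seed": stage_seed(cfg["seed"], stage),
                    "inputs": {str(p): _sha256(out / p) for p in inputs},
                    "outputs": {str(p): _sha256(out / p) for p in outputs},
                    "skipped": False,
                }
            )
    except Exception as exc:
        manifest["failure"] = {"stage": stage, "error": str(exc)}
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        root.removeHandler(log_handler)
        raise
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    root.removeHandler(log_handler)
    return manifest


def _inputs_stale(entry, out_dir: Path) -> bool:
    for rel, digest in entry.get("inputs", {}).items():
        p = out_dir / rel
        if not p.exists() or _sha256(p) != digest:
            return True
    return False


# ---------------------------------------------------------------------------
# stage runners: (cfg, out_dir, state, load_only) -> (input relpaths, output relpaths)
# ---------------------------------------------------------------------------


def _load_tables(out: Path, state: dict):
    if "clinical" not in state:
        state["clinical"] = pd.read_csv(out / "simulate/clinical.tsv", sep="\t")
        state["outcomes"] = pd.read_csv(out / "simulate/outcomes.tsv", sep="\t")
        state["truth"] = json.loads((out / "simulate/truth.json").read_text())


def _run_simulate(cfg, out: Path, state: dict, load_only=False):
    outputs = [
        "simulate/cohort.vcf", "simulate/clinical.tsv", "simulate/outcomes.tsv",
        "simulate/truth.json", "simulate/regions.bed", "simulate/genome.tsv",
    ]
    if load_only:
        _load_tables(out, state)
        return [], outputs
    block = dict(cfg["simulate"])
    block["planted_effects"] = [tuple(e) for e in block["planted_effects"]]
    block["planted_effects_relapse"] = [tuple(e) for e in block["planted_effects_relapse"]]
    block["subgroup_spec"] = [(tuple(s), p, b) for s, p, b in block["subgroup_spec"]]
    scfg = sim.SimulationConfig(**block, seed=stage_seed(cfg["seed"], "simulate"))
    clinical, variants, outcomes, truth = sim.simulate_cohort(scfg)
    sim.write_cohort(clinical, variants, outcomes, truth, out / "simulate")
    state.update(clinical=clinical, outcomes=outcomes, truth=truth)
    return [], outputs


def _run_aggregate(cfg, out: Path, state: dict, load_only=False):
    block = cfg["aggregate"]
    outputs = [f"aggregate/matrix_{s}.tsv" for s in block["schemes"]]
    inputs = ["simulate/cohort.vcf", "simulate/regions.bed", "simulate/genome.tsv"]
    if load_only:
        state["matrices"] = {
            s: agg.CarrierMatrix.from_tsv(out / f"aggregate/matrix_{s}.tsv", s)
            for s in block["schemes"]
        }
        return inputs, outputs
    variants, samples = agg.read_vcf(
        out / "simulate/cohort.vcf", consequence_tag=block["consequence_tag"]
    )
    (out / "aggregate").mkdir(exist_ok=True)
    gene_regions = [
        r for r in agg.read_bed(out / "simulate/regions.bed") if not r.region_id.startswith("W")
    ]
    matrices = {}
    for scheme in block["schemes"]:
        if scheme == "gene_all":
            m = agg.collapse_by_gene(variants, gene_regions, samples)
        elif scheme == "gene_nonsyn":
            m = agg.collapse_by_gene(variants, gene_regions, samples, agg.NONSYN)
        elif scheme == "window":
            layout = agg.read_genome_layout(out / "simulate/genome.tsv")
            wins = agg.build_windows(layout, block["window_size"], block["step"])
            m = agg.collapse_by_regions(variants, wins, samples)
        else:
            raise PipelineError(f"config error at 'aggregate.schemes': unknown {scheme!r}")
        m = agg.filter_min_carriers(m, block["min_carriers"])
        m.to_tsv(out / f"aggregate/matrix_{scheme}.tsv")
        matrices[scheme] = m
    state["matrices"] = matrices
    return inputs, outputs


def _scan_outcome(cfg, state):
    _ = cfg
    o = state["outcomes"]
    endpoint = cfg["scan"]["endpoint"]
    if endpoint == "os":
        return o["os_time"].to_numpy(), o["os_event"].to_numpy(bool)
    if endpoint == "dfs":
        return o["dfs_time"].to_numpy(), o["dfs_event"].to_numpy(bool)
    raise PipelineError("scan.endpoint must be 'os' or 'dfs' for Cox scans; "
                        "use test='finegray' with 'relapse'/'trm'")


def _run_scan(cfg, out: Path, state: dict, load_only=False):
    block = cfg["scan"]
    outputs = ["scan/results.tsv", "scan/volcano.tsv"]
    inputs = [f"aggregate/matrix_{block['scheme']}.tsv", "simulate/outcomes.tsv",
              "simulate/clinical.tsv"]
    if load_only:
        state["scan_results"] = pd.read_csv(out / "scan/results.tsv", sep="\t")
        return inputs, outputs
    _load_tables(out, state)
    matrix = state["matrices"][block["scheme"]]
    cov = None
    if block["adjust"]:
        cov, _names = scanmod.encode_covariates(state["clinical"], block["adjust"])
    o = state["outcomes"]
    if block["test"] == "cox":
        t, e = _scan_outcome(cfg, state)
        results = scanmod.genome_scan(matrix, cov, t, e, test="cox")
    else:
        results = scanmod.genome_scan(
            matrix, cov, o["dfs_time"].to_numpy(), o["first_event_code"].to_numpy(),
            test="finegray", cause=block["endpoint"],
        )
    (out / "scan").mkdir(exist_ok=True)
    results.to_csv(out / "scan/results.tsv", sep="\t", index=False)
    scanmod.volcano_table(results).to_csv(out / "scan/volcano.tsv", sep="\t", index=False)
    state["scan_results"] = results
    return inputs, outputs


def _run_cluster(cfg, out: Path, state: dict, load_only=False):
    block = cfg["cluster"]
    outputs = ["cluster/assignments.tsv", "cluster/diagnostics.json", "cluster/km_tables.tsv",
               "cluster/heatmap.tsv"]
    inputs = ["aggregate/matrix_gene_all.tsv", "simulate/outcomes.tsv", "simulate/clinical.tsv"]
    if load_only:
        state["assignments"] = pd.read_csv(out / "cluster/assignments.tsv", sep="\t")
        return inputs, outputs
    _load_tables(out, state)
    matrix = state["matrices"]["gene_all"]
    clinical = state["clinical"]
    o = state["outcomes"]
    seed = stage_seed(cfg["seed"], "cluster")
    t = o["os_time"].to_numpy()
    e = o["os_event"].to_numpy(bool)

    fm_rec = clu.build_recurrent_cyto_features(matrix, clinical, sim.RECURRENT_GENES)
    unsup, chosen_k, sil = clu.unsupervised_subgroups(
        fm_rec, range(block["k_range"][0], block["k_range"][1] + 1), seed=seed
    )
    all_fm = clu.FeatureMatrix(matrix.patients, matrix.region_ids, matrix.values, "common")
    common, rare = clu.split_common_rare(all_fm, block["freq_threshold"])
    sup_cfg = clu.SupervisedConfig(
        k_clusters=block["supervised_k"],
        n_top_features=min(block["n_top_features"], len(common.feature_names)),
        n_folds=block["n_folds"],
        endpoint=block["endpoint"],
        seed=seed,
    )
    sup, diag = clu.supervised_cluster_cv(common, t, e, sup_cfg)
    assignments = pd.concat([unsup, sup], ignore_index=True)
    (out / "cluster").mkdir(exist_ok=True)
    assignments.to_csv(out / "cluster/assignments.tsv", sep="\t", index=False)

    report = clu.evaluate_subgroups(unsup, t, e, clinical, [])
    km_rows = []
    for label, tab in report["km_tables"].items():
        tab = tab.copy()
        tab.insert(0, "subgroup", label)
        km_rows.append(tab)
    pd.concat(km_rows, ignore_index=True).to_csv(out / "cluster/km_tables.tsv", sep="\t", index=False)

    # heatmap matrix: patients sorted by subgroup then burden; features by prevalence
    burden = fm_rec.values.sum(axis=1)
    order = sorted(
        range(len(matrix.patients)), key=lambda i: (unsup["subgroup_label"][i], -burden[i])
    )
    heat = pd.DataFrame(
        fm_rec.values[order], columns=fm_rec.feature_names,
        index=[matrix.patients[i] for i in order],
    )
    heat.index.name = "patient_id"
    heat.to_csv(out / "cluster/heatmap.tsv", sep="\t")

    diag_doc = {
        "unsupervised": {"chosen_k": int(chosen_k),
                         "silhouette": {str(k): float(v) for k, v in sil.items()},
                         "logrank_p": report["logrank_p"]},
        "supervised": diag,
    }
    (out / "cluster/diagnostics.json").write_text(json.dumps(diag_doc, indent=1, sort_keys=True))
    state["assignments"] = assignments
    return inputs, outputs


def _run_model(cfg, out: Path, state: dict, load_only=False):
    block = cfg["model"]
    outputs = ["model/table1.tsv", "model/brier.tsv", "model/vimp.tsv", "model/run_meta.json"]
    inputs = ["scan/results.tsv", "cluster/assignments.tsv", "simulate/clinical.tsv",
              "simulate/outcomes.tsv", "aggregate/matrix_gene_all.tsv"]
    if load_only:
        state["table1"] = pd.read_csv(out / "model/table1.tsv", sep="\t")
        return inputs, outputs
    _load_tables(out, state)
    clinical = state["clinical"]
    outcomes = state["outcomes"]
    matrix = state["matrices"]["gene_all"]
    results = state["scan_results"]
    assignments = state["assignments"]

    sig = results[results["q_bh"] < block["candidate_q"]]
    if len(sig) == 0:
        sig = results.head(block["candidate_top_n"])
    cand = [r for r in sig["region_id"] if r in matrix.region_ids]
    idx = [matrix.region_ids.index(r) for r in cand]
    counts = matrix.values[:, idx].sum(axis=1) if idx else np.zeros(len(clinical))

    def labels_for(method):
        sub = assignments[assignments["method"] == method]
        m = dict(zip(sub["patient_id"], sub["subgroup_label"]))
        return np.array([m.get(p, 0) for p in clinical["patient_id"]])

    feats = prog.build_ladder_features(
        clinical, counts, labels_for("supervised"), labels_for("unsupervised")
    )
    rcfg = prog.RSFConfig(
        n_trees=block["n_trees"], min_node_size=block["min_node_size"],
        n_bootstrap_ci=block["n_bootstrap_ci"], n_outer_folds=block["n_outer_folds"],
        seed=stage_seed(cfg["seed"], "model"),
    )
    table, details = prog.evaluate_ladder(
        clinical, outcomes, feats, endpoints=block["endpoints"],
        strata=block["strata"], config=rcfg,
    )
    (out / "model").mkdir(exist_ok=True)
    table.to_csv(out / "model/table1.tsv", sep="\t", index=False)
    brows = [
        {"model": m, "endpoint": e, "stratum": s, "time": t, "brier": b}
        for (m, e, s), curve in details["brier_curves"].items()
        for t, b in curve
    ]
    pd.DataFrame(brows).to_csv(out / "model/brier.tsv", sep="\t", index=False)
    vrows = [
        {"model": m, "endpoint": e, "feature": f, "vimp": v}
        for (m, e), vimp in details["vimp"].items()
        for f, v in vimp.items()
    ]
    pd.DataFrame(vrows).to_csv(out / "model/vimp.tsv", sep="\t", index=False)
    (out / "model/run_meta.json").write_text(
        json.dumps(
            {"seed": rcfg.seed, "config": {k: str(v) for k, v in vars(rcfg).items()},
             "candidates": cand},
            indent=1, sort_keys=True,
        )
    )
    state["table1"] = table
    return inputs, outputs


def _run_report(cfg, out: Path, state: dict, load_only=False):
    _ = cfg, state
    outputs, _made = render_report(out)
    return [], outputs


def render_report(out_dir) -> tuple[list, dict]:
    """Aggregate whichever stage outputs exist into report/ summary tables.

    Emits machine-readable TSVs (ladder grid, volcano, KM curves); rendering
    figures from them is left to the caller so the pipeline stays headless.
    """
    out = Path(out_dir)
    rep = out / "report"
    rep.mkdir(exist_ok=True)
    outputs = []
    made = {}
    if (out / "scan/volcano.tsv").exists():
        df = pd.read_csv(out / "scan/volcano.tsv", sep="\t")
        df.head(2000).to_csv(rep / "volcano.tsv", sep="\t", index=False)
        outputs.append("report/volcano.tsv")
        made["volcano"] = len(df)
    if (out / "cluster/km_tables.tsv").exists():
        df = pd.read_csv(out / "cluster/km_tables.tsv", sep="\t")
        df.to_csv(rep / "km_curves.tsv", sep="\t", index=False)
        outputs.append("report/km_curves.tsv")
        made["km"] = len(df)
    if (out / "model/table1.tsv").exists():
        t1 = pd.read_csv(out / "model/table1.tsv", sep="\t")
        wide = t1[t1["stratum"] == "all"].pivot_table(
            index="model", columns="endpoint", values="c_index", sort=False
        )
        wide.to_csv(rep / "ladder_grid.tsv", sep="\t")
        outputs.append("report/ladder_grid.tsv")
        made["ladder"] = wide.shape
    if not outputs:
        raise PipelineError("render_report: no stage outputs present")
    return outputs, made


_RUNNERS = {
    "simulate": _run_simulate,
    "aggregate": _run_aggregate,
    "scan": _run_scan,
    "cluster": _run_cluster,
    "model": _run_model,
    "report": _run_report,
}
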