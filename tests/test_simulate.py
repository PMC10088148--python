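"""Synthetic cohort generator: determinism, calibration and parameter recovery."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from mdswgs.coxph import fit_cox
from mdswgs.simulate import (
    ConfigurationError,
    SimulationConfig,
    simulate_cohort,
    simulate_competing_risks,
    write_cohort,
)


@pytest.mark.parametrize(
    "field,value,match",
    [
        ("n_patients", 0, "n_patients"),
        ("carrier_freq", 1.5, "carrier_freq"),
        ("baseline_hazard", -0.1, "baseline_hazard"),
        ("admin_censor_time", 0.0, "admin_censor_time"),
        ("weibull_shape", 0.0, "weibull_shape"),
    ],
)
def test_invalid_config_error_names_field(field, value, match):
    cfg = SimulationConfig(**{field: value})
    with pytest.raises(ConfigurationError, match=match):
        cfg.validate()


def test_subgroup_prevalences_must_sum_to_at_most_one():
    cfg = SimulationConfig(subgroup_spec=[(("TP53",), 0.7, 0.5), (("TET2",), 0.5, 0.1)])
    with pytest.raises(ConfigurationError, match="prevalences"):
        cfg.validate()


def test_fixed_seed_reproduces_tables_exactly():
    cfg = SimulationConfig(n_patients=80, n_genes=20, n_windows=5, seed=42)
    a = simulate_cohort(cfg)
    b = simulate_cohort(SimulationConfig(n_patients=80, n_genes=20, n_windows=5, seed=42))
    for x, y in zip(a[:3], b[:3]):
        pd.testing.assert_frame_equal(x, y)
    assert a[3] == b[3]


def test_neutral_region_carrier_fraction_within_binomial_bounds():
    """Empirical carrier fraction of every neutral region within 3 binomial SDs."""
    cfg = SimulationConfig(n_patients=500, n_genes=50, n_windows=10, carrier_freq=0.1, seed=7)
    _, _, _, truth = simulate_cohort(cfg)
    sd = np.sqrt(0.1 * 0.9 / 500)
    for rid in truth["region_ids"]:
        frac = len(truth["carrier_matrix"][rid]) / 500
        assert abs(frac - 0.1) < 3 * sd, rid


def test_outcome_table_invariants(base_cohort):
    o = base_cohort["outcomes"]
    assert (o["os_time"] > 0).all() and (o["dfs_time"] > 0).all()
    assert (o["dfs_time"] <= o["os_time"] + 1e-12).all()
    assert set(o["first_event_code"]) <= {0, 1, 2}
    # a relapse first event never coincides with an OS death at an earlier time
    relapse = o["first_event_code"] == 1
    assert (o.loc[relapse, "dfs_time"] <= o.loc[relapse, "os_time"]).all()


def test_competing_risks_degenerate_and_balanced_cases():
    cfg = SimulationConfig(n_patients=4000, seed=1).validate()
    rng = np.random.default_rng(0)
    zeros = np.zeros(4000)

    # relapse hazard zero -> no relapse events at all
    cfg.competing_fractions = {"relapse": 0.0, "trm": 1.0}
    o = simulate_competing_risks(zeros, zeros, cfg, rng)
    assert not (o["first_event_code"] == 1).any()

    # equal cause-specific hazards -> ~50/50 split among events
    cfg.competing_fractions = {"relapse": 1.0, "trm": 1.0}
    o = simulate_competing_risks(zeros, zeros, cfg, np.random.default_rng(2))
    events = o[o["first_event_code"] > 0]
    frac_relapse = (events["first_event_code"] == 1).mean()
    sd = np.sqrt(0.25 / len(events))
    assert abs(frac_relapse - 0.5) < 4 * sd

    # all hazards zero is impossible to simulate
    cfg.competing_fractions = {"relapse": 0.0, "trm": 0.0}
    with pytest.raises(ConfigurationError, match="hazard"):
        simulate_competing_risks(zeros, zeros, cfg, rng)


def test_extreme_censoring_censors_everything():
    cfg = SimulationConfig(n_patients=500, censoring_rate=1e4, seed=3).validate()
    o = simulate_competing_risks(np.zeros(500), np.zeros(500), cfg, np.random.default_rng(1))
    assert (o["first_event_code"] == 0).all()
    assert o["os_time"].max() < 0.01  # censoring times collapse toward zero


def test_null_km_matches_exponential_survivor_function():
    """Marginal KM of OS under the null lies on exp(-lambda t) within pointwise bands."""
    from lifelines import KaplanMeierFitter

    lam = 0.02
    cfg = SimulationConfig(
        n_patients=2000, n_genes=5, n_windows=2, baseline_hazard=lam,
        censoring_rate=0.0, admin_censor_time=1e6,
        clinical_effects={}, seed=21,
    )
    _, _, o, _ = simulate_cohort(cfg)
    kmf = KaplanMeierFitter().fit(o["os_time"], o["os_event"])
    grid = np.linspace(5, 120, 24)
    ci = kmf.confidence_interval_survival_function_
    lo = np.interp(grid, ci.index.values, ci.iloc[:, 0].values)
    hi = np.interp(grid, ci.index.values, ci.iloc[:, 1].values)
    true = np.exp(-lam * grid)
    inside = (true >= lo) & (true <= hi)
    # 95% pointwise bands: allow a small number of exceedances on the grid
    assert inside.mean() >= 0.9


def test_planted_log_hazard_ratio_recovered_within_3_se():
    cfg = SimulationConfig(
        n_patients=1000, n_genes=20, n_windows=5,
        planted_effects=[("TP53", 0.9)], clinical_effects={}, seed=17,
    )
    _, _, o, truth = simulate_cohort(cfg)
    carrier = np.zeros(1000)
    carrier[truth["carrier_matrix"]["TP53"]] = 1
    fit = fit_cox(carrier, o["os_time"].to_numpy(), o["os_event"].to_numpy(bool))
    assert abs(fit.beta[0] - 0.9) < 3 * fit.se[0]


def test_written_vcf_is_valid_and_sorted(cohort_dir):
    res = subprocess.run(
        ["bcftools", "view", str(cohort_dir["vcf"])], capture_output=True, text=True
    )
    assert res.returncode == 0, res.stderr
    pos = {}
    for line in res.stdout.splitlines():
        if line.startswith("#"):
            continue
        chrom, p = line.split("\t")[:2]
        assert pos.get(chrom, 0) <= int(p), "coordinates not sorted"
        pos[chrom] = int(p)


def test_empty_cohort_refused(tmp_path, base_cohort):
    empty = base_cohort["clinical"].iloc[0:0]
    with pytest.raises(ValueError, match="0 patients"):
        write_cohort(empty, base_cohort["variants"], base_cohort["outcomes"].iloc[0:0],
                     base_cohort["truth"], tmp_path)
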