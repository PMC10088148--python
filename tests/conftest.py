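import numpy as np
import pytest

from mdswgs.aggregate import CarrierMatrix, Region
from mdswgs.simulate import DEFAULT_SUBGROUP_SPEC, SimulationConfig, simulate_cohort


def truth_matrix(truth) -> CarrierMatrix:
    """Carrier matrix reconstructed from a cohort's truth record."""
    rids = truth["region_ids"]
    n = len(truth["patient_ids"])
    vals = np.zeros((n, len(rids)), np.int8)
    for j, r in enumerate(rids):
        vals[truth["carrier_matrix"][r], j] = 1
    regions = [
        Region(r["region_id"], r["chrom"], r["start"], r["end"], "gene_all", r["region_id"])
        for r in truth["regions"]
    ]
    return CarrierMatrix(truth["patient_ids"], regions, vals)


@pytest.fixture(scope="session")
def base_cohort():
    """Mid-size cohort with a planted TP53 effect and the default 4 subgroups."""
    cfg = SimulationConfig(
        n_patients=300,
        n_genes=60,
        n_windows=10,
        planted_effects=[("TP53", 0.9)],
        subgroup_spec=DEFAULT_SUBGROUP_SPEC,
        seed=123,
    )
    clinical, variants, outcomes, truth = simulate_cohort(cfg)
    return {
        "config": cfg,
        "clinical": clinical,
        "variants": variants,
        "outcomes": outcomes,
        "truth": truth,
        "matrix": truth_matrix(truth),
    }


@pytest.fixture(scope="session")
def cohort_dir(base_cohort, tmp_path_factory):
    """The same cohort serialised to VCF + TSVs."""
    from mdswgs.simulate import write_cohort

    out = tmp_path_factory.mktemp("cohort")
    paths = write_cohort(
        base_cohort["clinical"],
        base_cohort["variants"],
        base_cohort["outcomes"],
        base_cohort["truth"],
        out,
    )
    return paths
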