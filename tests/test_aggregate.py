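"""Variant reading, region collapse, window tiling and carrier filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdswgs.aggregate import (
    NONSYN,
    CarrierMatrix,
    Region,
    Variant,
    build_windows,
    collapse_by_gene,
    collapse_by_regions,
    filter_min_carriers,
    read_bed,
    read_vcf,
)

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1,length=100000>
##INFO=<ID=CONSEQ,Number=1,Type=String,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""


def write_vcf(tmp_path, body, header=VCF_HEADER):
    p = tmp_path / "t.vcf"
    p.write_text(header + body)
    return p


def test_single_het_call_gives_one_variant_one_carrier(tmp_path):
    p = write_vcf(tmp_path, "1\t100\t.\tA\tG\t.\t.\tCONSEQ=other\tGT\t0/1\t0/0\t0/0\n")
    variants, samples = read_vcf(p)
    assert samples == ["S1", "S2", "S3"]
    assert len(variants) == 1
    v = variants[0]
    assert (v.chrom, v.pos, v.ref, v.alt) == ("1", 100, "A", "G")
    assert v.carrier_ids == frozenset({"S1"})


def test_multiallelic_site_split_per_alt(tmp_path):
    p = write_vcf(tmp_path, "1\t200\t.\tA\tC,T\t.\t.\t.\tGT\t0/1\t0/2\t1/2\n")
    variants, _ = read_vcf(p)
    assert len(variants) == 2
    by_alt = {v.alt: v.carrier_ids for v in variants}
    assert by_alt["C"] == frozenset({"S1", "S3"})
    assert by_alt["T"] == frozenset({"S2", "S3"})
    assert all(v.pos == 200 for v in variants)


def test_missing_gt_format_is_an_error(tmp_path):
    header = VCF_HEADER.replace(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n', ""
    )
    p = write_vcf(tmp_path, "", header=header)
    with pytest.raises(ValueError, match="GT"):
        read_vcf(p)


def test_unknown_sample_subset_lists_missing_ids(tmp_path):
    p = write_vcf(tmp_path, "1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\t0/0\t0/0\n")
    with pytest.raises(ValueError, match="S9"):
        read_vcf(p, sample_subset=["S1", "S9"])


GENE = [Region("G1", "1", 50, 150, "gene_all", "G1")]


def make_variant(pos, carriers, conseq="other"):
    return Variant("1", pos, "A", "G", conseq, frozenset(carriers))


def test_consequence_filter_excludes_other_class():
    variants = [make_variant(100, {"S1"}, "other")]
    m = collapse_by_gene(variants, GENE, ["S1", "S2"], consequence_filter=NONSYN)
    assert m.values.sum() == 0


def test_two_variants_same_gene_binarise_to_one():
    variants = [make_variant(100, {"S1"}), make_variant(120, {"S1"})]
    m = collapse_by_gene(variants, GENE, ["S1", "S2"])
    assert m.values[0, 0] == 1 and m.values.sum() == 1


def test_variant_outside_all_regions_is_tallied_not_fatal():
    variants = [make_variant(5000, {"S1"})]
    m = collapse_by_gene(variants, GENE, ["S1"])
    assert m.values.sum() == 0  # silently outside; logged by the module


def test_collapse_order_independent(base_cohort):
    variants = []
    for _, row in base_cohort["variants"].iterrows():
        variants.append(
            Variant(row["chrom"], row["pos"], row["ref"], row["alt"],
                    row["consequence"], frozenset(row["carrier_ids"]))
        )
    regions = [
        Region(r["region_id"], r["chrom"], r["start"], r["end"], "gene_all", r["region_id"])
        for r in base_cohort["truth"]["regions"]
    ]
    patients = base_cohort["truth"]["patient_ids"]
    a = collapse_by_regions(variants, regions, patients)
    b = collapse_by_regions(variants[::-1], regions, patients)
    np.testing.assert_array_equal(a.values, b.values)


def test_nonsyn_carriers_subset_of_all_carriers(base_cohort, cohort_dir):
    variants, samples = read_vcf(cohort_dir["vcf"])
    genes = [r for r in read_bed(cohort_dir["regions_bed"]) if not r.region_id.startswith("W")]
    m_all = collapse_by_gene(variants, genes, samples)
    m_nonsyn = collapse_by_gene(variants, genes, samples, consequence_filter=NONSYN)
    assert m_all.region_ids == m_nonsyn.region_ids
    assert (m_nonsyn.values <= m_all.values).all()


def test_roundtrip_matches_generator_truth(base_cohort, cohort_dir):
    variants, samples = read_vcf(cohort_dir["vcf"])
    regions = read_bed(cohort_dir["regions_bed"])
    m = collapse_by_gene(variants, regions, samples)
    truth = base_cohort["truth"]["carrier_matrix"]
    for j, rid in enumerate(m.region_ids):
        assert set(np.flatnonzero(m.values[:, j])) == set(truth[rid]), rid


def test_window_arithmetic_examples():
    wins = build_windows({"c": 100}, 50, 25)
    assert [(w.start, w.end) for w in wins] == [(1, 50), (26, 75), (51, 100)]
    tiles = build_windows({"c": 120}, 50, 50)
    assert len(tiles) == -(-120 // 50)  # ceil(L / size)
    assert [(w.start, w.end) for w in tiles] == [(1, 50), (51, 100), (101, 120)]


def test_step_greater_than_size_rejected():
    with pytest.raises(ValueError, match="step"):
        build_windows({"c": 100}, 10, 20)


@given(
    length=st.integers(1, 5000),
    size=st.integers(1, 400),
    step_frac=st.floats(0.1, 1.0),
)
@settings(max_examples=60, deadline=None)
def test_every_position_covered_when_step_le_size(length, size, step_frac):
    step = max(1, int(size * step_frac))
    wins = build_windows({"c": length}, size, step)
    covered = np.zeros(length + 1, dtype=int)
    for w in wins:
        covered[w.start : w.end + 1] += 1
    assert (covered[1:] >= 1).all()
    if step == size:  # non-overlapping tiling partitions positions exactly once
        assert (covered[1:] == 1).all()


def test_min_carrier_filter_semantics():
    vals = np.zeros((10, 3), dtype=np.int8)
    vals[:2, 0] = 1   # 2 carriers
    vals[:5, 1] = 1   # 5 carriers
    vals[:9, 2] = 1   # 9 carriers -> only 1 non-carrier
    m = CarrierMatrix(
        [f"P{i}" for i in range(10)],
        [Region(f"R{j}", "1", 1, 10, "gene_all", f"R{j}") for j in range(3)],
        vals,
    )
    assert filter_min_carriers(m, 1).region_ids == ["R0", "R1", "R2"]
    assert filter_min_carriers(m, 3).region_ids == ["R1"]
    with pytest.raises(ValueError, match="k_min"):
        filter_min_carriers(m, 0)


@given(st.integers(1, 6))
@settings(max_examples=6, deadline=None)
def test_min_carrier_filter_monotone(k):
    rng = np.random.default_rng(0)
    vals = rng.binomial(1, 0.3, (20, 15)).astype(np.int8)
    m = CarrierMatrix(
        [f"P{i}" for i in range(20)],
        [Region(f"R{j}", "1", 1, 10, "gene_all", f"R{j}") for j in range(15)],
        vals,
    )
    stricter = set(filter_min_carriers(m, k + 1).region_ids)
    looser = set(filter_min_carriers(m, k).region_ids)
    assert stricter <= looser


def test_carrier_matrix_tsv_roundtrip(tmp_path, base_cohort):
    m = base_cohort["matrix"]
    m.to_tsv(tmp_path / "m.tsv")
    back = CarrierMatrix.from_tsv(tmp_path / "m.tsv")
    assert back.patients == m.patients
    assert back.region_ids == m.region_ids
    np.testing.assert_array_equal(back.values, m.values)


def test_bed_intervals_merged_per_gene(tmp_path):
    p = tmp_path / "g.bed"
    p.write_text("1\t0\t100\tG1\n1\t50\t200\tG1\n1\t500\t600\tG2\n")
    regions = read_bed(p)
    g1 = [r for r in regions if r.region_id == "G1"]
    assert len(g1) == 1 and (g1[0].start, g1[0].end) == (1, 200)
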