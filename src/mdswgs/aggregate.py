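"""Collapse somatic variant calls into per-patient, per-region carrier status.

Three region schemes mirror the genome-scan designs used downstream:
gene-based on nonsynonymous coding variants only (``gene_nonsyn``),
gene-based on all variants (``gene_all``), and genome-wide sliding windows
(``window``). A patient "carries" a region when at least one qualifying
variant with at least one alternate allele falls inside it — the standard
burden-test collapse.

Coordinate conventions: everything in memory is 1-based inclusive. BED input
(0-based half-open) is converted on read; VCF positions are 1-based already.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from intervaltree import IntervalTree

__all__ = [
    "Variant",
    "Region",
    "CarrierMatrix",
    "read_vcf",
    "read_bed",
    "read_genome_layout",
    "collapse_by_regions",
    "collapse_by_gene",
    "build_windows",
    "filter_min_carriers",
]

logger = logging.getLogger(__name__)

NONSYN = "nonsynonymous_coding"
DEFAULT_CONSEQUENCE_TAG = "CONSEQ"


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    consequence: str  # NONSYN or "other"
    carrier_ids: frozenset


@dataclass(frozen=True)
class Region:
    region_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    scheme: str  # gene_nonsyn | gene_all | window
    label: str = ""


@dataclass
class CarrierMatrix:
    """Binary patients x regions incidence matrix with aligned orderings."""

    patients: list
    regions: list  # list[Region]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.patients), len(self.regions)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.patients)} patients x {len(self.regions)} regions"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("carrier matrix values must be 0/1")

    @property
    def region_ids(self) -> list:
        return [r.region_id for r in self.regions]

    @property
    def n_carriers(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patients, columns=self.region_ids)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "patient_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, scheme: str = "gene_all") -> "CarrierMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        regions = [Region(c, ".", 1, 1, scheme, c) for c in df.columns]
        return cls(list(df.index), regions, df.to_numpy())


def read_vcf(path, sample_subset=None, consequence_tag: str = DEFAULT_CONSEQUENCE_TAG):
    """Read a multi-sample VCF into :class:`Variant` records.

    One record is produced per ALT allele per site (multi-allelic sites are
    split); carriers are the samples with at least one copy of that ALT.
    Sites where no requested sample carries the ALT are dropped (they have no
    bearing on any carrier matrix). Returns ``(variants, samples)`` with
    ``samples`` in VCF column order (restricted to ``sample_subset`` if given).
    """
    vcf = VCF(str(path), gts012=False)
    header_samples = list(vcf.samples)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in header_samples]
        if missing:
            raise ValueError(f"samples not present in VCF header: {missing}")
        keep = [s for s in header_samples if s in set(sample_subset)]
    else:
        keep = header_samples
    keep_idx = np.array([header_samples.index(s) for s in keep], dtype=int)

    if "GT" not in vcf:
        raise ValueError(f"{path}: VCF has no GT FORMAT field; carrier status undefined")

    variants = []
    for rec in vcf:
        # genotype allele indices, shape (n_samples, ploidy)
        gts = np.array([g[:-1] for g in rec.genotypes], dtype=int)[keep_idx]
        conseq = rec.INFO.get(consequence_tag)
        conseq = NONSYN if conseq == NONSYN else "other"
        for alt_index, alt in enumerate(rec.ALT, start=1):
            carrier_mask = (gts == alt_index).any(axis=1)
            if not carrier_mask.any():
                continue
            variants.append(
                Variant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    consequence=conseq,
                    carrier_ids=frozenset(np.array(keep)[carrier_mask].tolist()),
                )
            )
    return variants, keep


def read_bed(path, scheme: str = "gene_all"):
    """Read gene/region definitions from BED (name column = region id).

    Intervals sharing a name are merged per chromosome so each region id maps
    to a set of disjoint 1-based inclusive intervals, returned as one
    :class:`Region` per merged interval.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: BED line needs >= 4 columns (chrom,start,end,name)")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            rows.append((name, chrom, start + 1, end))  # to 1-based inclusive
    merged = []
    df = pd.DataFrame(rows, columns=["name", "chrom", "start", "end"])
    for (name, chrom), grp in df.groupby(["name", "chrom"], sort=False):
        ivs = sorted(zip(grp["start"], grp["end"]))
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                merged.append(Region(name, chrom, cur_s, cur_e, scheme, name))
                cur_s, cur_e = s, e
        merged.append(Region(name, chrom, cur_s, cur_e, scheme, name))
    return merged


def read_genome_layout(path) -> dict:
    """Chromosome lengths from a two-column TSV (chrom, length)."""
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "length"} <= set(df.columns):
        raise ValueError(f"{path}: genome layout needs 'chrom' and 'length' columns")
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def build_windows(genome_layout: dict, window_size: int, step: int):
    """Tile every chromosome with sliding windows.

    Windows start at 1 and advance by ``step``; the last window is clipped at
    the chromosome end. Ids are deterministic ``chrom:start-end``. With
    ``step == window_size`` the windows partition the chromosome.
    """
    if step < 1 or window_size < 1:
        raise ValueError("window_size and step must be >= 1")
    if step > window_size:
        raise ValueError(f"step ({step}) must not exceed window_size ({window_size})")
    regions = []
    for chrom, length in genome_layout.items():
        if length < 1:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        n_win = max(1, -(-(length - window_size) // step) + 1) if length > window_size else 1
        for i in range(n_win):
            start = 1 + i * step
            end = min(start + window_size - 1, length)
            regions.append(
                Region(f"{chrom}:{start}-{end}", str(chrom), start, end, "window", f"{chrom}:{i}")
            )
    return regions


def collapse_by_regions(variants, regions, patients, consequence_filter=None) -> CarrierMatrix:
    """Binary collapse: patient carries region iff >= 1 qualifying variant inside.

    A variant overlapping several regions (e.g. overlapping sliding windows)
    contributes to each. Variants outside all regions are tallied and logged,
    never an error. ``consequence_filter`` restricts to one consequence class
    (e.g. ``"nonsynonymous_coding"``).
    """
    pat_index = {p: i for i, p in enumerate(patients)}
    trees = {}
    for j, r in enumerate(regions):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1, j)
    values = np.zeros((len(patients), len(regions)), dtype=np.int8)
    n_outside = 0
    n_filtered = 0
    for v in variants:
        if consequence_filter is not None and v.consequence != consequence_filter:
            n_filtered += 1
            continue
        tree = trees.get(v.chrom)
        hits = tree[v.pos] if tree is not None else set()
        if not hits:
            n_outside += 1
            continue
        rows = [pat_index[p] for p in v.carrier_ids if p in pat_index]
        for h in hits:
            values[rows, h.data] = 1
    logger.info(
        "collapse: %d variants -> %d regions (%d outside all regions, %d failed consequence filter)",
        len(variants), len(regions), n_outside, n_filtered,
    )
    return CarrierMatrix(list(patients), list(regions), values)


def collapse_by_gene(variants, gene_regions, patients, consequence_filter=None) -> CarrierMatrix:
    """Gene-level collapse over (merged) BED gene intervals.

    Multiple intervals of one gene are OR-ed into a single gene column, so
    each gene appears once regardless of how many merged intervals define it.
    """
    per_interval = collapse_by_regions(variants, gene_regions, patients, consequence_filter)
    scheme = "gene_nonsyn" if consequence_filter == NONSYN else "gene_all"
    order = list(dict.fromkeys(r.region_id for r in gene_regions))
    cols = {rid: np.zeros(len(patients), dtype=np.int8) for rid in order}
    for j, r in enumerate(gene_regions):
        np.maximum(cols[r.region_id], per_interval.values[:, j], out=cols[r.region_id])
    regions = []
    for rid in order:
        ivs = [r for r in gene_regions if r.region_id == rid]
        regions.append(
            Region(rid, ivs[0].chrom, min(r.start for r in ivs), max(r.end for r in ivs),
                   scheme, rid)
        )
    values = np.column_stack([cols[rid] for rid in order]) if order else np.zeros((len(patients), 0), dtype=np.int8)
    return CarrierMatrix(list(patients), regions, values)


def filter_min_carriers(matrix: CarrierMatrix, k_min: int) -> CarrierMatrix:
    """Drop regions with fewer than ``k_min`` carriers or non-carriers.

    Near-monomorphic regions carry no usable survival contrast; both tails
    are removed symmetrically. The removal is logged with counts.
    """
    if k_min < 1:
        raise ValueError(f"k_min must be >= 1, got {k_min}")
    n = len(matrix.patients)
    counts = matrix.n_carriers
    keep = (counts >= k_min) & (counts <= n - k_min)
    dropped = int((~keep).sum())
    logger.info(
        "filter_min_carriers(k_min=%d): kept %d / %d regions (dropped %d)",
        k_min, int(keep.sum()), len(matrix.regions), dropped,
    )
    return CarrierMatrix(
        matrix.patients,
        [r for r, k in zip(matrix.regions, keep) if k],
        matrix.values[:, keep],
    )
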