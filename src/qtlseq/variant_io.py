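"""VCF input and tabular output for the bulk-segregant scan.

Reads a four-sample VCF (two parents, two bulks) into parent-oriented
per-site records: at each retained site the "index allele" is the allele
NOT carried by the short-mesocotyl (recurrent) parent, so a QTL for the
high phenotype shows a high SNP-index in the high bulk. Only sites where
the two parents are homozygous for different alleles are informative;
everything else is dropped with a per-reason tally.

Coordinates are 1-based internally (VCF convention); BED output converts
to 0-based half-open.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "BulkSite",
    "IndelVariant",
    "VcfReadResult",
    "read_bulk_vcf",
    "sites_to_frame",
    "sim_sites_to_frame",
    "write_site_table",
    "read_site_table",
    "write_window_table",
    "write_region_table",
    "write_region_bed",
]

# full round-trip precision for floats in TSV output
_FLOAT_FMT = "%.17g"

SITE_COLUMNS = ["chrom", "pos", "index_high", "index_low", "delta",
                "depth_high", "depth_low", "G"]


@dataclass(frozen=True)
class BulkSite:
    """One biallelic SNP with parent-oriented bulk allele depths.

    Depth pairs are (recurrent-parent-allele reads, other-allele reads);
    "other" is the index allele. GQ is None when the caller emitted none.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    index_allele_is_alt: bool
    high_depths: tuple[int, int]
    low_depths: tuple[int, int]
    high_gq: float | None
    low_gq: float | None


@dataclass(frozen=True)
class IndelVariant:
    """A parent-polymorphic InDel kept aside for marker design.

    ``length`` is signed: positive insertions, negative deletions,
    relative to the reference allele.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    length: int


@dataclass
class VcfReadResult:
    sites: list[BulkSite]
    indels: list[IndelVariant]
    dropped: Counter

    @property
    def n_input(self) -> int:
        return len(self.sites) + len(self.indels) + sum(self.dropped.values())


def _parent_hom_allele(gt: list) -> int | None:
    """Allele index if the genotype is a called homozygote, else None."""
    alleles = gt[:-1]  # last element is the phased flag
    if any(a is None or a < 0 for a in alleles):
        return None
    if len(set(alleles)) != 1:
        return None
    return alleles[0]


def read_bulk_vcf(path, parent_short_sample: str, parent_long_sample: str,
                  high_sample: str, low_sample: str) -> VcfReadResult:
    """Read a bulk/parent VCF into oriented :class:`BulkSite` records.

    Keeps biallelic SNPs where the parents are homozygous for different
    alleles; orients each so the index allele is the long-parent allele.
    Biallelic parent-polymorphic InDels are returned separately for the
    marker-design stage. Multiallelic, parent-missing and non-polymorphic
    sites are dropped and tallied by reason.

    Raises ``ValueError`` if the VCF has no AD FORMAT field.
    """
    vcf = VCF(str(path))
    samples = vcf.samples
    try:
        idx = {name: samples.index(name)
               for name in (parent_short_sample, parent_long_sample,
                            high_sample, low_sample)}
    except ValueError as e:
        raise ValueError(f"sample not found in VCF: {e}") from None

    sites: list[BulkSite] = []
    indels: list[IndelVariant] = []
    dropped: Counter = Counter()

    for v in vcf:
        if len(v.ALT) != 1:
            dropped["multiallelic"] += 1
            continue
        ad = v.format("AD")
        if ad is None:
            raise ValueError(f"AD FORMAT field missing at {v.CHROM}:{v.POS}")

        gts = v.genotypes
        a_short = _parent_hom_allele(gts[idx[parent_short_sample]])
        a_long = _parent_hom_allele(gts[idx[parent_long_sample]])
        if a_short is None or a_long is None:
            dropped["parent_missing"] += 1
            continue
        if a_short == a_long:
            dropped["non_polymorphic"] += 1
            continue

        ref, alt = v.REF, v.ALT[0]
        if len(ref) != len(alt):
            indels.append(IndelVariant(v.CHROM, v.POS, ref, alt,
                                       len(alt) - len(ref)))
            continue
        if len(ref) != 1:
            dropped["non_snp"] += 1
            continue

        gq = v.gt_quals

        def oriented(sample: str) -> tuple[int, int]:
            a = ad[idx[sample]]
            ref_d, alt_d = max(int(a[0]), 0), max(int(a[1]), 0)
            # recurrent allele = the short parent's allele
            if a_short == 0:
                return ref_d, alt_d
            return alt_d, ref_d

        def gq_of(sample: str) -> float | None:
            q = float(gq[idx[sample]])
            return None if q < 0 else q

        sites.append(BulkSite(
            chrom=v.CHROM, pos=v.POS, ref=ref, alt=alt,
            index_allele_is_alt=(a_short == 0),
            high_depths=oriented(high_sample),
            low_depths=oriented(low_sample),
            high_gq=gq_of(high_sample),
            low_gq=gq_of(low_sample),
        ))

    return VcfReadResult(sites, indels, dropped)


def sites_to_frame(sites: Iterable[BulkSite]) -> pd.DataFrame:
    """Flatten BulkSite records into the scan's working DataFrame."""
    rows = [(s.chrom, s.pos, s.high_depths[0], s.high_depths[1],
             s.low_depths[0], s.low_depths[1],
             np.nan if s.high_gq is None else s.high_gq,
             np.nan if s.low_gq is None else s.low_gq)
            for s in sites]
    return pd.DataFrame(rows, columns=["chrom", "pos", "high_rec", "high_other",
                                       "low_rec", "low_other", "gq_high", "gq_low"])


def sim_sites_to_frame(sim_sites: Iterable) -> pd.DataFrame:
    """Oriented site frame directly from simulator output (``SimSite``),
    bypassing the VCF round-trip for large in-memory runs."""
    rows = []
    for s in sim_sites:
        if s.long_allele_is_alt:
            hr, ho = s.high_ad
            lr, lo = s.low_ad
        else:
            ho, hr = s.high_ad
            lo, lr = s.low_ad
        rows.append((s.chrom, s.pos, hr, ho, lr, lo,
                     float(s.high_gq), float(s.low_gq)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "high_rec", "high_other",
                                       "low_rec", "low_other", "gq_high", "gq_low"])


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT,
              lineterminator="\n")


def write_site_table(records: pd.DataFrame, path) -> None:
    """Per-site SNP-index table (chrom, pos, indices, delta, depths, G)."""
    _write_tsv(records[SITE_COLUMNS], path)


def read_site_table(path) -> pd.DataFrame:
    # round_trip parsing so %.17g output re-reads bit-exactly
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_window_table(windows: pd.DataFrame, path) -> None:
    _write_tsv(windows, path)


def _regions_frame(regions: Sequence) -> pd.DataFrame:
    from .scan import QTLRegion  # late import to avoid a cycle

    rows = [(r.chrom, r.start, r.end, r.length, r.pos_max_g, r.pos_max_delta,
             r.peak_delta, r.peak_g, r.n_windows) for r in regions]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "length",
                                       "pos_max_G", "pos_max_delta",
                                       "peak_delta", "peak_G", "n_windows"])


def write_region_table(regions: Sequence, path) -> None:
    """Candidate-region TSV (1-based inclusive coordinates)."""
    _write_tsv(_regions_frame(regions), path)


def write_region_bed(regions: Sequence, path) -> None:
    """Candidate regions as BED: 0-based half-open, with peak positions,
    peak values and window count as extra columns."""
    df = _regions_frame(regions)
    bed = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"] - 1,
        "end": df["end"],
        "pos_max_G": df["pos_max_G"],
        "pos_max_delta": df["pos_max_delta"],
        "peak_delta": df["peak_delta"],
        "peak_G": df["peak_G"],
        "n_windows": df["n_windows"],
    })
    bed.to_csv(path, sep="\t", index=False, header=False,
               float_format=_FLOAT_FMT, lineterminator="\n")
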