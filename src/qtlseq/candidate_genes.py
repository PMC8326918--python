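"""Candidate-gene triage around a QTL peak and relative-expression
(2^-ΔΔCt) calculation.

Genes inside the linkage-disequilibrium flank of a peak are tiered:

* Tier 1 — annotation is informative (not an "expressed/hypothetical/
  transposon/retrotransposon protein" placeholder) and the gene carries
  at least one nonsynonymous coding variant;
* Tier 2 — a qualifying variant is carried identically (homozygous) by
  every co-localized donor parent;
* Tier 3 ("high confidence") — the annotation additionally matches a
  phytohormone-pathway keyword (mesocotyl elongation is hormone
  regulated).

Tiers are nested (3 ⊆ 2 ⊆ 1); every flank gene lands in exactly one
partition cell: its highest tier or an exclusion reason.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneVariant",
    "GeneRecord",
    "TriageConfig",
    "TriageResult",
    "triage_genes",
    "DdctResult",
    "fold_change_ddct",
    "read_gene_table",
]

EXCLUDED_KEYWORDS = ("expressed protein", "hypothetical protein",
                     "transposon protein", "retrotransposon protein")
PRIORITY_KEYWORDS = ("strigolactone", "cytokinin", "brassinosteroid", "abscisic",
                     "jasmonate", "gibberellin", "auxin", "ethylene",
                     "cellulose synthase")

CodingEffect = Literal["synonymous", "missense", "noncoding"]


@dataclass(frozen=True)
class GeneVariant:
    """A variant inside a gene: ``effect`` is 'missense' for any
    nonsynonymous coding change, 'synonymous', or 'noncoding';
    ``carriers`` maps donor-parent name -> zygosity
    ('hom' / 'het' / 'absent') for the non-reference allele."""

    position: int
    effect: str
    carriers: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int
    end: int
    annotation: str
    variants: tuple[GeneVariant, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")


@dataclass(frozen=True)
class TriageConfig:
    flank: int = 150_000
    excluded_keywords: tuple[str, ...] = EXCLUDED_KEYWORDS
    priority_keywords: tuple[str, ...] = PRIORITY_KEYWORDS
    allow_het_carriers: bool = False

    def __post_init__(self) -> None:
        if self.flank <= 0:
            raise ValueError("flank must be > 0")


@dataclass
class TriageResult:
    tier1: list[GeneRecord]
    tier2: list[GeneRecord]
    tier3: list[GeneRecord]
    exclusions: list[tuple[str, str]]  # (gene_id, reason)

    def partition(self) -> dict[str, str]:
        """Each in-flank gene -> its highest tier or exclusion reason."""
        out = {g: reason for g, reason in self.exclusions}
        for g in self.tier1:
            out[g.gene_id] = "tier1"
        for g in self.tier2:
            out[g.gene_id] = "tier2"
        for g in self.tier3:
            out[g.gene_id] = "tier3"
        return out


def _matches(annotation: str, keywords: Sequence[str]) -> bool:
    text = annotation.lower()
    return any(k.lower() in text for k in keywords)


def _shared_by_all(variant: GeneVariant, parents: Sequence[str],
                   allow_het: bool) -> bool:
    ok = {"hom", "het"} if allow_het else {"hom"}
    return all(variant.carriers.get(p, "absent") in ok for p in parents)


def triage_genes(genes: Sequence[GeneRecord], peak_chrom: str, peak: int,
                 cfg: TriageConfig = TriageConfig(),
                 co_localized_parents: Sequence[str] = ()) -> TriageResult:
    """Tier genes in [peak − flank, peak + flank] on the peak chromosome.

    A gene overlaps the flank iff its span intersects the interval. With
    no co-localized parents listed, the parent-sharing condition is
    vacuously true and Tier 2 equals Tier 1.
    """
    lo, hi = peak - cfg.flank, peak + cfg.flank
    tier1: list[GeneRecord] = []
    tier2: list[GeneRecord] = []
    tier3: list[GeneRecord] = []
    exclusions: list[tuple[str, str]] = []

    for g in genes:
        if g.chrom != peak_chrom or g.end < lo or g.start > hi:
            continue  # outside the flank: not part of the triage universe
        if _matches(g.annotation, cfg.excluded_keywords):
            exclusions.append((g.gene_id, "annotation"))
            continue
        qualifying = [v for v in g.variants if v.effect == "missense"]
        if not qualifying:
            exclusions.append((g.gene_id, "no_coding_change"))
            continue
        tier1.append(g)
        if any(_shared_by_all(v, co_localized_parents, cfg.allow_het_carriers)
               for v in qualifying):
            tier2.append(g)
            if _matches(g.annotation, cfg.priority_keywords):
                tier3.append(g)

    return TriageResult(tier1=tier1, tier2=tier2, tier3=tier3,
                        exclusions=exclusions)


@dataclass(frozen=True)
class DdctResult:
    """Relative expression of a gene in a target vs reference sample."""

    gene: str
    target_sample: str
    reference_sample: str
    ddct: float                     # mean ΔCt(target) − mean ΔCt(reference)
    fold_change: float              # 2^(−ΔΔCt)
    ddct_replicates: tuple[float, ...]
    t_statistic: float
    p_value: float

    @property
    def significance(self) -> str:
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def fold_change_ddct(ct: pd.DataFrame, gene: str, target_sample: str,
                     reference_sample: str, control_gene: str = "control") -> DdctResult:
    """2^-ΔΔCt relative expression with an internal-control gene.

    ``ct`` needs columns sample, gene, replicate, ct. Per replicate of a
    sample, ΔCt = Ct(gene) − Ct(control gene); ΔΔCt is the difference of
    sample mean ΔCt values (target − reference) and the fold change is
    2^(−ΔΔCt). Replicate ΔCt values of the two samples feed a two-sample
    t-test for the * (p<0.05) / ** (p<0.01) flags; at least 2 replicates
    per sample are required for the test.

    Raises ``ValueError`` if any target Ct lacks its control Ct.
    """
    def delta_ct(sample: str) -> np.ndarray:
        sub = ct[ct["sample"] == sample]
        tgt = sub[sub["gene"] == gene].set_index("replicate")["ct"]
        ctl = sub[sub["gene"] == control_gene].set_index("replicate")["ct"]
        if tgt.empty:
            raise ValueError(f"no Ct values for gene {gene!r} in sample {sample!r}")
        missing = tgt.index.difference(ctl.index)
        if len(missing):
            raise ValueError(
                f"control gene {control_gene!r} Ct missing for sample "
                f"{sample!r} replicate(s) {sorted(missing)}")
        return (tgt - ctl.reindex(tgt.index)).to_numpy(dtype=float)

    d_t = delta_ct(target_sample)
    d_r = delta_ct(reference_sample)
    if len(d_t) < 2 or len(d_r) < 2:
        raise ValueError("need >= 2 replicates per sample for the t-test")
    ddct = float(d_t.mean() - d_r.mean())
    t_stat, p = stats.ttest_ind(d_t, d_r, equal_var=True)
    return DdctResult(
        gene=gene, target_sample=target_sample, reference_sample=reference_sample,
        ddct=ddct, fold_change=float(2.0 ** (-ddct)),
        ddct_replicates=tuple(float(x - d_r.mean()) for x in d_t),
        t_statistic=float(t_stat), p_value=float(p),
    )


def read_gene_table(gff_path, annotation_tsv, effects_tsv=None) -> list[GeneRecord]:
    """Assemble :class:`GeneRecord` objects from a GFF3 of gene features,
    a TSV of functional annotations (gene_id, annotation) and, optionally,
    a variant-effect TSV (gene_id, position, effect, parent, zygosity)."""
    import gffutils

    db = gffutils.create_db(str(gff_path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    ann = pd.read_csv(annotation_tsv, sep="\t").set_index("gene_id")["annotation"]
    variants: dict[str, list[GeneVariant]] = {}
    if effects_tsv is not None:
        eff = pd.read_csv(effects_tsv, sep="\t")
        for (gid, pos, effect), grp in eff.groupby(["gene_id", "position", "effect"]):
            carriers = dict(zip(grp["parent"], grp["zygosity"]))
            variants.setdefault(gid, []).append(
                GeneVariant(position=int(pos), effect=str(effect), carriers=carriers))
    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.id
        genes.append(GeneRecord(
            gene_id=gid, chrom=feat.seqid, start=feat.start, end=feat.end,
            annotation=str(ann.get(gid, "")),
            variants=tuple(variants.get(gid, ()))))
    return genes
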