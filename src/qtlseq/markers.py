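"""InDel-to-PCR marker bookkeeping and marker-trait association.

An InDel marker is a primer pair spanning an insertion/deletion inside a
candidate region; its two alleles amplify fragments differing by the
InDel length, scorable on an agarose gel when the difference is >= ~10 bp
and the fragments are not too large relative to the InDel (amplicon no
more than 10x the InDel length). Validation associates the marker
genotype groups with the phenotype by ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IndelMarker",
    "MarkerAssociation",
    "select_marker_indels",
    "amplicon_sizes",
    "check_size_ratio",
    "associate_marker",
    "associate_markers_two_way",
]


@dataclass(frozen=True)
class IndelMarker:
    """A PCR gel marker on an InDel. ``indel_length`` is signed (insertion
    in the alternate allele positive); amplicon sizes are in bp on the
    reference and alternate alleles."""

    name: str
    chrom: str
    pos: int
    indel_length: int
    primer_forward: str
    primer_reverse: str
    amplicon_size_ref: int
    amplicon_size_alt: int

    def __post_init__(self) -> None:
        if abs(self.amplicon_size_alt - self.amplicon_size_ref) != abs(self.indel_length):
            raise ValueError(
                f"{self.name}: amplicon size difference "
                f"{abs(self.amplicon_size_alt - self.amplicon_size_ref)} bp "
                f"does not equal |indel length| {abs(self.indel_length)} bp")
        primer_total = len(self.primer_forward) + len(self.primer_reverse)
        if min(self.amplicon_size_ref, self.amplicon_size_alt) <= primer_total:
            raise ValueError(f"{self.name}: amplicon smaller than combined primers")


def select_marker_indels(indels: Sequence, region, min_len: int = 10) -> list:
    """InDels inside ``region`` with |length| >= ``min_len`` (default 10 bp,
    the agarose-gel resolvability bound), sorted by distance to the
    region's Δ(SNP-index) peak."""
    hits = [v for v in indels
            if v.chrom == region.chrom and region.start <= v.pos <= region.end
            and abs(v.length) >= min_len]
    return sorted(hits, key=lambda v: (abs(v.pos - region.pos_max_delta), v.pos))


def amplicon_sizes(forward_start: int, reverse_end: int, indel_pos: int,
                   indel_length: int) -> tuple[int, int]:
    """Amplicon sizes on the two alleles for primers at reference
    coordinates ``forward_start``..``reverse_end`` (1-based inclusive)
    spanning an InDel.

    size_ref = reverse_end − forward_start + 1; the alternate allele adds
    the signed InDel length. Raises if the primers do not strictly span
    the InDel footprint.
    """
    if reverse_end <= forward_start:
        raise ValueError("reverse primer must end after the forward primer starts")
    footprint_end = indel_pos + (abs(indel_length) if indel_length < 0 else 0)
    if not (forward_start < indel_pos and footprint_end < reverse_end):
        raise ValueError(
            f"primers ({forward_start}-{reverse_end}) do not span the InDel "
            f"at {indel_pos} (footprint to {footprint_end})")
    size_ref = reverse_end - forward_start + 1
    return size_ref, size_ref + indel_length


def check_size_ratio(marker: IndelMarker, max_ratio: float = 10.0) -> tuple[bool, float]:
    """Gel-scorability rule: the larger amplicon may be at most
    ``max_ratio`` times the InDel length (inclusive boundary)."""
    if marker.indel_length == 0:
        raise ValueError("size ratio undefined for a zero-length indel")
    ratio = max(marker.amplicon_size_ref, marker.amplicon_size_alt) / abs(marker.indel_length)
    return ratio <= max_ratio, ratio


@dataclass(frozen=True)
class MarkerAssociation:
    """One-way ANOVA of phenotype on marker genotype groups."""

    marker: str
    group_means: Mapping[str, float]
    group_sizes: Mapping[str, int]
    mean_difference: float
    f_statistic: float
    p_value: float
    r_squared: float
    df_effect: int
    df_residual: int

    def __post_init__(self) -> None:
        if not (np.isnan(self.r_squared) or 0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("R^2 outside [0, 1]")


def _check_groups(labels: pd.Series) -> None:
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 genotype groups")
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"group(s) with < 2 observations: {list(small.index)}")


def associate_marker(haplotypes: Sequence[str], phenotypes: Sequence[float],
                     marker: str = "marker") -> MarkerAssociation:
    """One-way fixed-effects ANOVA of phenotype on haplotype group.

    F = MS_between / MS_within with p from the F distribution;
    R^2 = SS_between / SS_total. ``mean_difference`` is the spread between
    the extreme group means (for two groups: |mean difference|). With
    zero between-group variance F is 0 and p is 1.
    """
    df = pd.DataFrame({"hap": list(haplotypes), "y": np.asarray(phenotypes, float)})
    _check_groups(df["hap"])
    grand = df["y"].mean()
    groups = df.groupby("hap")["y"]
    means = groups.mean()
    sizes = groups.size()
    ss_between = float((sizes * (means - grand) ** 2).sum())
    ss_total = float(((df["y"] - grand) ** 2).sum())
    ss_within = ss_total - ss_between
    df_b = len(means) - 1
    df_w = len(df) - len(means)

    if ss_between <= 0.0:
        f_stat, p = 0.0, 1.0
    elif ss_within <= 0.0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f_stat, df_b, df_w))
    r2 = ss_between / ss_total if ss_total > 0 else float("nan")
    return MarkerAssociation(
        marker=marker,
        group_means=dict(means),
        group_sizes={k: int(v) for k, v in sizes.items()},
        mean_difference=float(means.max() - means.min()),
        f_statistic=float(f_stat),
        p_value=p,
        r_squared=float(r2),
        df_effect=df_b,
        df_residual=df_w,
    )


def associate_markers_two_way(data: pd.DataFrame, marker_a: str, marker_b: str,
                              phenotype: str = "phenotype") -> pd.DataFrame:
    """Two-way fixed-effects ANOVA with interaction for two markers.

    Expects one row per accession with columns ``marker_a``, ``marker_b``
    (haplotype labels) and ``phenotype``. Returns the ANOVA table
    (df, sum_sq, mean_sq, F, PR(>F), R2 per effect with
    R2 = SS_effect / SS_total, type-II sums of squares).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data.rename(columns={marker_a: "_a", marker_b: "_b",
                              phenotype: "_y"})[["_a", "_b", "_y"]].dropna()
    for col in ("_a", "_b"):
        _check_groups(df[col])
    model = smf.ols("_y ~ C(_a) + C(_b) + C(_a):C(_b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(index={"C(_a)": marker_a, "C(_b)": marker_b,
                                "C(_a):C(_b)": f"{marker_a}:{marker_b}"})
    table["mean_sq"] = table["sum_sq"] / table["df"]
    ss_total = float(((df["_y"] - df["_y"].mean()) ** 2).sum())
    table["R2"] = table["sum_sq"] / ss_total
    return table
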