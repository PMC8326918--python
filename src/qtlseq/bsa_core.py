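"""Per-site bulk-segregant statistics: SNP-index, site filters, Δ(SNP-index)
and the 2x2 G statistic.

The SNP-index of a bulk at a site is the fraction of its reads carrying
the allele not inherited from the recurrent (short-phenotype) parent;
Δ(SNP-index) = index(high bulk) − index(low bulk). G is the
log-likelihood-ratio statistic of allele x bulk independence on the
2x2 read-count table, G = 2·Σ obs·ln(obs/exp) with expectations from
the row x column marginals and 0·ln(0) ≡ 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FilterConfig",
    "snp_index",
    "delta_snp_index",
    "g_statistic",
    "g_statistic_arrays",
    "compute_site_stats",
    "apply_filters",
]


@dataclass(frozen=True)
class FilterConfig:
    """Site-filter thresholds.

    Clause 1 drops sites whose SNP-index is below ``low_index_threshold``
    in BOTH bulks, or (independently, the default reading) whose depth is
    below ``min_depth`` in either bulk; ``clause1_conjunctive=True`` instead
    requires both the low-index and low-depth conditions together.
    Clause 2 drops sites whose index is undefined (zero reads) in either
    bulk; clause 3 drops sites with GQ below ``min_gq`` (or missing GQ)
    in either bulk.
    """

    low_index_threshold: float = 0.2
    min_depth: int = 7
    min_gq: float = 20.0
    clause1_conjunctive: bool = False

    def __post_init__(self) -> None:
        if self.low_index_threshold < 0 or self.min_depth < 0 or self.min_gq < 0:
            raise ValueError("filter thresholds must be >= 0")


def snp_index(recurrent_reads: int, other_reads: int) -> float:
    """Fraction of reads carrying the non-recurrent-parent allele.

    Returns NaN when the site has no reads (handled by filter clause 2).
    """
    if recurrent_reads < 0 or other_reads < 0:
        raise ValueError("read counts must be >= 0")
    total = recurrent_reads + other_reads
    if total == 0:
        return float("nan")
    return other_reads / total


def delta_snp_index(index_high: float, index_low: float) -> float:
    """Δ(SNP-index) = index(high bulk) − index(low bulk), in [−1, 1]."""
    return index_high - index_low


def g_statistic(high_recurrent: int, high_other: int,
                low_recurrent: int, low_other: int) -> float:
    """G = 2·Σ obs·ln(obs/exp) on the 2x2 bulk x allele read table.

    Zero iff the table is exactly proportional; symmetric under swapping
    bulks or alleles; NaN for an all-zero table.
    """
    out = g_statistic_arrays(np.array([high_recurrent]), np.array([high_other]),
                             np.array([low_recurrent]), np.array([low_other]))
    return float(out[0])


def g_statistic_arrays(hr: np.ndarray, ho: np.ndarray,
                       lr: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Vectorised :func:`g_statistic` over parallel count arrays."""
    obs = np.stack([hr, ho, lr, lo], axis=0).astype(float)
    row_h = hr + ho
    row_l = lr + lo
    col_r = hr + lr
    col_o = ho + lo
    n = row_h + row_l
    with np.errstate(divide="ignore", invalid="ignore"):
        exp = np.stack([row_h * col_r, row_h * col_o,
                        row_l * col_r, row_l * col_o], axis=0) / n
        term = obs * np.log(obs / exp)
    term = np.where(obs == 0, 0.0, term)   # 0*ln(0) := 0
    g = 2.0 * np.nansum(term, axis=0)
    g = np.where(n == 0, np.nan, np.maximum(g, 0.0))
    return g


def compute_site_stats(sites: pd.DataFrame) -> pd.DataFrame:
    """Add SNP-index, Δ, depth and G columns to a site frame.

    Expects columns high_rec, high_other, low_rec, low_other (oriented
    read counts) as produced by ``variant_io.sites_to_frame``.
    """
    df = sites.copy()
    dp_h = df["high_rec"] + df["high_other"]
    dp_l = df["low_rec"] + df["low_other"]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["index_high"] = np.where(dp_h > 0, df["high_other"] / dp_h, np.nan)
        df["index_low"] = np.where(dp_l > 0, df["low_other"] / dp_l, np.nan)
    df["delta"] = df["index_high"] - df["index_low"]
    df["depth_high"] = dp_h
    df["depth_low"] = dp_l
    df["G"] = g_statistic_arrays(df["high_rec"].to_numpy(), df["high_other"].to_numpy(),
                                 df["low_rec"].to_numpy(), df["low_other"].to_numpy())
    return df


def apply_filters(records: pd.DataFrame,
                  cfg: FilterConfig = FilterConfig()) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the three site filters; return retained sites and drop counts.

    A site dropped by several clauses is tallied under the first that
    matches (clause order 1, 2, 3). Idempotent: re-filtering the retained
    set drops nothing.
    """
    df = records
    low_both = ((df["index_high"] < cfg.low_index_threshold)
                & (df["index_low"] < cfg.low_index_threshold))
    shallow = (df["depth_high"] < cfg.min_depth) | (df["depth_low"] < cfg.min_depth)
    if cfg.clause1_conjunctive:
        clause1 = low_both & shallow
    else:
        clause1 = low_both | shallow
    clause2 = df["index_high"].isna() | df["index_low"].isna()
    clause3 = (df["gq_high"].isna() | df["gq_low"].isna()
               | (df["gq_high"] < cfg.min_gq) | (df["gq_low"] < cfg.min_gq))

    drop1 = clause1
    drop2 = clause2 & ~drop1
    drop3 = clause3 & ~drop1 & ~drop2
    counts = {
        "clause1_low_index_or_depth": int(drop1.sum()),
        "clause2_missing_index": int(drop2.sum()),
        "clause3_low_gq": int(drop3.sum()),
    }
    retained = df[~(drop1 | drop2 | drop3)].reset_index(drop=True)
    return retained, counts
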