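"""Genome scan: sliding-window smoothing, simulated null confidence
intervals, significance calling and candidate-region assembly.

Significance of a window's mean Δ(SNP-index) is assessed against
Monte-Carlo quantiles of the statistic under the no-QTL null: an
unlinked F2 locus is drawn per replicate (each bulk's index-allele
frequency is Binomial(2k, 1/2)/2k over the k bulked individuals), reads
are then drawn binomially at a given depth, and empirical quantiles of
Δ and G are tabulated per depth.

Within a 200-kb window the bulked individuals are shared and markers are
tightly linked, so the bulk-composition component of the window mean's
variance does not average out while the read-noise component does. The
window mean of m sites at per-site depth D therefore has the null
distribution of a single site sequenced to total depth m·D, and the CI
lookup uses that effective total depth by default (``depth_mode="total"``;
``"mean"`` reproduces the naive per-site lookup, which is strongly
conservative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .bsa_core import g_statistic_arrays

__all__ = [
    "WindowConfig",
    "CITable",
    "QTLRegion",
    "sliding_windows",
    "simulate_null_ci",
    "call_significant_windows",
    "assemble_regions",
    "run_scan",
]

DELTA_QUANTILES = (0.5, 1.0, 2.5, 5.0, 95.0, 97.5, 99.0, 99.5)
G_QUANTILES = (95.0, 99.0)

DEFAULT_DEPTH_GRID = (10, 20, 30, 40, 50, 75, 100, 150, 200, 300,
                      500, 750, 1000, 1500, 2000, 3000)

WINDOW_COLUMNS = ["chrom", "start", "end", "n_sites", "mean_index_high",
                  "mean_index_low", "mean_delta", "mean_G", "mean_depth",
                  "pass_min_sites"]


@dataclass(frozen=True)
class WindowConfig:
    window_size: int = 200_000
    step: int = 10_000
    min_sites_per_window: int = 10
    merge_gap: int | None = None  # default: one window size

    def __post_init__(self) -> None:
        if self.window_size <= 0 or self.step <= 0 or self.min_sites_per_window <= 0:
            raise ValueError("window parameters must be > 0")
        if self.step > self.window_size:
            raise ValueError("step must be <= window_size")

    @property
    def effective_merge_gap(self) -> int:
        return self.window_size if self.merge_gap is None else self.merge_gap


def sliding_windows(records: pd.DataFrame, cfg: WindowConfig = WindowConfig()) -> pd.DataFrame:
    """Tile each chromosome with windows of ``window_size`` every ``step`` bp.

    A site belongs to a window iff start <= pos < end; window means are
    unweighted over member sites. Windows with fewer than
    ``min_sites_per_window`` sites are kept but flagged ``pass_min_sites``
    False and are never called significant. Requires records sorted by
    (chrom, pos).
    """
    pos_sorted = records.groupby("chrom", sort=False)["pos"].is_monotonic_increasing
    if not pos_sorted.all():
        raise ValueError("site records must be sorted by (chromosome, position)")

    frames = []
    for chrom, grp in records.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if pos.size == 0:
            continue
        max_pos = int(pos.max())
        starts = np.arange(1, max_pos + 1, cfg.step, dtype=np.int64)
        ends = starts + cfg.window_size

        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        n = hi - lo

        def window_mean(col: str) -> np.ndarray:
            c = np.concatenate([[0.0], np.nancumsum(grp[col].to_numpy())])
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.where(n > 0, (c[hi] - c[lo]) / n, np.nan)

        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "n_sites": n,
            "mean_index_high": window_mean("index_high"),
            "mean_index_low": window_mean("index_low"),
            "mean_delta": window_mean("delta"),
            "mean_G": window_mean("G"),
            "mean_depth": window_mean("depth_high") / 2 + window_mean("depth_low") / 2,
            "pass_min_sites": n >= cfg.min_sites_per_window,
        }))
    if not frames:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    return pd.concat(frames, ignore_index=True)


@dataclass
class CITable:
    """Simulated null quantiles of Δ(SNP-index) and G, indexed by depth.

    For a fixed F2 design with bulk size ``k``: per replicate one unlinked
    locus is drawn (bulk index-allele frequencies Binomial(2k, 1/2)/2k,
    independent between bulks), then one binomial read draw per bulk at
    each grid depth. ``table`` has one row per depth with columns
    ``delta_q<q>`` and ``g_q<q>``.
    """

    bulk_size: int
    n_replicates: int
    seed: int
    table: pd.DataFrame
    design: str = "F2"

    def validate(self, tol: float = 0.01) -> None:
        """Interval widths must be non-increasing in depth (up to Monte-Carlo
        jitter ``tol``); Δ quantiles symmetric about 0 within 3*SE."""
        widths = (self.table["delta_q97.5"] - self.table["delta_q2.5"]).to_numpy()
        if np.any(np.diff(widths) > tol):
            raise ValueError("null CI width increases with depth beyond tolerance")

    def quantile(self, stat: Literal["delta", "g"], q: float,
                 depth: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of the ``q``-percent null quantile on the
        depth grid, clamped at the grid ends."""
        col = f"{stat}_q{q:g}"
        if col not in self.table.columns:
            raise KeyError(f"quantile {q} for {stat} not tabulated")
        depths = self.table["depth"].to_numpy(dtype=float)
        vals = self.table[col].to_numpy(dtype=float)
        return np.interp(np.asarray(depth, dtype=float), depths, vals)


def simulate_null_ci(k: int, depth_grid: Sequence[int] = DEFAULT_DEPTH_GRID,
                     n_replicates: int = 20_000, seed: int = 0) -> CITable:
    """Monte-Carlo null quantiles of per-site Δ(SNP-index) and G.

    Deterministic given ``seed``. ``n_replicates`` of 10,000+ is
    recommended for stable 95%/99% quantiles.
    """
    if k <= 0:
        raise ValueError("bulk size k must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    # one frequency draw pair per replicate, shared across the depth grid,
    # so quantiles vary smoothly in depth
    f_high = rng.binomial(2 * k, 0.5, size=n_replicates) / (2.0 * k)
    f_low = rng.binomial(2 * k, 0.5, size=n_replicates) / (2.0 * k)
    for depth in depth_grid:
        r_high = rng.binomial(depth, f_high)
        r_low = rng.binomial(depth, f_low)
        delta = r_high / depth - r_low / depth
        g = g_statistic_arrays(depth - r_high, r_high, depth - r_low, r_low)
        row: dict[str, float] = {"depth": float(depth)}
        for q in DELTA_QUANTILES:
            row[f"delta_q{q:g}"] = float(np.percentile(delta, q))
        for q in G_QUANTILES:
            row[f"g_q{q:g}"] = float(np.percentile(g, q))
        rows.append(row)
    ci = CITable(bulk_size=k, n_replicates=n_replicates, seed=seed,
                 table=pd.DataFrame(rows).sort_values("depth").reset_index(drop=True))
    ci.validate()
    return ci


def _delta_threshold_quantile(level: int, two_sided: bool) -> float:
    if level == 95:
        return 97.5 if two_sided else 95.0
    if level == 99:
        return 99.5 if two_sided else 99.0
    raise ValueError("level must be 95 or 99")


def call_significant_windows(windows: pd.DataFrame, ci: CITable, level: int = 95,
                             rule: Literal["delta", "g", "either"] = "either",
                             two_sided: bool = False,
                             depth_mode: Literal["total", "mean"] = "total") -> pd.DataFrame:
    """Flag windows whose mean Δ (and/or mean G) exceeds the null quantile.

    The Δ comparison is one-sided toward positive Δ (index-allele
    enrichment in the high bulk) by default; ``two_sided`` also calls
    windows with mean Δ below the lower quantile. Exceedance is strict;
    min-sites-flagged windows are never significant. The null quantile
    is looked up at the window's effective total depth
    (n_sites x mean depth) by default — see the module docstring.
    """
    out = windows.copy()
    depth = out["mean_depth"].to_numpy(dtype=float)
    if depth_mode == "total":
        depth = depth * out["n_sites"].to_numpy(dtype=float)
    elif depth_mode != "mean":
        raise ValueError("depth_mode must be 'total' or 'mean'")

    q = _delta_threshold_quantile(level, two_sided)
    upper = ci.quantile("delta", q, depth)
    out["delta_threshold"] = upper
    sig_delta = out["mean_delta"].to_numpy() > upper
    if two_sided:
        lower = ci.quantile("delta", 100.0 - q, depth)
        sig_delta = sig_delta | (out["mean_delta"].to_numpy() < lower)

    # G gains no power from pooling reads across the window (it is a
    # per-test-scale statistic), so its null quantile is looked up at the
    # per-site mean depth; this is conservative for a window mean.
    g_upper = ci.quantile("g", float(level), out["mean_depth"].to_numpy(dtype=float))
    out["g_threshold"] = g_upper
    sig_g = out["mean_G"].to_numpy() > g_upper

    out["significant_delta"] = sig_delta & out["pass_min_sites"]
    out["significant_g"] = sig_g & out["pass_min_sites"]
    if rule == "delta":
        out["significant"] = out["significant_delta"]
    elif rule == "g":
        out["significant"] = out["significant_g"]
    elif rule == "either":
        out["significant"] = out["significant_delta"] | out["significant_g"]
    else:
        raise ValueError("rule must be 'delta', 'g' or 'either'")
    return out


@dataclass(frozen=True)
class QTLRegion:
    """A called candidate interval with its site-level peak positions."""

    chrom: str
    start: int
    end: int
    pos_max_g: int
    pos_max_delta: int
    peak_delta: float
    peak_g: float
    n_windows: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _peak_pos(grp: pd.DataFrame, col: str) -> tuple[int, float]:
    vals = grp[col].to_numpy()
    if np.all(np.isnan(vals)):
        return int(grp["pos"].iloc[0]), float("nan")
    i = int(np.nanargmax(vals))  # nanargmax returns the FIRST max -> smallest pos
    return int(grp["pos"].iloc[i]), float(vals[i])


def assemble_regions(called_windows: pd.DataFrame, site_records: pd.DataFrame,
                     cfg: WindowConfig = WindowConfig()) -> list[QTLRegion]:
    """Merge runs of significant windows into candidate regions.

    Consecutive significant windows on one chromosome merge when the gap
    between them is at most ``cfg.effective_merge_gap`` bp; each region
    spans min(start)..max(end) and reports the positions of the
    site-level Δ and G maxima inside it (ties -> smallest position).
    """
    regions: list[QTLRegion] = []
    sig = called_windows[called_windows["significant"]]
    for chrom, grp in sig.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        gap = starts[1:] - ends[:-1]
        breaks = np.flatnonzero(gap > cfg.effective_merge_gap)
        bounds = np.concatenate([[0], breaks + 1, [len(grp)]])
        chrom_sites = site_records[site_records["chrom"] == chrom]
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            start = int(starts[b0])
            end = int(ends[b1 - 1])
            inside = chrom_sites[(chrom_sites["pos"] >= start)
                                 & (chrom_sites["pos"] < end)]
            if inside.empty:
                continue
            pos_d, peak_d = _peak_pos(inside, "delta")
            pos_g, peak_g = _peak_pos(inside, "G")
            regions.append(QTLRegion(chrom=str(chrom), start=start, end=end,
                                     pos_max_g=pos_g, pos_max_delta=pos_d,
                                     peak_delta=peak_d, peak_g=peak_g,
                                     n_windows=int(b1 - b0)))
    return regions


def run_scan(site_records: pd.DataFrame, ci: CITable,
             cfg: WindowConfig = WindowConfig(), level: int = 95,
             rule: Literal["delta", "g", "either"] = "either",
             two_sided: bool = False) -> tuple[pd.DataFrame, list[QTLRegion]]:
    """Windows -> significance -> regions, in one call."""
    windows = sliding_windows(site_records, cfg)
    called = call_significant_windows(windows, ci, level=level, rule=rule,
                                      two_sided=two_sided)
    regions = assemble_regions(called, site_records, cfg)
    return called, regions
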