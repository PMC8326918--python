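"""Sliding windows, the Monte-Carlo null, significance calling and
candidate-region assembly."""

import numpy as np
import pandas as pd
import pytest

from qtlseq import bsa_core, f2sim, variant_io
from qtlseq.scan import (CITable, QTLRegion, WindowConfig, assemble_regions,
                         call_significant_windows, run_scan, simulate_null_ci,
                         sliding_windows)


def site_frame(positions, deltas, chrom="chr1", depth=50, g=1.0):
    n = len(positions)
    df = pd.DataFrame({
        "chrom": chrom, "pos": positions,
        "index_high": np.asarray(deltas) / 2 + 0.5,
        "index_low": 0.5 - np.asarray(deltas) / 2,
        "delta": deltas,
        "depth_high": depth, "depth_low": depth,
        "G": g if np.ndim(g) else np.full(n, g),
    })
    return df


class TestSlidingWindows:
    def test_single_window_mean(self):
        df = site_frame([10_000, 20_000, 30_000], [0.2, 0.4, 0.6])
        w = sliding_windows(df, WindowConfig(window_size=200_000, step=200_000,
                                             min_sites_per_window=1))
        assert len(w) == 1
        assert w.loc[0, "mean_delta"] == pytest.approx(0.4)
        assert w.loc[0, "n_sites"] == 3

    def test_membership_is_half_open(self):
        """A site at pos == window end belongs to the next window only."""
        df = site_frame([100_001, 200_001], [0.5, 0.9])
        w = sliding_windows(df, WindowConfig(window_size=100_000, step=100_000,
                                             min_sites_per_window=1))
        first = w[(w["start"] == 100_001)]
        assert first["n_sites"].iloc[0] == 1
        assert first["mean_delta"].iloc[0] == pytest.approx(0.5)

    def test_constant_delta_gives_constant_window_means(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(1, 2_000_000, 1000), 500, replace=False))
        df = site_frame(pos, np.full(500, 0.3))
        w = sliding_windows(df)
        nonempty = w[w["n_sites"] > 0]
        assert np.allclose(nonempty["mean_delta"], 0.3)

    def test_unsorted_input_raises(self):
        df = site_frame([30_000, 10_000], [0.1, 0.2])
        with pytest.raises(ValueError, match="sorted"):
            sliding_windows(df)

    def test_sparse_windows_flagged(self):
        df = site_frame([10_000], [0.9])
        w = sliding_windows(df)  # default min 10 sites
        assert not w["pass_min_sites"].any()

    def test_step_must_not_exceed_window(self):
        with pytest.raises(ValueError):
            WindowConfig(window_size=10_000, step=20_000)


class TestNullCI:
    def test_delta_quantiles_symmetric_about_zero(self, null_ci_k50):
        t = null_ci_k50.table
        for lo, hi in (("delta_q2.5", "delta_q97.5"),
                       ("delta_q0.5", "delta_q99.5")):
            assert np.allclose(t[lo], -t[hi], atol=0.02)

    def test_interval_narrows_with_depth(self):
        ci = simulate_null_ci(50, depth_grid=(10, 100), n_replicates=100_000,
                              seed=11)
        w = ci.table["delta_q97.5"] - ci.table["delta_q2.5"]
        assert w.iloc[1] < w.iloc[0]

    def test_high_depth_limit_matches_binomial_closed_form(self):
        """depth -> inf: Var(Δ) -> 2 * 0.25/(2k); the 97.5% quantile
        approaches 1.96 * sqrt(0.005) ~ 0.139 at k=50."""
        ci = simulate_null_ci(50, depth_grid=(10_000,), n_replicates=100_000,
                              seed=13)
        q = ci.table["delta_q97.5"].iloc[0]
        assert q == pytest.approx(1.96 * np.sqrt(0.005), abs=0.01)

    def test_deterministic_given_seed(self):
        a = simulate_null_ci(20, depth_grid=(30, 60), n_replicates=5000, seed=4)
        b = simulate_null_ci(20, depth_grid=(30, 60), n_replicates=5000, seed=4)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_invalid_bulk_size(self):
        with pytest.raises(ValueError):
            simulate_null_ci(0)


def one_window(mean_delta, n_sites=20, mean_depth=50.0, mean_g=1.0,
               pass_min=True):
    return pd.DataFrame({
        "chrom": ["chr1"], "start": [1], "end": [200_001],
        "n_sites": [n_sites], "mean_index_high": [0.5 + mean_delta / 2],
        "mean_index_low": [0.5 - mean_delta / 2], "mean_delta": [mean_delta],
        "mean_G": [mean_g], "mean_depth": [mean_depth],
        "pass_min_sites": [pass_min],
    })


class TestSignificance:
    def test_zero_delta_never_significant(self, null_ci_k50):
        called = call_significant_windows(one_window(0.0), null_ci_k50)
        assert not called["significant"].any()

    def test_large_delta_is_significant(self, null_ci_k50):
        """mean Δ = 0.9 at depth 50 far exceeds the simulated null 95%
        quantile for k=50."""
        called = call_significant_windows(one_window(0.9, n_sites=1,
                                                     mean_depth=50.0),
                                          null_ci_k50, rule="delta")
        assert called["significant"].all()

    def test_threshold_boundary_is_not_significant(self, null_ci_k50):
        thr = float(null_ci_k50.quantile("delta", 95.0, 50.0))
        called = call_significant_windows(one_window(thr, n_sites=1,
                                                     mean_depth=50.0),
                                          null_ci_k50, rule="delta")
        assert not called["significant"].any()

    def test_sparse_window_never_significant(self, null_ci_k50):
        called = call_significant_windows(one_window(0.9, pass_min=False),
                                          null_ci_k50)
        assert not called["significant"].any()

    def test_two_sided_calls_negative_delta(self, null_ci_k50):
        w = one_window(-0.9, n_sites=1, mean_depth=50.0)
        one = call_significant_windows(w, null_ci_k50, rule="delta")
        two = call_significant_windows(w, null_ci_k50, rule="delta",
                                       two_sided=True)
        assert not one["significant"].any()
        assert two["significant"].all()

    def test_g_rule(self, null_ci_k50):
        called = call_significant_windows(one_window(0.0, mean_g=50.0),
                                          null_ci_k50, rule="g")
        assert called["significant"].all()


class TestRegions:
    def cfg(self):
        return WindowConfig(window_size=100_000, step=100_000,
                            min_sites_per_window=1)

    def called(self, starts, sig, chrom="chr1"):
        starts = np.asarray(starts)
        return pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + 100_000,
            "n_sites": 5, "mean_index_high": 0.7, "mean_index_low": 0.2,
            "mean_delta": 0.5, "mean_G": 5.0, "mean_depth": 50.0,
            "pass_min_sites": True, "significant": sig,
        })

    def test_no_significant_windows_gives_no_regions(self):
        sites = site_frame([50_000], [0.5])
        assert assemble_regions(self.called([1], [False]), sites, self.cfg()) == []

    def test_distant_windows_make_two_regions(self):
        sites = site_frame([50_000, 950_000], [0.5, 0.6])
        regions = assemble_regions(
            self.called([1, 900_001], [True, True]), sites, self.cfg())
        assert len(regions) == 2

    def test_adjacent_windows_merge_and_peaks_are_site_maxima(self):
        sites = site_frame([50_000, 150_000, 160_000], [0.5, 0.8, 0.8],
                           g=[3.0, 9.0, 9.0])
        regions = assemble_regions(
            self.called([1, 100_001], [True, True]), sites, self.cfg())
        (r,) = regions
        assert (r.start, r.end) == (1, 200_001)
        assert r.peak_delta == 0.8
        # ties broken by smallest position
        assert r.pos_max_delta == 150_000
        assert r.pos_max_g == 150_000
        assert r.length == r.end - r.start
        assert r.n_windows == 2

    def test_peak_delta_equals_max_site_delta_in_span(self, null_ci_k50):
        rng = np.random.default_rng(21)
        pos = np.arange(10_000, 3_000_001, 10_000)
        deltas = np.clip(rng.normal(0.6, 0.1, pos.size), -1, 1)
        sites = site_frame(pos, deltas)
        _, regions = run_scan(sites, null_ci_k50, rule="delta")
        assert regions
        for r in regions:
            inside = sites[(sites["pos"] >= r.start) & (sites["pos"] < r.end)]
            assert r.peak_delta == inside["delta"].max()


class TestEndToEnd:
    def simulate_sites(self, seed, qtl=True, a=1.5):
        genome = f2sim.rice_like_genome(2, 40_000_000)
        qtls = (f2sim.QTLSpec("chr1", 15_000_000, a),) if qtl else ()
        cfg = f2sim.F2SimConfig(genome=genome, qtls=qtls, population_size=720,
                                bulk_size=50, residual_sd=1.0, seed=seed)
        _, _, _, sites = f2sim.simulate_experiment(cfg)
        df = bsa_core.compute_site_stats(variant_io.sim_sites_to_frame(sites))
        df, _ = bsa_core.apply_filters(df)
        return df

    def test_planted_qtl_recovered_in_one_region(self, null_ci_k50):
        """A single QTL at 15.0 Mb (a/sigma = 1.5, n=720, k=50, ~50x) yields
        exactly one candidate region on its chromosome, containing the QTL."""
        df = self.simulate_sites(seed=42)
        _, regions = run_scan(df, null_ci_k50, rule="delta")
        chr1 = [r for r in regions if r.chrom == "chr1"]
        assert len(chr1) == 1
        assert chr1[0].start <= 15_000_000 <= chr1[0].end

    def test_halving_step_moves_region_hull_less_than_one_window(self, null_ci_k50):
        df = self.simulate_sites(seed=43)
        hulls = {}
        for step in (20_000, 10_000):
            cfg = WindowConfig(window_size=200_000, step=step)
            _, regions = run_scan(df, null_ci_k50, cfg, rule="delta")
            chr1 = [r for r in regions if r.chrom == "chr1"]
            hulls[step] = (min(r.start for r in chr1), max(r.end for r in chr1))
        assert abs(hulls[10_000][0] - hulls[20_000][0]) <= 200_000
        assert abs(hulls[10_000][1] - hulls[20_000][1]) <= 200_000
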