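"""Aneuploidy statistics against exhaustive oracles, plus the simulation
designs (whole-chromosome scaling, segmental events, co-occurring
polysomes)."""

import itertools

import numpy as np
import pytest
from scipy import stats

from feralgen.ploidy import (
    GAIN,
    LOSS,
    NONE,
    DepthProfile,
    InstabilityRecord,
    aneuploidy_rate_weights,
    call_aneuploidies,
    compare_groups,
    coverage_gate,
    default_site_counts,
    hodges_lehmann_shift,
    instability_records,
    instability_regression,
    normalized_depth_track,
    rank_biserial,
    simulate_cooccurrence,
    simulate_depth_profile,
    simulate_power_grid,
    simulate_segmental_grid,
)
from feralgen.ploidy import test_chromosome as chromosome_test


def profile_from(depths: dict) -> DepthProfile:
    return DepthProfile("t", {c: np.asarray(v) for c, v in depths.items()})


class TestHodgesLehmannOracle:
    @pytest.mark.parametrize("n1,n2,seed", [(7, 9, 0), (50, 31, 1), (200, 200, 2),
                                            (499, 500, 3)])
    def test_matches_exhaustive_pairwise_median(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 80, size=n1).astype(float)
        y = rng.integers(0, 80, size=n2).astype(float)
        oracle = np.median(np.subtract.outer(x, y))
        assert hodges_lehmann_shift(x, y) == pytest.approx(oracle, abs=1e-9)

    def test_shifted_shuffle_instance(self):
        # half the test sites +30 over a shuffled copy of the background
        rng = np.random.default_rng(4)
        y = rng.integers(10, 60, size=200).astype(float)
        x = rng.permutation(y).copy()
        x[:100] += 30
        oracle = np.median(np.subtract.outer(x, y))
        assert hodges_lehmann_shift(x, y) == pytest.approx(oracle, abs=1e-9)

    def test_non_integer_fallback(self):
        x = np.array([1.5, 2.5, 3.5])
        y = np.array([0.5, 1.0])
        assert hodges_lehmann_shift(x, y) == np.median(np.subtract.outer(x, y))


class TestRankBiserial:
    def test_complete_separation(self):
        prof = profile_from({"a": [45] * 50, "b": [30] * 60})
        r, hl, p = chromosome_test(prof, "a")
        assert r == 1.0 and hl == 15.0

    def test_null_identical_distributions(self):
        rng = np.random.default_rng(5)
        x = rng.normal(30, 10, 10_000).round()
        y = rng.normal(30, 10, 10_000).round()
        r, _ = rank_biserial(x, y)
        assert abs(r) < 0.05

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(6)
        x = rng.normal(40, 10, 500).round()
        y = rng.normal(30, 10, 700).round()
        r_xy, _ = rank_biserial(x, y)
        r_yx, _ = rank_biserial(y, x)
        assert r_xy == pytest.approx(-r_yx, abs=1e-12)
        assert -1 <= r_xy <= 1

    def test_oracle_pair_counting(self):
        """r equals (wins - losses)/(n1*n2) counted exhaustively."""
        rng = np.random.default_rng(7)
        x = rng.integers(0, 20, 40).astype(float)
        y = rng.integers(0, 20, 30).astype(float)
        wins = sum(a > b for a, b in itertools.product(x, y))
        losses = sum(a < b for a, b in itertools.product(x, y))
        r, _ = rank_biserial(x, y)
        assert r == pytest.approx((wins - losses) / (len(x) * len(y)), abs=1e-9)

    def test_degenerate_identical_constants(self):
        prof = profile_from({"a": [30] * 10, "b": [30] * 10})
        r, hl, p = chromosome_test(prof, "a")
        assert r == 0.0 and hl == 0.0


class TestCoverageGate:
    @pytest.mark.parametrize("mean,accepted", [(19.9, False), (20.0, True), (30, True)])
    def test_threshold_inclusive(self, mean, accepted):
        prof = profile_from({"a": [mean] * 100, "b": [mean] * 100})
        assert coverage_gate(prof) is accepted


class TestCallAneuploidies:
    def test_noiseless_gain_and_loss(self):
        prof = profile_from(
            {"c1": [45] * 80, "c2": [30] * 80, "c3": [30] * 80, "c4": [15] * 80}
        )
        calls = {c.chrom: c for c in call_aneuploidies(prof)}
        assert calls["c1"].direction == GAIN
        assert calls["c4"].direction == LOSS and calls["c4"].hl_shift_raw < 0
        assert calls["c2"].direction == NONE
        # normalization by euploid median (30)
        assert calls["c1"].hl_shift_norm == pytest.approx(0.5)
        assert calls["c4"].hl_shift_norm == pytest.approx(-0.5)

    def test_simulated_trisomy_power(self):
        """3N chromosome on Normal(30,10) noise is detected (rank-biserial
        >= 0.5) in >= 99% of seeds."""
        counts = default_site_counts()
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            prof = simulate_depth_profile(counts, aneuploidies=[("chrVI", 0.5)],
                                          seed=seed)
            r, _, _ = chromosome_test(prof, "chrVI")
            hits += r >= 0.5
        assert hits >= 0.99 * n_seeds

    def test_zero_depth_chromosome(self):
        prof = simulate_depth_profile(
            {"c1": 200, "c2": 300, "c3": 300}, aneuploidies=[("c1", -1.0)], seed=1
        )
        assert prof.depths["c1"].max() == 0
        r, hl, _ = chromosome_test(prof, "c1")
        # Normal(30,10) background floored at 0 leaves a handful of zero-depth
        # ties, so complete separation is approached but not exact.
        assert r <= -0.99
        assert hl < 0

    def test_single_chromosome_rejected(self):
        with pytest.raises(ValueError):
            DepthProfile("t", {"a": np.array([30])})

    def test_subsampling_stability(self):
        """Capping sites changes rank-biserial by < 0.02 at 1e4 sites/group."""
        prof = simulate_depth_profile(
            {c: n * 4 for c, n in default_site_counts(16000).items()},
            aneuploidies=[("chrIV", 0.3)], seed=2,
        )
        r_full, _, _ = chromosome_test(prof, "chrIV")
        r_sub, _, _ = chromosome_test(prof, "chrIV", max_sites_per_group=10_000,
                                      seed=3)
        assert abs(r_full - r_sub) < 0.02


class TestInstabilityRegression:
    def test_exact_linear_records(self):
        recs = [
            InstabilityRecord("i%d" % i, "c1", 2.0 * x, x)
            for i, x in enumerate([0.5, 1.0, 1.5, 2.0])
        ]
        df = instability_regression(recs)
        row = df[df["stratum"] == "c1"].iloc[0]
        assert row["slope"] == pytest.approx(2.0)
        assert row["r2"] == pytest.approx(1.0)

    def test_single_polysome_isolates_excluded(self):
        recs = [InstabilityRecord("i1", "c1", 1.0, None)] * 5
        assert instability_regression(recs).empty

    def test_slope_recovery(self):
        """Slope 0.9 + N(0, 0.2) noise, n = 200: recovered within 0.1."""
        rng = np.random.default_rng(8)
        x = rng.uniform(0.5, 3.0, 200)
        y = 0.9 * x + rng.normal(0, 0.2, 200)
        recs = [InstabilityRecord(f"i{k}", "c1", yy, xx)
                for k, (xx, yy) in enumerate(zip(x, y))]
        df = instability_regression(recs)
        slope = df[df["stratum"] == "pooled"].iloc[0]["slope"]
        assert slope == pytest.approx(0.9, abs=0.1)

    def test_records_builder_background_means(self):
        from feralgen.ploidy import AneuploidyCall

        calls = [
            AneuploidyCall("i", "c1", 0.9, 15, 0.5, GAIN, 0.001),
            AneuploidyCall("i", "c2", 0.8, 30, 1.0, GAIN, 0.001),
            AneuploidyCall("i", "c3", 0.1, 1, 0.03, NONE, 0.4),
        ]
        recs = instability_records({"i": calls})
        by_chrom = {r.chrom: r for r in recs}
        assert by_chrom["c1"].mean_background_shift == pytest.approx(1.0)
        assert by_chrom["c2"].mean_background_shift == pytest.approx(0.5)
        assert "c3" not in by_chrom


class TestCompareGroups:
    def _recs(self, a_vals, b_vals):
        recs = []
        for i, v in enumerate(a_vals):
            recs.append(InstabilityRecord(f"a{i}", "c1", v, 0.0, group="admixed"))
        for i, v in enumerate(b_vals):
            recs.append(InstabilityRecord(f"b{i}", "c1", v, 0.0, group="feral"))
        return recs

    def test_identical_groups_p_half(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(0, 2, 15)
        p, method = compare_groups(self._recs(vals, vals))
        assert p == pytest.approx(0.5, abs=0.05)
        assert method == "exact"

    def test_complete_dominance_small_p(self):
        p, _ = compare_groups(self._recs([2, 3, 4, 5, 6], [0.1, 0.2, 0.3, 0.4, 0.5]))
        from math import comb

        assert p <= 1 / comb(10, 5) + 1e-12

    def test_large_sample_matches_permutation_oracle(self):
        """Asymptotic one-sided p agrees with a permutation oracle within
        Monte-Carlo error for shifted exponentials, n = (90, 244)."""
        rng = np.random.default_rng(10)
        a = rng.exponential(1.0, 90) + 0.15
        b = rng.exponential(1.0, 244)
        p, method = compare_groups(self._recs(a, b))
        assert method == "asymptotic"
        pooled = np.concatenate([a, b])
        obs = stats.mannwhitneyu(a, b, alternative="greater").statistic
        n_perm = 20_000
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            u = stats.mannwhitneyu(perm[:90], perm[90:], alternative="greater").statistic
            count += u >= obs
        p_perm = (count + 1) / (n_perm + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p - p_perm) < 4 * se + 1e-3

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(self._recs([1.0], []))


class TestSimulationGrids:
    def test_power_grid_null_and_detection_cells(self):
        df = simulate_power_grid(seed=1, scale_grid=[0.0, 0.5, -1.0],
                                 n_background_aneu=[0], n_reps=25,
                                 site_counts=default_site_counts())
        null = df[df["scale"] == 0.0]["rank_biserial"].abs()
        assert null.mean() < 0.05
        detect = df[df["scale"] == 0.5]["rank_biserial"]
        assert (detect >= 0.5).mean() >= 0.99
        # floored-at-0 background sites tie with the all-zero chromosome,
        # so complete separation is approached but not exact
        assert (df[df["scale"] == -1.0]["rank_biserial"] <= -0.99).all()

    def test_segmental_events_do_not_trigger_calls(self):
        df = simulate_segmental_grid(seed=2, fraction_grid=[0.0, 0.5, -0.5],
                                     n_background_aneu=[0], n_reps=25,
                                     site_counts=default_site_counts())
        assert df[df["fraction"] == 0.0]["rank_biserial"].abs().mean() < 0.05
        for frac in (0.5, -0.5):
            called = (df[df["fraction"] == frac]["rank_biserial"].abs() >= 0.5)
            assert called.mean() < 0.10

    def test_segmental_directionality(self):
        """Segmental gain shifts rank-biserial positive, segmental loss
        negative; both stay below the whole-chromosome call threshold.
        (The magnitudes are NOT symmetric: a 1N segment separates from the
        2N background more sharply than a 3N segment does, because depth
        variance scales with copy number.)"""
        df = simulate_segmental_grid(seed=3, fraction_grid=[0.5, -0.5],
                                     n_background_aneu=[0], n_reps=40,
                                     site_counts=default_site_counts(6000))
        plus = df[df["fraction"] == 0.5]["rank_biserial"]
        minus = df[df["fraction"] == -0.5]["rank_biserial"]
        assert plus.mean() > 0 > minus.mean()
        assert plus.abs().mean() < 0.5 and minus.abs().mean() < 0.5

    def test_cooccurrence_unbiased_without_background(self):
        df = simulate_cooccurrence(seed=4, n_cooccurring=[0],
                                   background_shift=[0.0],
                                   foreground_shift_grid=[1.0, 3.0, 5.0],
                                   n_reps=10)
        bias = df.groupby("foreground_shift")["underestimation"].mean()
        assert (bias.abs() < 0.03).all()

    def test_cooccurrence_monotone_in_burden(self):
        """Underestimation grows with the number and copy number of
        co-occurring polysomes at fixed foreground shift."""
        df = simulate_cooccurrence(seed=5, n_cooccurring=[0, 2, 5],
                                   background_shift=[1.0, 3.0],
                                   foreground_shift_grid=[5.0], n_reps=12)
        cell = df.groupby(["n_cooccurring", "background_shift"])[
            "underestimation"].mean()
        for b in (1.0, 3.0):
            assert cell[0, b] <= cell[2, b] + 0.02 <= cell[5, b] + 0.04
        assert cell[5, 1.0] <= cell[5, 3.0]

    def test_weights_favor_short_chromosomes(self):
        w = aneuploidy_rate_weights()
        assert w["chrI"] > w["chrIV"]
        assert sum(w.values()) == pytest.approx(1.0)


class TestPlots:
    def test_track_and_heatmap_render(self, tmp_path):
        from feralgen.ploidy import plot_normalized_track, plot_shift_heatmap

        prof = simulate_depth_profile({"cA": 1500, "cB": 1500},
                                      aneuploidies=[("cA", 0.5)], seed=20)
        calls = call_aneuploidies(prof)
        track = normalized_depth_track(prof, calls, window=100, step=50)
        plot_normalized_track(track, tmp_path / "track.png")
        import pandas as pd

        shifts = pd.DataFrame(
            [{"isolate": f"i{k}", "chrom": c, "hl_shift_norm": v}
             for k in range(4)
             for c, v in (("cA", 0.5 * k), ("cB", 0.0))]
        )
        plot_shift_heatmap(shifts, tmp_path / "heat.png")
        assert (tmp_path / "track.png").stat().st_size > 0
        assert (tmp_path / "heat.png").stat().st_size > 0


class TestNormalizedDepthTrack:
    def test_uniform_diploid_near_one(self):
        prof = simulate_depth_profile(default_site_counts(6000), seed=6)
        calls = call_aneuploidies(prof)
        track = normalized_depth_track(prof, calls)
        assert track["norm_depth"].median() == pytest.approx(1.0, abs=0.05)

    def test_trisomic_chromosome_near_one_point_five(self):
        prof = simulate_depth_profile(default_site_counts(6000),
                                      aneuploidies=[("chrX", 0.5)], seed=7)
        calls = call_aneuploidies(prof)
        track = normalized_depth_track(prof, calls)
        on = track[track["chrom"] == "chrX"]["norm_depth"]
        assert on.median() == pytest.approx(1.5, abs=0.1)

    def test_segmental_bimodality(self):
        prof = simulate_depth_profile(
            {"cA": 2000, "cB": 2000, "cC": 2000},
            segmental=[("cA", 0.4, 1.5)], seed=8,
        )
        calls = call_aneuploidies(prof)
        track = normalized_depth_track(prof, calls, window=200, step=100)
        on = track[track["chrom"] == "cA"]["norm_depth"]
        lo = on[on < 1.25]
        hi = on[on >= 1.25]
        assert len(lo) > 0 and len(hi) > 0
        assert np.median(lo) == pytest.approx(1.0, abs=0.1)
        assert np.median(hi) == pytest.approx(1.5, abs=0.1)
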