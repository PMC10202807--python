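"""Goodness of fit, simulated annealing, posterior resampling, PPC."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.stats import chisquare

from maternalsim.calibration import (
    AnnealConfig, PosteriorArchive, anneal, goodness_of_fit, posterior_sample,
    ppc, train_test_split,
)


class TestGoodnessOfFit:
    def test_exact_match_scores_zero(self):
        assert goodness_of_fit([1.0, 2.0], [1.0, 2.0], scales=1.0) == 0.0

    def test_single_squared_distance(self):
        assert goodness_of_fit([13.0], [10.0], scales=1.0) == 9.0

    def test_hand_summed_distances(self):
        # diffs (1, 2, 2) with unit weights and scales -> 1 + 4 + 4 = 9
        assert goodness_of_fit([2.0, 3.0, 0.0], [1.0, 1.0, 2.0], scales=1.0) == 9.0

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            goodness_of_fit([1.0, 2.0], [1.0])

    def test_weight_scaling_scales_score(self, rng):
        pred, obs = rng.normal(size=20), rng.normal(size=20)
        s1 = goodness_of_fit(pred, obs, weights=1.0)
        s3 = goodness_of_fit(pred, obs, weights=3.0)
        assert s3 == pytest.approx(3 * s1)

    def test_order_invariance(self, rng):
        pred, obs = rng.normal(size=20), rng.normal(size=20)
        perm = rng.permutation(20)
        assert goodness_of_fit(pred[perm], obs[perm]) == pytest.approx(
            goodness_of_fit(pred, obs))


class TestTrainTestSplit:
    def test_cut_2015_partitions_1990_2020(self):
        df = pd.DataFrame({"year": np.arange(1990, 2021), "value": 0.0})
        out = train_test_split(df, 2015)
        assert (out["split"] == "train").sum() == 26
        assert (out["split"] == "test").sum() == 5

    def test_all_years_before_cut_empty_test(self):
        out = train_test_split(pd.DataFrame({"year": [2000, 2001]}), 2015)
        assert (out["split"] == "test").sum() == 0

    def test_idempotent(self):
        df = pd.DataFrame({"year": [2000, 2018]})
        once = train_test_split(df, 2015)
        twice = train_test_split(once, 2015)
        pd.testing.assert_frame_equal(once, twice)


def quad_gof(theta):
    return float((theta[0] - 1.0) ** 2 + (theta[1] + 2.0) ** 2)


class TestAnneal:
    def test_finds_quadratic_optimum_within_tolerance(self):
        config = AnnealConfig(steps=2000, seed=5)
        archive = anneal(quad_gof, np.zeros(2), np.array([1.0, 1.0]), config)
        best, _ = archive.best(1)
        assert np.linalg.norm(best[0] - np.array([1.0, -2.0])) < 0.05

    def test_matches_independent_optimizer(self):
        config = AnnealConfig(steps=2000, seed=5)
        archive = anneal(quad_gof, np.zeros(2), np.array([1.0, 1.0]), config)
        best, _ = archive.best(1)
        ref = minimize(quad_gof, np.zeros(2)).x
        assert np.linalg.norm(best[0] - ref) < 0.05

    def test_zero_temperature_is_greedy_descent(self):
        config = AnnealConfig(steps=500, t0=0.0, cooling=0.99, seed=3)
        archive = anneal(quad_gof, np.zeros(2), np.array([0.5, 0.5]), config)
        # the accepted score sequence never worsens, so the best-score trace
        # equals the running minimum and the final best is <= the start
        scores = np.array(archive.scores)
        assert scores.min() <= scores[0]
        best, bscores = archive.best(1)
        assert bscores[0] <= quad_gof(np.zeros(2))

    def test_same_seed_gives_identical_archives(self):
        config = AnnealConfig(steps=300, seed=12)
        a1 = anneal(quad_gof, np.zeros(2), np.ones(2), config)
        a2 = anneal(quad_gof, np.zeros(2), np.ones(2), config)
        assert a1.scores == a2.scores
        assert all(np.array_equal(x, y) for x, y in zip(a1.thetas, a2.thetas))

    def test_best_score_trace_is_monotone(self):
        config = AnnealConfig(steps=400, seed=8)
        archive = anneal(quad_gof, np.zeros(2), np.ones(2), config)
        trace = archive.best_score_trace
        assert np.all(np.diff(trace) <= 0)

    def test_failing_evaluations_are_skipped(self):
        calls = {"n": 0}

        def flaky(theta):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise RuntimeError("simulator failure")
            return quad_gof(theta)

        archive = anneal(flaky, np.zeros(2), np.ones(2),
                         AnnealConfig(steps=200, seed=1))
        assert len(archive) > 0
        assert np.isfinite(archive.scores).all()


class TestPosteriorSample:
    def make_archive(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        arch = PosteriorArchive()
        for _ in range(n):
            th = rng.normal(size=3)
            arch.append(th, quad_gof(th[:2]))
        return arch

    def test_single_best_set_used_for_all_iterations(self, rng):
        arch = self.make_archive()
        thetas, seeds = posterior_sample(arch, 1, 50, rng)
        assert np.all(thetas == thetas[0])
        assert len(set(seeds.tolist())) > 1  # fresh first-order seeds

    def test_uniform_resampling_multinomial(self, rng):
        arch = self.make_archive(500)
        thetas, _ = posterior_sample(arch, 100, 10_000, rng)
        best, _ = arch.best(100)
        counts = np.zeros(100)
        lookup = {b.tobytes(): i for i, b in enumerate(best)}
        for t in thetas:
            counts[lookup[t.tobytes()]] += 1
        _stat, p = chisquare(counts)
        assert p > 0.01

    def test_short_archive_rejected(self, rng):
        with pytest.raises(ValueError):
            posterior_sample(self.make_archive(10), 100, 5, rng)

    def test_ties_broken_deterministically_by_hash(self):
        thetas = [np.array([float(i), 0.0]) for i in range(6)]
        a1, a2 = PosteriorArchive(), PosteriorArchive()
        for t in thetas:
            a1.append(t, 1.0)
        for t in reversed(thetas):
            a2.append(t, 1.0)
        b1, _ = a1.best(3)
        b2, _ = a2.best(3)
        np.testing.assert_array_equal(b1, b2)


class TestPpc:
    def make_frame(self, obs, lo, hi, mean):
        return pd.DataFrame({"obs": obs, "ui_lo": lo, "ui_hi": hi, "pred_mean": mean})

    def test_full_coverage(self):
        f = self.make_frame([1, 2], [0, 0], [3, 3], [1, 2])
        assert ppc(f).coverage_probability == 100.0

    def test_three_of_four_inside(self):
        f = self.make_frame([1, 2, 3, 10], [0] * 4, [5] * 4, [1, 2, 3, 4])
        assert ppc(f).coverage_probability == 75.0

    def test_mae_and_me(self):
        f = self.make_frame([10, 10], [0, 0], [20, 20], [12, 8])
        rep = ppc(f)
        assert rep.mean_absolute_error == pytest.approx(2.0)
        assert rep.mean_error == pytest.approx(0.0)

    def test_unmatched_target_rejected(self):
        f = self.make_frame([1.0, np.nan], [0, 0], [2, 2], [1, 1])
        with pytest.raises(ValueError):
            ppc(f)

    def test_grouped_reports(self):
        f = self.make_frame([1, 10], [0, 0], [5, 5], [1, 8])
        f["split"] = ["train", "test"]
        out = ppc(f, by=["split"])
        assert set(out["split"]) == {"train", "test"}
        assert out.loc[out["split"] == "test", "coverage_probability"].item() == 0.0
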