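"""Posterior-summary tests: quartiles, densities, firing order, T_rep."""

import numpy as np
import pytest

import okfire as ok
from okfire import synthetic
from okfire.inference import ChainSet, MCMCConfig, PARAM_NAMES
from okfire.model_core import collision_normal_params, simulate_population
from okfire.summaries import (
    collision_density,
    firing_diff_density,
    firing_order_table,
    median_replication_time,
    point_estimates,
    prob_fires_earlier,
    summarize_licencing,
    summarize_obscuring,
)


def chainset_from_population(pop, theta_row=None, n_keep=None):
    """Fabricate a one-chain ChainSet whose 'samples' expose a simulated
    population's latent cells (collisions, licencing, times)."""
    trip = pop.triplet
    M = pop.M if n_keep is None else n_keep
    theta = np.zeros((1, 1, 11)) if theta_row is None else np.asarray(theta_row).reshape(1, 1, 11)
    sub_t = np.where(pop.licenced, pop.times, 0.0)[None, :M, :]
    coll = np.full((1, M, 2), np.nan)
    pairs = np.full((1, M, 2), -1, dtype=np.int8)
    x = trip.x
    for c in range(M):
        kk = 0
        prev = -1
        for j in range(3):
            if pop.realized[c, j]:
                if prev >= 0:
                    coll[0, c, kk] = 0.5 * (x[prev] + x[j] + pop.times[c, j] - pop.times[c, prev])
                    pairs[0, c, kk] = {(0, 1): 0, (1, 2): 1, (0, 2): 2}[(prev, j)]
                    kk += 1
                prev = j
    pair_frac = np.array(
        [[[pop.pair_realized_fraction(p) for p in ((0, 1), (1, 2), (0, 2))]]]
    )
    return ChainSet(
        triplet=trip,
        config=MCMCConfig(M=pop.M),
        theta=theta,
        realized_frac=pop.realized_fraction()[None, None, :],
        obscuring=pop.obscuring_matrix()[None, None, :, :],
        pair_frac=pair_frac,
        sub_licenced=pop.licenced[None, :M, :],
        sub_times=sub_t,
        sub_collisions=coll,
        sub_pairs=pairs,
        acceptance=np.zeros((1, 12)),
    )


def chainset_from_theta(theta_samples, triplet):
    """ChainSet carrying only parameter samples (1 chain)."""
    t = np.asarray(theta_samples, dtype=float)[None, :, :]
    n = t.shape[1]
    return ChainSet(
        triplet=triplet,
        config=MCMCConfig(),
        theta=t,
        realized_frac=np.zeros((1, n, 3)),
        obscuring=np.zeros((1, n, 3, 3)),
        pair_frac=np.zeros((1, n, 3)),
        sub_licenced=np.zeros((1, n, 0, 3), dtype=bool),
        sub_times=np.zeros((1, n, 0, 3)),
        sub_collisions=np.zeros((1, n, 0, 2)),
        sub_pairs=np.zeros((1, n, 0, 2), dtype=np.int8),
        acceptance=np.zeros((1, 12)),
    )


class TestQuantileSummaries:
    def test_midpoint_quartiles(self, triplet):
        theta = np.zeros((4, 11))
        theta[:, PARAM_NAMES.index("q_1")] = [0.1, 0.2, 0.3, 0.4]
        cs = chainset_from_theta(theta, triplet)
        row = summarize_licencing(cs).iloc[0]
        assert row["median"] == pytest.approx(0.25)
        assert row["q25"] == pytest.approx(0.15)
        assert row["q75"] == pytest.approx(0.35)

    def test_degenerate_samples(self, triplet):
        theta = np.zeros((10, 11))
        theta[:, PARAM_NAMES.index("q_2")] = 1.0
        cs = chainset_from_theta(theta, triplet)
        row = summarize_licencing(cs).iloc[1]
        assert row["median"] == row["q25"] == row["q75"] == 1.0
        assert row["sd"] == 0.0

    def test_single_sample(self, triplet):
        theta = np.zeros((1, 11))
        theta[:, PARAM_NAMES.index("q_3")] = 0.42
        row = summarize_licencing(chainset_from_theta(theta, triplet)).iloc[2]
        assert row["median"] == row["q25"] == row["q75"] == pytest.approx(0.42)


class TestObscuringSummary:
    def test_all_zero_obscuring(self, triplet, rng):
        pop = simulate_population(synthetic.strong_origins(), triplet, 200, rng)
        cs = chainset_from_population(pop)
        df = summarize_obscuring(cs)
        assert (df["median"] >= 0).all()

    def test_gaussian_significance(self, triplet):
        # mean 0.14, sd 0.01 -> overwhelmingly nonzero
        n = 1000
        rng = np.random.default_rng(1)
        obsc = np.zeros((1, n, 3, 3))
        obsc[0, :, 1, 0] = rng.normal(0.14, 0.01, n)
        cs = chainset_from_theta(np.zeros((n, 11)), triplet)
        cs.obscuring = obsc
        df = summarize_obscuring(cs)
        row = df[(df["obscured"] == "O2") & (df["by"] == "O1")].iloc[0]
        assert row["p_vs_zero"] < 1e-10
        assert row["direction"] == "left"

    def test_obscured_middle_scenario_median(self, triplet):
        """Population-level left-obscuring in the obscured-middle scenario
        matches the analytic one-sided value."""
        pop = simulate_population(
            synthetic.obscured_middle(), triplet, 20000, np.random.default_rng(2)
        )
        cs = chainset_from_population(pop)
        row = summarize_obscuring(cs)
        r = row[(row["obscured"] == "O2") & (row["by"] == "O1")].iloc[0]
        assert r["median"] == pytest.approx(0.679, abs=0.015)


class TestCollisionDensity:
    def test_middle_off_only_end_pair_collides(self, triplet):
        fp = ok.FiringParams(np.zeros(3), np.full(3, 100.0), np.array([1.0, 0.0, 1.0]))
        pop = simulate_population(fp, triplet, 2000, np.random.default_rng(3))
        cs = chainset_from_population(pop)
        assert collision_density(cs, (0, 2)).realized_fraction == pytest.approx(1.0)
        assert collision_density(cs, (0, 1)).points.size == 0

    def test_gaussian_collision_density(self, triplet):
        from scipy.stats import kstest

        fp = synthetic.strong_origins()
        pop = simulate_population(fp, triplet, 6000, np.random.default_rng(4))
        cs = chainset_from_population(pop)
        cd = collision_density(cs, (0, 1))
        mean, sd = collision_normal_params((0, 1), triplet, fp)
        assert kstest(cd.points, "norm", args=(mean, sd)).pvalue > 0.01
        assert cd.realized_fraction > 0.95

    def test_strong_obscuring_truncates_at_origin(self, triplet):
        pop = simulate_population(
            synthetic.obscured_middle(), triplet, 5000, np.random.default_rng(5)
        )
        cs = chainset_from_population(pop)
        cd = collision_density(cs, (0, 1))
        # forks cannot collide beyond an origin they obscure
        assert cd.points.max() <= 1500.0 + 1e-9


class TestFiringDiffDensity:
    def test_gaussian_when_fully_licenced(self, triplet):
        fp = synthetic.strong_origins()
        pop = simulate_population(fp, triplet, 20000, np.random.default_rng(6))
        cs = chainset_from_population(pop)
        fd = firing_diff_density(cs, (0, 1))
        assert not fd.empty
        assert fd.diffs.mean() == pytest.approx(700, abs=3 * 141 / np.sqrt(20000) + 2)
        assert fd.diffs.std() == pytest.approx(141.4, rel=0.05)
        assert fd.threshold == 1300

    def test_mass_beyond_threshold_equals_obscuring(self, triplet):
        pop = simulate_population(
            synthetic.obscured_middle(), triplet, 20000, np.random.default_rng(7)
        )
        cs = chainset_from_population(pop)
        below, above = firing_diff_density(cs, (0, 1)).mass_beyond_threshold()
        obsc = pop.obscuring_matrix()
        # t2 - t1 > N1 <=> O1's fork reaches O2 before it fires
        assert above == pytest.approx(obsc[1, 0] + obsc[1, 2], abs=0.01)

    def test_empty_conditioning_set_flagged(self, triplet):
        fp = ok.FiringParams(np.zeros(3), np.full(3, 100.0), np.array([1.0, 0.0, 1.0]))
        pop = simulate_population(fp, triplet, 500, np.random.default_rng(8))
        cs = chainset_from_population(pop)
        fd = firing_diff_density(cs, (0, 1))
        assert fd.empty
        assert np.isnan(fd.mass_beyond_threshold()[0])


class TestFiringOrder:
    def test_table_one_style_values(self):
        assert round(prob_fires_earlier(4667, 10873), 2) == 0.33
        assert round(prob_fires_earlier(-12205, 15050), 2) == 0.79
        assert round(1 - prob_fires_earlier(-12205, 15050), 2) == 0.21
        assert round(prob_fires_earlier(-11582, 15138), 2) == 0.78

    def test_zero_difference_is_even_odds(self):
        assert prob_fires_earlier(0.0, 123.0) == 0.5

    def test_symmetry_exact(self):
        for d, s in ((100, 50), (4667, 10873), (-3, 7)):
            assert prob_fires_earlier(d, s) + prob_fires_earlier(-d, s) == pytest.approx(
                1.0, abs=1e-15
            )

    def test_rejects_bad_sd(self):
        with pytest.raises(ValueError):
            prob_fires_earlier(100, 0)

    def test_firing_order_table_consistency(self, triplet):
        rng = np.random.default_rng(9)
        n = 500
        theta = np.zeros((n, 11))
        theta[:, 0] = rng.normal(-400, 30, n)
        theta[:, 1] = rng.normal(300, 30, n)
        theta[:, 2] = -(theta[:, 0] + theta[:, 1])
        theta[:, 3:6] = np.abs(rng.normal(100, 5, (n, 3)))
        cs = chainset_from_theta(theta, triplet)
        df = firing_order_table(cs)
        d = theta[:, 1] - theta[:, 0]
        s = np.hypot(theta[:, 3], theta[:, 4])
        expect = prob_fires_earlier(d.mean(), s.mean())
        assert df.iloc[0]["pi_plugin"] == pytest.approx(expect)
        # plug-in and per-sample average agree for tight posteriors
        assert df.iloc[0]["pi_sample_mean"] == pytest.approx(expect, abs=0.02)


class TestReplicationTime:
    def test_sawtooth_in_deterministic_limit(self, triplet):
        fp = ok.FiringParams(np.zeros(3), np.full(3, 1e-9), np.ones(3))
        nu, anchor = 1.6, 10.0
        prof = median_replication_time(
            fp, triplet, nu, anchor_min=anchor, K=200, rng=np.random.default_rng(10)
        )
        x = triplet.x
        expected = anchor + np.min(
            np.abs(prof.positions[None, :] - x[:, None]), axis=0
        ) / (1000 * nu)
        np.testing.assert_allclose(prof.median, expected, atol=1e-6)
        np.testing.assert_allclose(prof.p5, expected, atol=1e-6)

    def test_percentile_ordering_everywhere(self, triplet):
        prof = median_replication_time(
            synthetic.recovery_truth(), triplet, 1.6, K=500, rng=np.random.default_rng(11)
        )
        assert np.all(prof.p5 <= prof.median + 1e-12)
        assert np.all(prof.median <= prof.p95 + 1e-12)

    def test_rejects_bad_inputs(self, triplet):
        fp = synthetic.strong_origins()
        with pytest.raises(ValueError):
            median_replication_time(fp, triplet, -1.0, K=200)
        with pytest.raises(ValueError):
            median_replication_time(fp, triplet, 1.6, K=10)

    def test_to_frame_monotone_columns(self, triplet):
        prof = median_replication_time(
            synthetic.strong_origins(), triplet, 3.3, K=300, rng=np.random.default_rng(12)
        )
        df = prof.to_frame()
        assert (df["t_p5_min"] <= df["t_median_min"]).all()
        assert (df["t_median_min"] <= df["t_p95_min"]).all()


class TestPointEstimates:
    def test_medians_recentred(self, triplet):
        rng = np.random.default_rng(13)
        theta = np.zeros((100, 11))
        theta[:, 0:3] = rng.normal([10, 20, 30], 1.0, (100, 3))
        theta[:, 3:6] = 100.0
        theta[:, 6:9] = 0.9
        theta[:, 9] = 0.1
        theta[:, 10] = 50.0
        fp, noise = point_estimates(chainset_from_theta(theta, triplet))
        assert fp.mu.sum() == pytest.approx(0.0, abs=1e-9)
        assert noise.tau == 50.0


def test_plot_summary_renders(triplet):
    """The summary figure renders from a fabricated chain set."""
    from okfire.plotting import plot_summary

    pop = simulate_population(synthetic.strong_origins(), triplet, 300, np.random.default_rng(20))
    theta = np.concatenate(
        [synthetic.strong_origins().mu, synthetic.strong_origins().sigma,
         synthetic.strong_origins().q, [0.1, 50.0]]
    )
    cs = chainset_from_population(pop, theta_row=theta)
    fig = plot_summary(cs)
    assert len(fig.axes) == 4
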