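"""Deterministic and graded-variance recursive pursuit algorithms."""

import math

import numpy as np
import pytest

from pursuit3d.recursion import (RecursionParams, det_recursion,
                                 det_recursion_1d, det_step, fixed_point,
                                 gv_experiment, gv_recursion_1d, gv_step,
                                 mixture_recursion, speed_gain)

P = RecursionParams()


class GradedVarianceLaw:
    """The exact graded-variance law exposed through the mixture-model API.

    Serves as the conditional generative transform in mixture_recursion
    without any fitting error.
    """

    pre_dim_ = 3

    def __init__(self, p=P):
        self.p = p

    def conditional_sample(self, pre, n, rng):
        az, alt, dist = pre
        p = self.p
        out = np.empty((n, 3))
        out[:, 0] = rng.normal(p.az_slope * az,
                               p.sigma_az_slope * abs(az) + p.sigma_az_intercept, n)
        out[:, 1] = rng.normal(p.alt_slope * alt + p.alt_intercept,
                               p.sigma_az_slope * abs(alt) + p.sigma_az_intercept, n)
        out[:, 2] = np.maximum(0.0, rng.normal(
            p.dist_slope * dist + p.dist_intercept,
            p.sigma_dist_slope * dist + p.sigma_dist_intercept, n))
        return out

    def sample_joint(self, n, rng):
        p = self.p
        az = rng.normal(0.7, 48.4, n)
        alt = np.clip(rng.normal(19.9, 19.7, n), -89, 89)
        dist = np.abs(rng.normal(3.4, 1.6, n)) + 0.2
        post = np.column_stack([c[:, 0] for c in
                                [self.conditional_sample((a, b, d), 1, rng).T
                                 for a, b, d in zip(az, alt, dist)]])
        return np.column_stack([az, alt, dist, post.T.reshape(n, 3)])


class TestDeterministicStep:
    def test_altitude_fixed_point_is_strike_altitude(self):
        # 0.54 * 18.1 + 8.34 = 18.1: the recursion parks prey at 18.1 deg
        _, alt, _ = det_step((0.0, 18.13, 0.5))
        assert float(f"{alt:.3g}") == 18.1

    def test_azimuth_fixed_point_zero(self):
        az, _, _ = det_step((0.0, 0.0, 0.5))
        assert az == 0.0

    def test_distance_transform(self):
        _, _, dist = det_step((0.0, 0.0, 1.0))
        assert dist == pytest.approx(0.84 * 1.0 - 0.0125)

    def test_distance_clamped(self):
        _, _, dist = det_step((0.0, 0.0, 0.01))
        assert dist == 0.0

    def test_contraction_rate_exact(self):
        """Distance from the altitude fixed point shrinks by exactly 0.54."""
        fp = fixed_point(P.alt_slope, P.alt_intercept)
        alt = 60.0
        for _ in range(50):
            new_alt = P.alt_slope * alt + P.alt_intercept
            assert abs(new_alt - fp) == pytest.approx(
                P.alt_slope * abs(alt - fp), abs=1e-12)
            alt = new_alt


class TestFixedPoint:
    def test_altitude_prints_as_18_1(self):
        assert round(fixed_point(0.54, 8.34), 1) == 18.1

    def test_zero_intercept(self):
        assert fixed_point(0.53, 0.0) == 0.0

    def test_distance_fixed_point_below_zero(self):
        # negative fixed point: distance decays through the window
        assert fixed_point(0.84, -0.0125) == pytest.approx(-0.078125)

    def test_unit_slope_rejected(self):
        with pytest.raises(ValueError):
            fixed_point(1.0, 5.0)


class TestDeterministicRecursion:
    def test_start_inside_windows_zero_bouts(self):
        res = det_recursion((0.0, 17.0, 0.5))
        assert res.n_bouts == 0 and res.terminated

    def test_az_from_200_takes_5(self):
        res = det_recursion_1d(200.0, 0.53, 0.0, (-10, 10))
        assert res.n_bouts == 5

    def test_az_just_outside_takes_1(self):
        res = det_recursion_1d(10.1, 0.53, 0.0, (-10, 10))
        assert res.n_bouts == 1

    def test_closed_form_on_full_grid(self):
        """Loop count equals the smallest n with 0.53^n az0 <= 10."""
        for az0 in np.arange(10.1, 200.1, 1.0):
            expected = math.ceil(math.log(10.0 / az0) / math.log(0.53))
            res = det_recursion_1d(float(az0), 0.53, 0.0, (-10, 10))
            assert res.n_bouts == expected

    def test_max_iter_reported(self):
        p = RecursionParams(max_iter=3)
        res = det_recursion((500.0, 0.0, 9.0), p)
        assert res.n_bouts == 3 and not res.terminated


class TestGradedVarianceStep:
    def test_degenerate_noise_is_deterministic(self):
        rng = np.random.default_rng(0)
        v = gv_step(5.0, 0.53, 0.0, 0.0, 1e-15, rng)
        assert v == pytest.approx(0.53 * 5.0, abs=1e-6)

    def test_noise_floor_at_goal(self):
        """At az = 0 the sd is the fixed-noise intercept 7.62 deg."""
        rng = np.random.default_rng(1)
        draws = [gv_step(0.0, 0.53, 0.0, 0.36, 7.62, rng) for _ in range(10_000)]
        assert np.std(draws) == pytest.approx(7.62, abs=0.15)

    def test_graded_sd_at_1mm(self):
        rng = np.random.default_rng(2)
        draws = [gv_step(1.0, 0.84, -0.0125, 0.137, 0.034, rng, clamp=True)
                 for _ in range(10_000)]
        assert np.std(draws) == pytest.approx(0.137 * 1.0 + 0.034, abs=0.005)

    def test_sample_mean_matches_law(self):
        rng = np.random.default_rng(3)
        draws = [gv_step(20.0, 0.53, 0.0, 0.36, 7.62, rng) for _ in range(10_000)]
        sd = 0.36 * 20 + 7.62
        assert np.mean(draws) == pytest.approx(0.53 * 20, abs=3 * sd / 100)


class TestGvExperiment:
    def test_zero_noise_equals_deterministic(self):
        p = RecursionParams(sigma_az_slope=0.0, sigma_az_intercept=1e-12,
                            sigma_dist_slope=0.0, sigma_dist_intercept=1e-12)
        table, summary = gv_experiment(p, reps=1, seed=0)
        assert (table.stoch_median == table.det_bouts).all()

    def test_structure_and_determinism(self):
        grids = dict(dist_grid=np.array([2.0, 4.0]),
                     az_grid=np.array([40.0, 120.0]))
        t1, s1 = gv_experiment(reps=30, seed=6, **grids)
        t2, s2 = gv_experiment(reps=30, seed=6, **grids)
        assert t1.equals(t2) and s1 == s2
        assert set(t1.variable) == {"az", "dist"}
        assert len(t1) == 4

    def test_example_start_present_on_default_grid(self):
        table, _ = gv_experiment(reps=5, seed=0)
        assert 3.8 in set(table[table.variable == "dist"].start)

    def test_nontermination_below_one_percent(self):
        """Graded-variance runs that hit max_iter are rare and reported."""
        table, summary = gv_experiment(reps=100, seed=13)
        total = 100 * len(table)
        stuck = table.n_max_iter.sum()
        assert stuck / total < 0.01
        assert summary["az"]["n_max_iter_total"] == int(
            table[table.variable == "az"].n_max_iter.sum())


class TestParameterRecovery:
    def test_transform_and_noise_slopes_recovered(self):
        """Straight-line fits on 5,000 graded-variance pairs recover the
        generating transform slope (0.53) and noise-law slope (0.36)."""
        rng = np.random.default_rng(4)
        pre = rng.normal(0.7, 48.4, 5_000)  # encounter-distributed azimuths
        post = np.array([gv_step(v, 0.53, 0.0, 0.36, 7.62, rng) for v in pre])
        slope, _ = np.polyfit(pre, post, 1)
        assert slope == pytest.approx(0.53, abs=0.02)
        # binned conditional sd vs azimuth magnitude
        resid = post - 0.53 * pre
        mag = np.abs(pre)
        bins = np.linspace(0, 90, 10)
        centers = (bins[:-1] + bins[1:]) / 2
        sds = [np.std(resid[(mag >= lo) & (mag < hi)], ddof=1)
               for lo, hi in zip(bins[:-1], bins[1:])]
        noise_slope, _ = np.polyfit(centers, sds, 1)
        assert noise_slope == pytest.approx(0.36, abs=0.04)


class TestMixtureRecursion:
    def test_point_mass_model_matches_deterministic(self):
        p0 = RecursionParams(sigma_az_slope=0.0, sigma_az_intercept=1e-12,
                             sigma_dist_slope=0.0, sigma_dist_intercept=1e-12)
        df = mixture_recursion(GradedVarianceLaw(p0),
                               [(40.0, 5.0, 3.0)], reps=5, seed=0)
        det = df[df.arm == "deterministic"].n_bouts.iloc[0]
        assert (df[df.arm == "stochastic"].n_bouts == det).all()

    def test_stochastic_ties_or_beats_deterministic(self):
        """Graded noise never costs the median hunt a bout, and a
        sizeable fraction of stochastic hunts finish strictly faster."""
        starts = []
        rng = np.random.default_rng(30)
        for _ in range(40):
            starts.append((rng.normal(0.7, 48.4),
                           float(np.clip(rng.normal(19.9, 19.7), -89, 89)),
                           abs(rng.normal(3.4, 1.6)) + 0.2))
        df = mixture_recursion(GradedVarianceLaw(), starts, reps=40,
                               overshoot_terminates=True, seed=7)
        det = df[df.arm == "deterministic"].set_index("start_id").n_bouts
        sto = df[df.arm == "stochastic"]
        assert sto.n_bouts.median() <= det.median()
        faster = np.mean([row.n_bouts < det[row.start_id]
                          for row in sto.itertuples()])
        assert faster > 0.10

    def test_same_seed_reproduces(self):
        df1 = mixture_recursion(GradedVarianceLaw(), [(30.0, 10.0, 2.5)],
                                reps=10, seed=3)
        df2 = mixture_recursion(GradedVarianceLaw(), [(30.0, 10.0, 2.5)],
                                reps=10, seed=3)
        assert df1.equals(df2)


class TestSpeedGain:
    def test_printed_range(self):
        assert speed_gain(1, (4, 7)) == (14, 25)

    def test_zero_reduction(self):
        assert speed_gain(0, (4, 7)) == (0, 0)

    def test_two_bout_reduction(self):
        assert speed_gain(2, (4, 8)) == (25, 50)

    def test_reduction_must_be_smaller_than_hunt(self):
        with pytest.raises(ValueError):
            speed_gain(4, (4, 7))
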