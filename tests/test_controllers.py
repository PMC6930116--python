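"""Regression transforms, Euler projection, pool filtering and bout choice."""

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from pursuit3d.controllers import (ControllerKind, EmptyPoolError,
                                   RegressionCoeffs, choose_bout, filter_pool,
                                   project_position, projected_coefficient,
                                   regression_bout, score_bout)
from pursuit3d.geometry import Bout, EgocentricPrey
from pursuit3d.simulator import StrikeZone
from pursuit3d.synthetic import BoutPool, gen_bout_pool

ZONE = StrikeZone()
COEFFS = RegressionCoeffs()


def ego(az=0.0, alt=0.0, dist=3.0, d_az=0.0, d_alt=0.0, d_dist=0.0):
    return EgocentricPrey(az=az, alt=alt, dist=dist, d_az=d_az, d_alt=d_alt,
                          d_dist=d_dist)


class TestRegressionBout:
    def test_altitude_offsets_dive(self):
        # prey level with the fish: dive ~15 deg, rotate down ~2 deg
        b = regression_bout(ego(alt=0.0), COEFFS, 0.176)
        assert b.bout_alt == pytest.approx(-15.13)
        assert b.d_pitch == pytest.approx(-1.79)

    def test_azimuth_offsets_negligible(self):
        b = regression_bout(ego(az=0.0), COEFFS, 0.176)
        assert b.bout_az == pytest.approx(0.3)
        assert b.d_yaw == pytest.approx(0.48)

    def test_velocity_bias(self):
        b = regression_bout(ego(az=10.0, d_az=20.0), COEFFS, 0.176)
        assert b.bout_az == pytest.approx(1.43 * 10 + 0.251 * 20 + 0.3)

    def test_distance_never_negative(self):
        b = regression_bout(ego(dist=0.5, d_dist=-40.0), COEFFS, 0.176)
        assert b.bout_dist == 0.0

    def test_position_only_zeroes_velocity_terms(self):
        c = COEFFS.position_only()
        b_still = regression_bout(ego(az=5.0), c, 0.176)
        b_moving = regression_bout(ego(az=5.0, d_az=100.0, d_dist=5.0), c, 0.176)
        assert b_still.bout_az == b_moving.bout_az
        assert b_still.bout_dist == b_moving.bout_dist


class TestProjection:
    def test_zero_dt_identity(self):
        e = ego(az=10, alt=5, dist=2, d_az=30)
        assert project_position(e, 0.0) == e

    def test_euler_step(self):
        # mean observed azimuth rate over a mean-duration bout
        e = project_position(ego(az=10.0, d_az=29.0), 0.176)
        assert e.az == pytest.approx(10 + 29 * 0.176)

    def test_zero_velocity_identity(self):
        e = ego(az=-20, alt=10, dist=4)
        assert project_position(e, 1.0) == e

    @pytest.mark.parametrize("slope_vel, expected", [
        (0.251, 1.43), (0.300, 1.70), (0.0, 0.0)])
    def test_projected_coefficient(self, slope_vel, expected):
        assert round(projected_coefficient(slope_vel, 0.176), 2) == expected

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            projected_coefficient(0.251, 0.0)


@given(az=st.floats(-60, 60), alt=st.floats(-40, 40), dist=st.floats(0.3, 8),
       d_az=st.floats(-50, 50), d_alt=st.floats(-50, 50),
       d_dist=st.floats(-3, 3), dur=st.floats(0.1, 0.3))
def test_velocity_equals_position_on_projected_prey(az, alt, dist, d_az,
                                                    d_alt, d_dist, dur):
    """If slope_vel = slope_pos * duration in every channel, transforming
    (position, velocity) equals transforming the Euler-projected position:
    the projected-coefficient identity."""
    assume(dist + d_dist * dur > 0)
    assume(abs(alt + d_alt * dur) < 89)
    c = RegressionCoeffs(
        slope_vel_az=COEFFS.slope_pos_az * dur,
        slope_vel_yaw=COEFFS.slope_pos_yaw * dur,
        slope_vel_alt=COEFFS.slope_pos_alt * dur,
        slope_vel_pitch=COEFFS.slope_pos_pitch * dur,
        slope_vel_dist=COEFFS.slope_pos_dist * dur)
    e = ego(az, alt, dist, d_az, d_alt, d_dist)
    with_vel = regression_bout(e, c, dur)
    on_projected = regression_bout(project_position(e, dur),
                                   c.position_only(), dur)
    for f in ("bout_az", "bout_alt", "bout_dist", "d_yaw", "d_pitch"):
        assert getattr(with_vel, f) == pytest.approx(getattr(on_projected, f),
                                                     abs=1e-9)


class TestFilterPool:
    def pool(self, durations):
        return BoutPool(bouts=[Bout(duration=d) for d in durations])

    def test_identity_filter(self):
        p = self.pool([0.1, 0.2, 0.3])
        assert filter_pool(p, 0.0, np.inf).bouts == p.bouts

    def test_window_filter(self):
        p = self.pool([0.10, 0.18, 0.30])
        kept = filter_pool(p, 0.15, 0.25)
        assert [b.duration for b in kept.bouts] == [0.18]

    def test_empty_result_signalled(self):
        with pytest.raises(EmptyPoolError):
            filter_pool(self.pool([0.1, 0.2]), 0.5, np.inf)


class TestScoreBout:
    def test_zero_score_at_zone_means(self):
        # null bout leaves the percept where it is: already at the means
        e = ego(az=ZONE.az_mean, alt=ZONE.alt_mean, dist=ZONE.dist_mean)
        assert score_bout(Bout(duration=0.176), e, ZONE) == pytest.approx(
            0.0, abs=1e-12)

    def test_closer_candidate_scores_lower(self):
        e = ego(az=30.0, alt=0.0, dist=3.0)
        toward = Bout(bout_az=30.0, bout_dist=1.5, d_yaw=25.0, duration=0.176)
        away = Bout(bout_az=-30.0, bout_dist=1.0, d_yaw=-25.0, duration=0.176)
        assert score_bout(toward, e, ZONE) < score_bout(away, e, ZONE)

    @pytest.mark.parametrize("project", [False, True])
    def test_ideal_choice_is_brute_force_argmin(self, project):
        """Vectorised pool choice equals exhaustive scalar scoring."""
        pool = gen_bout_pool(n=100, seed=17)
        kind = (ControllerKind.IDEAL_VELOCITY if project
                else ControllerKind.IDEAL_POSITION)
        for e in (ego(az=40, alt=10, dist=3, d_az=-25, d_dist=1.0),
                  ego(az=-15, alt=25, dist=1.2, d_alt=12.0),
                  ego(az=0, alt=17, dist=0.9)):
            scores = [score_bout(b, e, ZONE, project=project)
                      for b in pool.bouts]
            expected = pool.bouts[int(np.argmin(scores))]
            chosen = choose_bout(kind, e, pool=pool, zone=ZONE)
            assert chosen.bout_az == expected.bout_az
            assert chosen.duration == expected.duration


class TestChooseBout:
    def test_random_single_bout_pool(self):
        pool = BoutPool(bouts=[Bout(bout_az=5.0, duration=0.2)])
        b = choose_bout(ControllerKind.RANDOM_CHOICE, ego(), pool=pool,
                        rng=np.random.default_rng(0))
        assert b.bout_az == 5.0

    def test_ideal_finds_zero_score_bout(self):
        e = ego(az=ZONE.az_mean, alt=ZONE.alt_mean, dist=ZONE.dist_mean)
        zero = Bout(duration=0.176)
        decoy = Bout(bout_az=40.0, bout_dist=2.0, duration=0.176)
        pool = BoutPool(bouts=[decoy, zero])
        b = choose_bout(ControllerKind.IDEAL_POSITION, e, pool=pool, zone=ZONE)
        assert b.bout_az == 0.0 and b.bout_dist == 0.0

    def test_projection_moot_for_static_prey(self):
        pool = gen_bout_pool(n=60, seed=23)
        e = ego(az=25.0, alt=5.0, dist=2.5)  # zero velocities
        a = choose_bout(ControllerKind.IDEAL_POSITION, e, pool=pool, zone=ZONE)
        b = choose_bout(ControllerKind.IDEAL_VELOCITY, e, pool=pool, zone=ZONE)
        assert a == b

    def test_regression_kind_needs_coeffs(self):
        with pytest.raises(ValueError):
            choose_bout(ControllerKind.REGRESSION_VELOCITY, ego())

    def test_choice_kind_needs_pool(self):
        with pytest.raises(EmptyPoolError):
            choose_bout(ControllerKind.IDEAL_POSITION, ego(), zone=ZONE)

    def test_filter_fallback_logged(self, caplog):
        pool = BoutPool(bouts=[Bout(duration=0.1)])
        with caplog.at_level("WARNING", logger="pursuit3d.controllers"):
            b = choose_bout(ControllerKind.RANDOM_CHOICE, ego(), pool=pool,
                            rng=np.random.default_rng(1), min_duration=0.5)
        assert b.duration == 0.1
        assert "unfiltered" in caplog.text

    def test_deterministic_given_seed(self):
        pool = gen_bout_pool(n=40, seed=2)
        picks = [choose_bout(ControllerKind.RANDOM_CHOICE, ego(), pool=pool,
                             rng=np.random.default_rng(99)) for _ in range(2)]
        assert picks[0] == picks[1]
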