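"""Bout-choice controllers: regression, random and ideal pool choice.

Six controller kinds map an egocentric prey percept to the next bout:

* ``replay`` — re-issue recorded bouts (or, lacking recordings, a
  noisy velocity-regression surrogate; see :mod:`pursuit3d.simulator`);
* ``regression_position`` — linear transform of prey position only;
* ``regression_velocity`` — linear transform of prey position and
  velocity (the Euler-projection strategy);
* ``random_choice`` — a random bout from the pursuit-bout pool;
* ``ideal_position`` / ``ideal_velocity`` — the pool bout minimising a
  normalised squared distance of the post-bout prey coordinate to the
  strike-zone means, without / with Euler projection of prey motion.

The velocity regression encodes the field's central observation: the
velocity coefficients divided by the mean bout duration reproduce the
position coefficients, i.e. the fish transforms a Euler-projected
future prey position rather than reacting to velocity per se.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from typing import TYPE_CHECKING, Optional

import numpy as np

from .geometry import (Bout, EgocentricPrey, FishState, apply_bout,
                       fish_frame, from_egocentric, to_egocentric)

if TYPE_CHECKING:  # avoid a runtime cycle with synthetic (pool generation)
    from .synthetic import BoutPool

log = logging.getLogger(__name__)

__all__ = [
    "RegressionCoeffs",
    "ControllerKind",
    "EmptyPoolError",
    "regression_bout",
    "project_position",
    "projected_coefficient",
    "filter_pool",
    "score_bout",
    "choose_bout",
]

#: mean pursuit bout duration, s
MEAN_BOUT_DURATION = 0.176


@dataclass(frozen=True)
class RegressionCoeffs:
    """Linear bout-transform coefficients.

    Each bout variable k is ``slope_pos_k * position + slope_vel_k *
    rate + offset_k``.  Position slopes default to the projected
    coefficients (velocity slope / mean bout duration); velocity slopes
    and offsets to the printed multiple-regression fits.  Velocity
    slopes carry units of seconds (they multiply deg/s or mm/s).
    """

    slope_pos_az: float = 1.43
    slope_vel_az: float = 0.251
    offset_az: float = 0.3          # deg
    slope_pos_yaw: float = 0.31
    slope_vel_yaw: float = 0.054
    offset_yaw: float = 0.48        # deg
    slope_pos_alt: float = 1.70
    slope_vel_alt: float = 0.300
    offset_alt: float = -15.13      # deg
    slope_pos_pitch: float = 0.18
    slope_vel_pitch: float = 0.031
    offset_pitch: float = -1.79     # deg
    slope_pos_dist: float = 0.105
    slope_vel_dist: float = 0.053
    offset_dist: float = 0.0        # mm

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if not np.isfinite(value):
                raise ValueError(f"{name} not finite")

    def position_only(self) -> "RegressionCoeffs":
        """Copy with all velocity slopes zeroed (position-only model)."""
        return replace(self, slope_vel_az=0.0, slope_vel_yaw=0.0,
                       slope_vel_alt=0.0, slope_vel_pitch=0.0,
                       slope_vel_dist=0.0)


class ControllerKind(str, Enum):
    REPLAY = "replay"
    REGRESSION_POSITION = "regression_position"
    REGRESSION_VELOCITY = "regression_velocity"
    RANDOM_CHOICE = "random_choice"
    IDEAL_POSITION = "ideal_position"
    IDEAL_VELOCITY = "ideal_velocity"


class EmptyPoolError(ValueError):
    """Duration filtering left no candidate bouts."""


def regression_bout(ego: EgocentricPrey, coeffs: RegressionCoeffs,
                    duration: float, onset_time: float = 0.0) -> Bout:
    """Linear transform of the prey percept into the next bout."""
    c = coeffs
    return Bout(
        bout_az=c.slope_pos_az * ego.az + c.slope_vel_az * ego.d_az + c.offset_az,
        bout_alt=c.slope_pos_alt * ego.alt + c.slope_vel_alt * ego.d_alt + c.offset_alt,
        bout_dist=max(0.0, c.slope_pos_dist * ego.dist
                      + c.slope_vel_dist * ego.d_dist + c.offset_dist),
        d_yaw=c.slope_pos_yaw * ego.az + c.slope_vel_yaw * ego.d_az + c.offset_yaw,
        d_pitch=c.slope_pos_pitch * ego.alt + c.slope_vel_pitch * ego.d_alt
        + c.offset_pitch,
        duration=duration, onset_time=onset_time)


def project_position(ego: EgocentricPrey, dt: float) -> EgocentricPrey:
    """Euler-project the prey percept forward by ``dt`` seconds.

    Future position = current position + instantaneous rate * dt;
    rates are left unchanged.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    alt = float(np.clip(ego.alt + ego.d_alt * dt, -90.0, 90.0))
    return EgocentricPrey(az=ego.az + ego.d_az * dt, alt=alt,
                          dist=max(0.0, ego.dist + ego.d_dist * dt),
                          d_az=ego.d_az, d_alt=ego.d_alt, d_dist=ego.d_dist)


def projected_coefficient(slope_vel: float,
                          mean_duration: float = MEAN_BOUT_DURATION) -> float:
    """Convert a velocity coefficient (s) to its projected positional one.

    Dividing the velocity-regression coefficient by the mean bout
    duration gives the coefficient applied to the projected change in
    prey position over an average bout.
    """
    if mean_duration <= 0:
        raise ValueError("mean_duration must be > 0")
    return slope_vel / mean_duration


def filter_pool(pool: "BoutPool", min_duration: float = 0.0,
                max_end_gap: float = np.inf) -> "BoutPool":
    """Duration pre-filter applied before pool choice.

    A candidate may not be shorter than the bout scheduled at this
    juncture (``min_duration``) and may not extend past the next
    scheduled onset (``max_end_gap``).
    """
    kept = [b for b in pool.bouts
            if min_duration <= b.duration <= max_end_gap]
    if not kept:
        raise EmptyPoolError(
            f"no pool bout with duration in [{min_duration}, {max_end_gap}]")
    return replace(pool, bouts=kept)


_CANONICAL = FishState(position=np.zeros(3), yaw=0.0, pitch=0.0)


def score_bout(candidate: Bout, ego: EgocentricPrey, zone,
               project: bool = False) -> float:
    """Score a candidate bout by closeness of post-bout prey to the zone.

    The candidate is simulated from a canonical origin-aligned fish
    state; the prey (optionally Euler-projected to the candidate's end
    time) is re-expressed in the post-bout frame and the score is the
    sum over az/alt/dist of squared zone-normalised deviations from the
    strike-zone means.  Lower is better.
    """
    target = project_position(ego, candidate.duration) if project else ego
    prey_world = from_egocentric(_CANONICAL, target.az, target.alt, target.dist)
    post_state = apply_bout(_CANONICAL, candidate)
    az, alt, dist = to_egocentric(post_state, prey_world)
    return (((az - zone.az_mean) / zone.az_sd) ** 2
            + ((alt - zone.alt_mean) / zone.alt_sd) ** 2
            + ((dist - zone.dist_mean) / zone.dist_sd) ** 2)


def _score_pool_vectorised(bouts_arr: dict, ego: EgocentricPrey, zone,
                           project: bool) -> np.ndarray:
    """Scores of all pool candidates at once (numpy broadcast).

    ``bouts_arr`` holds per-field arrays (see BoutPool.as_arrays).
    The geometry mirrors score_bout from the canonical identity frame,
    where forward/right/up are the world axes (+x, -y, +z).
    """
    dur = bouts_arr["duration"]
    if project:
        az_p = ego.az + ego.d_az * dur
        alt_p = np.clip(ego.alt + ego.d_alt * dur, -90.0, 90.0)
        dist_p = np.maximum(0.0, ego.dist + ego.d_dist * dur)
    else:
        az_p = np.full_like(dur, ego.az)
        alt_p = np.full_like(dur, ego.alt)
        dist_p = np.full_like(dur, ego.dist)
    azr, altr = np.deg2rad(az_p), np.deg2rad(alt_p)
    # prey in identity frame: forward=+x, right=-y, up=+z
    px = dist_p * np.cos(altr) * np.cos(azr)
    py = -dist_p * np.cos(altr) * np.sin(azr)
    pz = dist_p * np.sin(altr)
    bazr, baltr = np.deg2rad(bouts_arr["bout_az"]), np.deg2rad(bouts_arr["bout_alt"])
    bd = bouts_arr["bout_dist"]
    vx = px - bd * np.cos(baltr) * np.cos(bazr)
    vy = py + bd * np.cos(baltr) * np.sin(bazr)
    vz = pz - bd * np.sin(baltr)
    # post-bout frame from (d_yaw, clamped d_pitch)
    yawr = np.deg2rad(bouts_arr["d_yaw"])
    pitchr = np.deg2rad(np.clip(bouts_arr["d_pitch"], -90.0, 90.0))
    fx = np.cos(pitchr) * np.cos(yawr)
    fy = -np.cos(pitchr) * np.sin(yawr)
    fz = np.sin(pitchr)
    rx, ry, rz = -np.sin(yawr), -np.cos(yawr), np.zeros_like(yawr)
    ux = ry * fz - rz * fy
    uy = rz * fx - rx * fz
    uz = rx * fy - ry * fx
    dist = np.sqrt(vx ** 2 + vy ** 2 + vz ** 2)
    safe = np.where(dist > 0, dist, 1.0)
    az = np.rad2deg(np.arctan2(vx * rx + vy * ry + vz * rz,
                               vx * fx + vy * fy + vz * fz))
    alt = np.rad2deg(np.arcsin(np.clip((vx * ux + vy * uy + vz * uz) / safe,
                                       -1.0, 1.0)))
    return (((az - zone.az_mean) / zone.az_sd) ** 2
            + ((alt - zone.alt_mean) / zone.alt_sd) ** 2
            + ((dist - zone.dist_mean) / zone.dist_sd) ** 2)


def _filtered_or_full(pool, min_duration, max_end_gap):
    try:
        return filter_pool(pool, min_duration, max_end_gap)
    except EmptyPoolError:
        log.warning("duration filter emptied the pool; falling back to the "
                    "unfiltered pool (min=%.3f, max=%.3f)",
                    min_duration, max_end_gap)
        return pool


def choose_bout(kind: ControllerKind, ego: EgocentricPrey,
                pool: Optional["BoutPool"] = None,
                coeffs: Optional[RegressionCoeffs] = None,
                zone=None, rng: Optional[np.random.Generator] = None,
                duration: float = MEAN_BOUT_DURATION,
                min_duration: float = 0.0,
                max_end_gap: float = np.inf,
                onset_time: float = 0.0) -> Bout:
    """Dispatch a single bout decision for one controller kind.

    Regression kinds need ``coeffs`` (the position kind zeroes the
    velocity slopes); pool-choice kinds need ``pool`` and ``zone``
    (plus ``rng`` for random choice) and honour the duration filter.
    Ideal choice breaks ties at the lowest pool index.
    """
    kind = ControllerKind(kind)
    if kind in (ControllerKind.REGRESSION_POSITION,
                ControllerKind.REGRESSION_VELOCITY, ControllerKind.REPLAY):
        if coeffs is None:
            raise ValueError(f"{kind.value} requires regression coefficients")
        if kind is ControllerKind.REGRESSION_POSITION:
            coeffs = coeffs.position_only()
        return regression_bout(ego, coeffs, duration, onset_time)
    if pool is None or not pool.bouts:
        raise EmptyPoolError(f"{kind.value} requires a non-empty bout pool")
    cand = _filtered_or_full(pool, min_duration, max_end_gap)
    if kind is ControllerKind.RANDOM_CHOICE:
        if rng is None:
            raise ValueError("random_choice requires an rng")
        chosen = cand.bouts[int(rng.integers(len(cand.bouts)))]
    else:
        if zone is None:
            raise ValueError("ideal choice requires a strike zone")
        scores = _score_pool_vectorised(
            cand.as_arrays(), ego, zone,
            project=kind is ControllerKind.IDEAL_VELOCITY)
        chosen = cand.bouts[int(np.argmin(scores))]
    return replace(chosen, onset_time=onset_time)
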