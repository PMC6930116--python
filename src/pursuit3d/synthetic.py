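"""Synthetic prey trajectories, encounters, bout schedules and bout pools.

This module replaces the study's raw recordings with generators that
reproduce the statistical structure the analysis assumes:

* paramecium swimming in a 2x2x2 cm tank sampled at 62.5 Hz, with the
  observed heavy-tailed speed structure (74% of frames above 3 body
  lengths/s, 27% above 6);
* hunt initial conditions (prey placed at the measured egocentric
  Gaussians: az 0.7 +/- 48.4 deg, alt 19.9 +/- 19.7 deg, dist 3.4 +/-
  1.6 mm);
* bout timing (log-normal durations, median 176 ms, IQR 144-208 ms);
* a pursuit-bout pool (nominal size 1782) produced by running the
  velocity-regression controller with graded noise on random percepts.

All generators are pure functions of (params, seed): identical inputs
give identical output arrays.  The tank is centred on the origin.

Prey motion model
-----------------
Velocity follows a 3-D Ornstein-Uhlenbeck process (exponentially
correlated, correlation time ``speed_persistence``) with occasional
isotropic "tumbles" that redirect the velocity while preserving speed,
and reflecting walls.  A single OU process has a Maxwell stationary
speed distribution, which is too thin-tailed to match both printed
speed-tail fractions simultaneously; real paramecium populations are
heterogeneous, so each trajectory draws its own speed scale from a
log-normal across-individual distribution.  The two calibration
constants (``speed_scale``, ``speed_log_sd``) were solved once from the
two tail equations and are frozen here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .controllers import RegressionCoeffs, regression_bout
from .geometry import Bout, EgocentricPrey, FishState, from_egocentric
from .recursion import RecursionParams

__all__ = [
    "PreyMotionParams",
    "EncounterParams",
    "BoutScheduleParams",
    "BoutPool",
    "gen_prey_trajectory",
    "gen_encounter",
    "gen_bout_schedule",
    "gen_bout_pool",
    "speed_tail_fractions",
]

#: swimming-prey speed threshold, mm/s (below it prey are "floating")
SWIMMING_THRESHOLD = 0.330


@dataclass(frozen=True)
class PreyMotionParams:
    """Paramecium trajectory generator parameters.

    ``speed_scale`` is the median per-component OU stationary sd (mm/s)
    across trajectories; ``speed_log_sd`` the log-normal sd of the
    per-trajectory multiplier.  Both were calibrated jointly against
    the two speed-tail fractions and should be treated as one frozen
    unit.  ``paramecium_length`` converts body lengths/s to mm/s.
    """

    frame_rate: float = 62.5          # Hz
    tank_edge: float = 20.0           # mm, cube side
    paramecium_length: float = 0.2    # mm
    speed_persistence: float = 0.5    # s, velocity correlation time
    speed_scale: float = 0.578        # mm/s, calibrated
    speed_log_sd: float = 0.312       # calibrated
    tumble_rate: float = 0.2          # 1/s
    seed: int = 0

    def __post_init__(self):
        for name in ("frame_rate", "tank_edge", "paramecium_length",
                     "speed_persistence"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.speed_scale < 0 or self.speed_log_sd < 0 or self.tumble_rate < 0:
            raise ValueError("speed_scale, speed_log_sd, tumble_rate must be >= 0")


@dataclass(frozen=True)
class EncounterParams:
    """Egocentric prey placement at hunt initiation (Gaussian draws)."""

    az_mean: float = 0.7      # deg
    az_sd: float = 48.4
    alt_mean: float = 19.9    # deg
    alt_sd: float = 19.7
    dist_mean: float = 3.4    # mm
    dist_sd: float = 1.6
    min_dist: float = 0.2     # mm, truncation of the distance draw
    seed: int = 0

    def __post_init__(self):
        if min(self.az_sd, self.alt_sd, self.dist_sd) <= 0:
            raise ValueError("sds must be > 0")


@dataclass(frozen=True)
class BoutScheduleParams:
    """Bout timing: log-normal durations plus exponential inter-bout gaps.

    Only the duration median and IQR are measured; the inter-bout
    interval mean is an assumption exposed here.
    """

    duration_median: float = 0.176            # s
    duration_iqr: tuple = (0.144, 0.208)      # s
    interbout_interval_mean: float = 0.35     # s (assumption)
    interbout_interval_min: float = 0.05      # s
    #: bouts per schedule; default is the upper quartile of real
    #: successful hunt lengths — model hunts get the bout budget of a
    #: long real hunt, and are "exhausted" beyond it
    n_bouts_max: int = 7
    seed: int = 0

    def __post_init__(self):
        q1, q3 = self.duration_iqr
        if not 0 < q1 <= self.duration_median <= q3:
            raise ValueError("duration quantiles must be ordered and positive")
        if self.n_bouts_max < 1:
            raise ValueError("n_bouts_max must be >= 1")


@dataclass(frozen=True)
class BoutPool:
    """The pursuit repertoire: a pool of candidate bouts.

    ``provenance`` records whether the pool is synthetic or file-loaded.
    """

    bouts: tuple
    provenance: str = "synthetic"

    def __post_init__(self):
        object.__setattr__(self, "bouts", tuple(self.bouts))

    def __len__(self):
        return len(self.bouts)

    def as_arrays(self) -> dict:
        """Per-field numpy arrays for vectorised scoring (cached)."""
        cache = self.__dict__.get("_arrays")
        if cache is None:
            cache = {name: np.array([getattr(b, name) for b in self.bouts])
                     for name in ("bout_az", "bout_alt", "bout_dist",
                                  "d_yaw", "d_pitch", "duration")}
            object.__setattr__(self, "_arrays", cache)
        return cache


def _rng(params_seed: int, seed: Optional[int]) -> np.random.Generator:
    return np.random.default_rng(params_seed if seed is None else seed)


def gen_prey_trajectory(params: PreyMotionParams, duration: float,
                        seed: Optional[int] = None) -> np.ndarray:
    """Simulate one paramecium path; returns (n, 3) positions in mm.

    OU velocity (exact discretisation), Poisson tumbles preserving
    speed, reflecting walls; n = round(duration * frame_rate) + 1.
    """
    if duration < 1.0 / params.frame_rate:
        raise ValueError("duration shorter than one frame")
    rng = _rng(params.seed, seed)
    dt = 1.0 / params.frame_rate
    n = int(round(duration * params.frame_rate)) + 1
    half = params.tank_edge / 2.0
    sigma = params.speed_scale * np.exp(params.speed_log_sd * rng.standard_normal())
    decay = np.exp(-dt / params.speed_persistence)
    kick = sigma * np.sqrt(max(0.0, 1.0 - decay ** 2))
    pos = np.empty((n, 3))
    pos[0] = rng.uniform(-0.8 * half, 0.8 * half, size=3)
    v = sigma * rng.standard_normal(3)
    p_tumble = 1.0 - np.exp(-params.tumble_rate * dt)
    for i in range(1, n):
        v = decay * v + kick * rng.standard_normal(3)
        if rng.random() < p_tumble:
            speed = np.linalg.norm(v)
            u = rng.standard_normal(3)
            norm = np.linalg.norm(u)
            if norm > 0:
                v = speed * u / norm
        p = pos[i - 1] + v * dt
        # reflecting walls
        for k in range(3):
            if p[k] > half:
                p[k] = 2 * half - p[k]
                v[k] = -v[k]
            elif p[k] < -half:
                p[k] = -2 * half - p[k]
                v[k] = -v[k]
        pos[i] = np.clip(p, -half, half)
    return pos


def speed_tail_fractions(trajectories, params: PreyMotionParams,
                         thresholds=(3.0, 6.0)) -> tuple:
    """Fraction of frames with 3D speed above each threshold (body lengths/s)."""
    speeds = []
    for traj in trajectories:
        d = np.diff(np.asarray(traj), axis=0) * params.frame_rate
        speeds.append(np.linalg.norm(d, axis=1))
    speeds = np.concatenate(speeds) / params.paramecium_length
    return tuple(float(np.mean(speeds > t)) for t in thresholds)


def gen_encounter(params: EncounterParams, tank_edge: float = 20.0,
                  seed: Optional[int] = None, max_retries: int = 100):
    """Draw one hunt initial condition: (FishState, prey world position).

    The fish is placed uniformly in the central half of the tank with a
    random yaw and zero pitch; the prey at egocentric coordinates drawn
    from the three measured Gaussians (distance truncated above
    ``min_dist``).  Draws that would place the prey outside the tank
    are redone, up to ``max_retries``.
    """
    rng = _rng(params.seed, seed)
    half = tank_edge / 2.0
    for _ in range(max_retries):
        fish = FishState(position=rng.uniform(-half / 2, half / 2, size=3),
                         yaw=rng.uniform(-180.0, 180.0), pitch=0.0)
        az = rng.normal(params.az_mean, params.az_sd)
        alt = float(np.clip(rng.normal(params.alt_mean, params.alt_sd),
                            -89.9, 89.9))
        dist = rng.normal(params.dist_mean, params.dist_sd)
        while dist <= params.min_dist:
            dist = rng.normal(params.dist_mean, params.dist_sd)
        prey = from_egocentric(fish, az, alt, dist)
        if np.all(np.abs(prey) < half):
            return fish, prey
    raise RuntimeError(f"no valid encounter after {max_retries} retries")


def _duration_lognorm_params(params: BoutScheduleParams):
    q1, q3 = params.duration_iqr
    mu = np.log(params.duration_median)
    # quartiles of a log-normal sit at exp(mu +/- 0.6745 sigma)
    sigma = (np.log(q3) - np.log(q1)) / (2 * 0.674489750196082)
    return mu, sigma


def gen_bout_schedule(params: BoutScheduleParams,
                      seed: Optional[int] = None) -> list:
    """Generate [(onset_time, duration), ...] with strictly increasing onsets."""
    rng = _rng(params.seed, seed)
    mu, sigma = _duration_lognorm_params(params)
    durations = np.exp(mu + sigma * rng.standard_normal(params.n_bouts_max))
    gaps = params.interbout_interval_min + rng.exponential(
        max(params.interbout_interval_mean - params.interbout_interval_min, 0.0),
        size=params.n_bouts_max)
    onsets = np.empty(params.n_bouts_max)
    onsets[0] = 0.0
    for i in range(1, params.n_bouts_max):
        onsets[i] = onsets[i - 1] + durations[i - 1] + gaps[i - 1]
    return list(zip(onsets.tolist(), durations.tolist()))


def gen_bout_pool(coeffs: RegressionCoeffs = RegressionCoeffs(),
                  noise_law: RecursionParams = RecursionParams(),
                  n: int = 1782,
                  encounter: EncounterParams = EncounterParams(),
                  schedule: BoutScheduleParams = BoutScheduleParams(),
                  prey_rate_sds=(36.3, 31.3, 1.0),
                  seed: int = 0) -> BoutPool:
    """Generate a synthetic pursuit repertoire of ``n`` bouts.

    Each pool bout samples an encounter-distributed egocentric percept
    with Gaussian prey rates (sds chosen so the mean absolute angular
    rates match the observed 29 and 25 deg/s), applies the
    velocity-regression controller, and perturbs each bout variable
    with graded noise (sd from the graded-variance laws evaluated at
    the percept; yaw/pitch noise scaled by the ratio of their slopes to
    the az/alt slopes).  Durations follow the bout-timing law.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mu, sig = _duration_lognorm_params(schedule)
    yaw_ratio = coeffs.slope_vel_yaw / coeffs.slope_vel_az
    pitch_ratio = coeffs.slope_vel_pitch / coeffs.slope_vel_alt
    bouts = []
    for _ in range(n):
        az = rng.normal(encounter.az_mean, encounter.az_sd)
        alt = float(np.clip(rng.normal(encounter.alt_mean, encounter.alt_sd),
                            -89.9, 89.9))
        dist = rng.normal(encounter.dist_mean, encounter.dist_sd)
        while dist <= encounter.min_dist:
            dist = rng.normal(encounter.dist_mean, encounter.dist_sd)
        ego = EgocentricPrey(az=az, alt=alt, dist=dist,
                             d_az=rng.normal(0.0, prey_rate_sds[0]),
                             d_alt=rng.normal(0.0, prey_rate_sds[1]),
                             d_dist=rng.normal(0.0, prey_rate_sds[2]))
        duration = float(np.exp(mu + sig * rng.standard_normal()))
        base = regression_bout(ego, coeffs, duration)
        sd_az = noise_law.sigma_az_slope * abs(az) + noise_law.sigma_az_intercept
        sd_alt = noise_law.sigma_az_slope * abs(alt) + noise_law.sigma_az_intercept
        sd_dist = (noise_law.sigma_dist_slope * dist
                   + noise_law.sigma_dist_intercept)
        bouts.append(Bout(
            bout_az=base.bout_az + rng.normal(0.0, sd_az),
            bout_alt=base.bout_alt + rng.normal(0.0, sd_alt),
            bout_dist=max(0.0, base.bout_dist + rng.normal(0.0, sd_dist)),
            d_yaw=base.d_yaw + rng.normal(0.0, sd_az * yaw_ratio),
            d_pitch=base.d_pitch + rng.normal(0.0, sd_alt * pitch_ratio),
            duration=duration))
    return BoutPool(bouts=bouts, provenance="synthetic")
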