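"""Virtual prey-capture simulation environment.

A virtual fish (3D position, yaw, pitch) is driven by one of the bout
controllers against a prey trajectory, issuing bouts at scheduled
onsets.  The hunt terminates with outcome ``strike`` the first time the
prey lies inside the egocentric strike zone — evaluated at every bout
end and at every inter-bout frame, since prey can drift into the zone
while the fish is quiescent — or ``exhausted`` when the schedule ends.
Each bout's energetic cost (translational kinetic energy of the centre
of mass plus rotational energy of yaw and pitch, point-mass inertia) is
accumulated per hunt, and the post-bout prey coordinates are recorded
for distributional comparison across controllers.

Cohorts run every controller on identical trajectories, encounters and
schedules (shared child seeds), so model comparisons are paired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .controllers import (ControllerKind, RegressionCoeffs, choose_bout,
                          regression_bout)
from .geometry import (Bout, EgocentricPrey, FishState, apply_bout,
                       to_egocentric, to_egocentric_many)
from .recursion import RecursionParams
from .synthetic import (BoutPool, BoutScheduleParams, EncounterParams,
                        PreyMotionParams, gen_bout_pool, gen_bout_schedule,
                        gen_encounter, gen_prey_trajectory)

log = logging.getLogger(__name__)

__all__ = [
    "StrikeZone",
    "EnergyParams",
    "SimResult",
    "in_strike_zone",
    "bout_energy",
    "run_hunt",
    "run_cohort",
]


@dataclass(frozen=True)
class StrikeZone:
    """Egocentric region in which strikes are launched.

    Means are the measured strike coordinates; only the azimuth sd is
    measured (7.2 deg) — the altitude and distance sds are assumptions
    exposed in config.  The angular window spans ``angular_k`` sds
    (default 1.96, a 95% interval) and the radial window ``dist_k`` sds
    (default 2).
    """

    az_mean: float = 0.9       # deg
    alt_mean: float = 17.4     # deg
    dist_mean: float = 0.870   # mm
    az_sd: float = 7.2         # deg, measured
    alt_sd: float = 7.0        # deg, assumption
    dist_sd: float = 0.30      # mm, assumption
    angular_k: float = 1.96
    dist_k: float = 2.0

    def __post_init__(self):
        if min(self.az_sd, self.alt_sd, self.dist_sd) <= 0:
            raise ValueError("zone sds must be > 0")
        if self.angular_k <= 0 or self.dist_k <= 0:
            raise ValueError("window multipliers must be > 0")


@dataclass(frozen=True)
class EnergyParams:
    """Fish mass and head-to-centre-of-mass distance, SI units."""

    mass: float = 1e-6         # kg (1 mg)
    com_radius: float = 5.3e-4  # m (0.53 mm)

    def __post_init__(self):
        if self.mass <= 0 or self.com_radius <= 0:
            raise ValueError("mass and com_radius must be > 0")


@dataclass(frozen=True)
class SimResult:
    """Outcome of one simulated hunt."""

    outcome: str               # "strike" | "exhausted"
    n_bouts: int
    energy: float              # joules
    post_bout_coords: tuple    # ((az, alt, dist), ...) after each bout
    kind: str
    seed: Optional[int] = None


def in_strike_zone(ego, zone: StrikeZone = StrikeZone()) -> bool:
    """True iff (az, alt, dist) lies inside the closed zone windows."""
    if isinstance(ego, EgocentricPrey):
        az, alt, dist = ego.az, ego.alt, ego.dist
    else:
        az, alt, dist = ego
    return (abs(az - zone.az_mean) <= zone.angular_k * zone.az_sd
            and abs(alt - zone.alt_mean) <= zone.angular_k * zone.alt_sd
            and abs(dist - zone.dist_mean) <= zone.dist_k * zone.dist_sd)


def _in_zone_mask(az, alt, dist, zone: StrikeZone) -> np.ndarray:
    return ((np.abs(az - zone.az_mean) <= zone.angular_k * zone.az_sd)
            & (np.abs(alt - zone.alt_mean) <= zone.angular_k * zone.alt_sd)
            & (np.abs(dist - zone.dist_mean) <= zone.dist_k * zone.dist_sd))


def bout_energy(bout: Bout, params: EnergyParams = EnergyParams()) -> float:
    """Energy of one bout, joules.

    E = 1/2 m (d/T)^2 + 1/2 I (w_yaw^2 + w_pitch^2), with point-mass
    inertia I = m r^2 and angular speeds in rad/s.  Displacement is
    converted mm -> m.
    """
    v = (bout.bout_dist * 1e-3) / bout.duration
    w_yaw = np.deg2rad(bout.d_yaw) / bout.duration
    w_pitch = np.deg2rad(bout.d_pitch) / bout.duration
    inertia = params.mass * params.com_radius ** 2
    return 0.5 * params.mass * v ** 2 + 0.5 * inertia * (w_yaw ** 2 + w_pitch ** 2)


def _percept(state: FishState, prey: np.ndarray, idx: int,
             frame_rate: float) -> EgocentricPrey:
    """Egocentric percept with instantaneous rates at frame ``idx``.

    Central difference where both neighbours exist, one-sided at the
    trajectory edges; the fish is stationary between bouts so the
    rates are taken in the current (static) frame.
    """
    lo, hi = max(idx - 1, 0), min(idx + 1, len(prey) - 1)
    az0, alt0, d0 = to_egocentric(state, prey[lo])
    az1, alt1, d1 = to_egocentric(state, prey[hi])
    az, alt, dist = to_egocentric(state, prey[idx])
    dt = (hi - lo) / frame_rate
    d_az = ((az1 - az0 + 180.0) % 360.0 - 180.0) / dt if dt > 0 else 0.0
    return EgocentricPrey(az=az, alt=float(np.clip(alt, -90, 90)), dist=dist,
                          d_az=d_az,
                          d_alt=(alt1 - alt0) / dt if dt > 0 else 0.0,
                          d_dist=(d1 - d0) / dt if dt > 0 else 0.0)


def _surrogate_noise(bout: Bout, ego: EgocentricPrey,
                     noise_law: RecursionParams, coeffs: RegressionCoeffs,
                     rng: np.random.Generator) -> Bout:
    """Graded-noise perturbation used by the synthetic replay surrogate."""
    sd_az = noise_law.sigma_az_slope * abs(ego.az) + noise_law.sigma_az_intercept
    sd_alt = noise_law.sigma_az_slope * abs(ego.alt) + noise_law.sigma_az_intercept
    sd_dist = noise_law.sigma_dist_slope * ego.dist + noise_law.sigma_dist_intercept
    yaw_ratio = coeffs.slope_vel_yaw / coeffs.slope_vel_az
    pitch_ratio = coeffs.slope_vel_pitch / coeffs.slope_vel_alt
    return Bout(bout_az=bout.bout_az + rng.normal(0.0, sd_az),
                bout_alt=bout.bout_alt + rng.normal(0.0, sd_alt),
                bout_dist=max(0.0, bout.bout_dist + rng.normal(0.0, sd_dist)),
                d_yaw=bout.d_yaw + rng.normal(0.0, sd_az * yaw_ratio),
                d_pitch=bout.d_pitch + rng.normal(0.0, sd_alt * pitch_ratio),
                duration=bout.duration, onset_time=bout.onset_time)


def run_hunt(kind, prey: np.ndarray, fish0: FishState, schedule,
             zone: StrikeZone = StrikeZone(),
             coeffs: Optional[RegressionCoeffs] = None,
             pool: Optional[BoutPool] = None,
             energy_params: EnergyParams = EnergyParams(),
             frame_rate: float = 62.5, seed: Optional[int] = 0,
             noise_law: Optional[RecursionParams] = None,
             fish_states: Optional[Sequence[FishState]] = None) -> SimResult:
    """Simulate one hunt of a controller against a prey trajectory.

    ``schedule`` is [(onset_time, duration), ...]; the trajectory must
    cover the schedule span.  The ``replay`` kind replays supplied
    ``fish_states`` (one per bout) when given; otherwise it falls back
    to the velocity-regression controller with graded noise
    (``noise_law``), the synthetic stand-in for a recorded fish.
    """
    kind = ControllerKind(kind)
    prey = np.asarray(prey, dtype=float)
    n_frames = len(prey)
    last_end = schedule[-1][0] + schedule[-1][1]
    if (n_frames - 1) / frame_rate < last_end:
        raise ValueError("trajectory does not cover the bout schedule")
    rng = np.random.default_rng(seed)
    state = fish0
    energy = 0.0
    post_coords = []
    prev_end_idx = None
    for j, (onset, sched_dur) in enumerate(schedule):
        onset_idx = min(int(round(onset * frame_rate)), n_frames - 1)
        # prey may drift into the zone while the fish is quiescent
        if prev_end_idx is not None and onset_idx > prev_end_idx:
            az, alt, dist = to_egocentric_many(
                state, prey[prev_end_idx + 1:onset_idx + 1])
            if _in_zone_mask(az, alt, dist, zone).any():
                return SimResult("strike", j, energy, tuple(post_coords),
                                 kind.value, seed)
        ego = _percept(state, prey, onset_idx, frame_rate)
        next_gap = (schedule[j + 1][0] - onset) if j + 1 < len(schedule) else np.inf
        if kind is ControllerKind.REPLAY and fish_states is not None:
            if j >= len(fish_states):
                break
            bout = None
            state = fish_states[j]
            exec_dur = sched_dur
        else:
            if kind is ControllerKind.REPLAY:
                if coeffs is None or noise_law is None:
                    raise ValueError("synthetic replay needs coeffs and noise_law")
                bout = regression_bout(ego, coeffs, sched_dur, onset)
                bout = _surrogate_noise(bout, ego, noise_law, coeffs, rng)
            else:
                bout = choose_bout(kind, ego, pool=pool, coeffs=coeffs,
                                   zone=zone, rng=rng, duration=sched_dur,
                                   min_duration=sched_dur, max_end_gap=next_gap,
                                   onset_time=onset)
            state = apply_bout(state, bout)
            energy += bout_energy(bout, energy_params)
            exec_dur = bout.duration
        end_idx = min(int(round((onset + exec_dur) * frame_rate)), n_frames - 1)
        post = to_egocentric(state, prey[end_idx])
        post_coords.append(post)
        log.debug("bout %d (%s): post az=%.1f alt=%.1f dist=%.2f",
                  j + 1, kind.value, *post)
        if in_strike_zone(post, zone):
            return SimResult("strike", j + 1, energy, tuple(post_coords),
                             kind.value, seed)
        prev_end_idx = end_idx
    return SimResult("exhausted", len(post_coords), energy,
                     tuple(post_coords), kind.value, seed)


def run_cohort(kinds, n_trajectories: int = 225, seed: int = 0,
               prey_params: PreyMotionParams = PreyMotionParams(),
               encounter_params: EncounterParams = EncounterParams(),
               schedule_params: BoutScheduleParams = BoutScheduleParams(),
               zone: StrikeZone = StrikeZone(),
               coeffs: RegressionCoeffs = RegressionCoeffs(),
               pool: Optional[BoutPool] = None,
               energy_params: EnergyParams = EnergyParams(),
               noise_law: RecursionParams = RecursionParams()):
    """Run several controllers on a shared synthetic cohort.

    Every controller sees identical prey trajectories, encounters and
    bout schedules (child seeds spawned from ``seed``), making the
    per-model comparison paired.

    Returns
    -------
    metrics : DataFrame
        one row per (model, hunt): outcome, n_bouts, energy.
    post_coords : dict
        per model, an (n, 3) array pooling post-bout (az, alt, dist)
        samples across the cohort.
    """
    kinds = [ControllerKind(k) for k in kinds]
    needs_pool = any(k in (ControllerKind.RANDOM_CHOICE,
                           ControllerKind.IDEAL_POSITION,
                           ControllerKind.IDEAL_VELOCITY) for k in kinds)
    root = np.random.SeedSequence(seed)
    pool_ss, *hunt_ss = root.spawn(n_trajectories + 1)
    if pool is None and needs_pool:
        pool = gen_bout_pool(coeffs, noise_law,
                             seed=int(pool_ss.generate_state(1)[0] % 2**31))
    rows = []
    post = {k.value: [] for k in kinds}
    for i, ss in enumerate(hunt_ss):
        s_traj, s_enc, s_sched, s_ctrl = (
            int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4))
        schedule = gen_bout_schedule(schedule_params, seed=s_sched)
        span = schedule[-1][0] + schedule[-1][1] + 1.0
        traj = gen_prey_trajectory(prey_params, span, seed=s_traj)
        fish0, prey0 = gen_encounter(encounter_params, prey_params.tank_edge,
                                     seed=s_enc)
        # splice the encounter's prey position onto the trajectory shape
        traj = traj - traj[0] + prey0
        half = prey_params.tank_edge / 2.0
        traj = np.clip(traj, -half, half)
        for kind in kinds:
            res = run_hunt(kind, traj, fish0, schedule, zone=zone,
                           coeffs=coeffs, pool=pool,
                           energy_params=energy_params,
                           frame_rate=prey_params.frame_rate, seed=s_ctrl,
                           noise_law=noise_law)
            rows.append({"model": kind.value, "hunt": i,
                         "outcome": res.outcome, "n_bouts": res.n_bouts,
                         "energy": res.energy})
            post[kind.value].extend(res.post_bout_coords)
    metrics = pd.DataFrame(rows)
    post_coords = {k: np.array(v).reshape(-1, 3) for k, v in post.items()}
    return metrics, post_coords
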