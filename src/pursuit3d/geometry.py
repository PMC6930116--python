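"""Egocentric spherical coordinates and discrete bout kinematics.

Larval zebrafish perceive prey in a spherical frame originating at the
mouth: azimuth (positive to the fish's right), altitude (positive above
the body axis) and radial distance.  The fish moves in discrete bouts
that displace it along an egocentric axis of motion and independently
rotate its yaw and pitch.  This module provides the transforms between
the world frame and the fish's frame, finite-difference egocentric
velocity estimation, and the application of a bout to a fish state.

Conventions
-----------
World frame is right-handed, +z up, millimetre units.  At yaw = 0,
pitch = 0 the fish faces world +x with up = +z.  Positive yaw turns the
heading toward the fish's *right* (consistent with the azimuth sign),
positive pitch tilts it upward.  Roll is assumed zero throughout: the
frame is fully determined by position, yaw and pitch.  Angles are stored
in degrees; radians appear only inside trigonometric calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FishState",
    "EgocentricPrey",
    "Bout",
    "wrap_angle",
    "fish_frame",
    "to_egocentric",
    "from_egocentric",
    "egocentric_rates",
    "apply_bout",
]

#: acquisition interval of the behavioural recordings, s
DEFAULT_DT = 1.0 / 62.5


def wrap_angle(angle):
    """Wrap angle(s) in degrees to the half-open interval (-180, 180]."""
    wrapped = -((-np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0)
    return wrapped if np.ndim(angle) else float(wrapped)


@dataclass(frozen=True)
class FishState:
    """Fish pose: 3D position (mm, world frame) plus yaw and pitch (degrees)."""

    position: np.ndarray
    yaw: float = 0.0
    pitch: float = 0.0

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        if not -90.0 <= self.pitch <= 90.0:
            raise ValueError(f"pitch {self.pitch} outside [-90, 90]")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "yaw", wrap_angle(self.yaw))
        object.__setattr__(self, "pitch", float(self.pitch))


@dataclass(frozen=True)
class EgocentricPrey:
    """Prey location and motion in the fish's spherical frame.

    az/alt in degrees (az positive right, alt positive above), dist in
    mm; d_az/d_alt in deg/s and d_dist in mm/s are the egocentric rates
    at the moment of percept.
    """

    az: float
    alt: float
    dist: float
    d_az: float = 0.0
    d_alt: float = 0.0
    d_dist: float = 0.0

    def __post_init__(self):
        if self.dist < 0:
            raise ValueError("dist must be >= 0")
        if not -90.0 <= self.alt <= 90.0:
            raise ValueError(f"alt {self.alt} outside [-90, 90]")
        object.__setattr__(self, "az", wrap_angle(self.az))


@dataclass(frozen=True)
class Bout:
    """One discrete swim movement.

    The displacement axis is given by (bout_az, bout_alt) in the
    PRE-bout fish frame with magnitude bout_dist (mm); d_yaw and d_pitch
    are the independent rotations (degrees, d_yaw positive rightward).
    """

    bout_az: float = 0.0
    bout_alt: float = 0.0
    bout_dist: float = 0.0
    d_yaw: float = 0.0
    d_pitch: float = 0.0
    duration: float = 0.176
    onset_time: float = 0.0

    def __post_init__(self):
        if self.bout_dist < 0:
            raise ValueError("bout_dist must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


def fish_frame(state: FishState):
    """Orthonormal (forward, right, up) unit vectors of the fish's frame.

    Zero roll: ``right`` stays horizontal; ``up = right x forward``.
    """
    yaw = np.deg2rad(state.yaw)
    pitch = np.deg2rad(state.pitch)
    heading = np.array([np.cos(yaw), -np.sin(yaw), 0.0])
    forward = np.cos(pitch) * heading + np.sin(pitch) * np.array([0.0, 0.0, 1.0])
    right = np.array([-np.sin(yaw), -np.cos(yaw), 0.0])
    up = np.cross(right, forward)
    return forward, right, up


def to_egocentric(state: FishState, prey_world, *, degenerate_tol: float = 1e-12):
    """Map a world-frame point (mm) to egocentric (az, alt, dist).

    Distance is the magnitude of the vector from the fish's mouth to the
    prey; azimuth is positive when the prey is to the fish's right,
    altitude positive above the (pitched) body axis.  A prey coincident
    with the mouth has undefined angles: (0, 0, 0) is returned with a
    warning.
    """
    v = np.asarray(prey_world, dtype=float) - state.position
    dist = float(np.linalg.norm(v))
    if dist <= degenerate_tol:
        warnings.warn("prey coincident with fish mouth; az/alt undefined",
                      RuntimeWarning, stacklevel=2)
        return 0.0, 0.0, 0.0
    forward, right, up = fish_frame(state)
    f, r, u = v @ forward, v @ right, v @ up
    az = np.rad2deg(np.arctan2(r, f))
    alt = np.rad2deg(np.arcsin(np.clip(u / dist, -1.0, 1.0)))
    return float(az), float(alt), dist


def to_egocentric_many(state: FishState, points: np.ndarray):
    """Vectorised :func:`to_egocentric` for an (n, 3) array of points.

    Degenerate points (coincident with the mouth) map to (0, 0, 0)
    silently; intended for bulk strike-zone tests along a trajectory.
    """
    v = np.asarray(points, dtype=float) - state.position
    dist = np.linalg.norm(v, axis=1)
    forward, right, up = fish_frame(state)
    with np.errstate(invalid="ignore", divide="ignore"):
        az = np.rad2deg(np.arctan2(v @ right, v @ forward))
        alt = np.rad2deg(np.arcsin(np.clip((v @ up) / np.where(dist > 0, dist, 1.0),
                                           -1.0, 1.0)))
    zero = dist <= 1e-12
    az[zero] = 0.0
    alt[zero] = 0.0
    return az, alt, dist


def _direction(az_deg: float, alt_deg: float, forward, right, up):
    az = np.deg2rad(az_deg)
    alt = np.deg2rad(alt_deg)
    return (np.cos(alt) * (np.cos(az) * forward + np.sin(az) * right)
            + np.sin(alt) * up)


def from_egocentric(state: FishState, az: float, alt: float, dist: float):
    """Inverse of :func:`to_egocentric`: world point at (az, alt, dist)."""
    forward, right, up = fish_frame(state)
    return state.position + dist * _direction(az, alt, forward, right, up)


def egocentric_rates(states, prey, dt: float = DEFAULT_DT):
    """Finite-difference rates of the egocentric prey coordinates.

    Parameters
    ----------
    states : FishState or sequence of FishState
        A single state (static fish) or one state per sample.
    prey : (n, 3) array
        Prey world positions at a fixed sampling interval ``dt``.

    Returns
    -------
    (d_az, d_alt, d_dist) : arrays, deg/s and mm/s
        Central differences in the interior, one-sided at the edges.
        Azimuth is unwrapped before differencing so a crossing of the
        +/-180 deg seam does not produce spurious rates.
    """
    prey = np.asarray(prey, dtype=float)
    if prey.ndim != 2 or prey.shape[0] < 2:
        raise ValueError("need at least 2 prey samples")
    if isinstance(states, FishState):
        states = [states] * prey.shape[0]
    if len(states) != prey.shape[0]:
        raise ValueError("states and prey lengths differ")
    coords = np.array([to_egocentric(s, p) for s, p in zip(states, prey)])
    az = np.unwrap(coords[:, 0], period=360.0)
    d_az = np.gradient(az, dt)
    d_alt = np.gradient(coords[:, 1], dt)
    d_dist = np.gradient(coords[:, 2], dt)
    return d_az, d_alt, d_dist


def apply_bout(state: FishState, bout: Bout) -> FishState:
    """Advance a fish state by one bout.

    The displacement is ``bout_dist`` along the spherical direction
    (bout_az, bout_alt) expressed in the PRE-bout frame; yaw and pitch
    then change by d_yaw / d_pitch (pitch clamped to [-90, 90]).  The
    rotation never alters the displacement.
    """
    forward, right, up = fish_frame(state)
    new_pos = state.position + bout.bout_dist * _direction(
        bout.bout_az, bout.bout_alt, forward, right, up)
    return FishState(position=new_pos,
                     yaw=wrap_angle(state.yaw + bout.d_yaw),
                     pitch=float(np.clip(state.pitch + bout.d_pitch, -90.0, 90.0)))
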