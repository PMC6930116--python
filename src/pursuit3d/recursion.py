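"""Recursive pursuit algorithms: deterministic and graded-variance stochastic.

Abstracted away from explicit fish movement, pursuit reduces to a
recursion on the egocentric prey coordinate: each bout multiplies the
pre-bout coordinate by a fixed slope (plus intercept) until the
coordinate enters the strike-zone window.  The measured transforms are

    az'   = 0.53 * az
    alt'  = 0.54 * alt + 8.34 deg
    dist' = 0.84 * dist - 0.0125 mm   (clamped at 0)

The altitude recursion converges to its fixed point intercept/(1-slope)
= 18.1 deg, which coincides with the mean strike altitude.  The
stochastic variant draws each post-bout coordinate from a Gaussian
centred on the deterministic transform whose standard deviation grows
linearly with the pre-bout coordinate ("graded variance"):

    sigma_az   = 0.36  * |az|   + 7.62 deg
    sigma_dist = 0.137 * dist   + 0.034 mm

Monte-Carlo experiments here compare bout counts of the two variants
over grids of start values, and embed a fitted conditional mixture
model (module :mod:`pursuit3d.mixture`) in the same recursion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "RecursionParams",
    "RecursionResult",
    "det_step",
    "det_step_1d",
    "fixed_point",
    "det_recursion",
    "det_recursion_1d",
    "gv_step",
    "gv_recursion_1d",
    "gv_experiment",
    "mixture_recursion",
    "speed_gain",
]


@dataclass(frozen=True)
class RecursionParams:
    """Slopes, intercepts, noise laws and termination windows.

    Slopes lie in (0, 1) so each transform is a contraction.  The
    termination window covers azimuth and distance; altitude converges
    to its fixed point and is tracked but does not gate termination
    (the printed windows cover only azimuth and distance).
    """

    az_slope: float = 0.53
    alt_slope: float = 0.54
    alt_intercept: float = 8.34        # deg
    dist_slope: float = 0.84
    dist_intercept: float = -0.0125    # mm
    sigma_az_slope: float = 0.36
    sigma_az_intercept: float = 7.62   # deg
    sigma_dist_slope: float = 0.137
    sigma_dist_intercept: float = 0.034  # mm
    az_window: tuple = (-10.0, 10.0)   # deg
    dist_window: tuple = (0.1, 1.0)    # mm
    max_iter: int = 100
    #: if True, undershooting the lower distance edge counts as terminal;
    #: by default the recursion continues (window is two-sided).
    overshoot_terminates: bool = False

    def __post_init__(self):
        for name in ("az_slope", "alt_slope", "dist_slope"):
            s = getattr(self, name)
            if not 0.0 < s < 1.0:
                raise ValueError(f"{name}={s} outside (0, 1): not a contraction")
        if self.sigma_az_intercept <= 0 or self.sigma_dist_intercept <= 0:
            raise ValueError("sigma intercepts must be > 0")
        if not (self.az_window[0] < self.az_window[1]
                and self.dist_window[0] < self.dist_window[1]):
            raise ValueError("termination windows must be ordered")


@dataclass(frozen=True)
class RecursionResult:
    n_bouts: int
    path: np.ndarray            # iterates including the start
    terminated: bool


def fixed_point(slope: float, intercept: float) -> float:
    """Fixed point of x -> slope*x + intercept (slope != 1)."""
    if slope == 1.0:
        raise ValueError("slope = 1 has no fixed point")
    return intercept / (1.0 - slope)


def det_step_1d(value: float, slope: float, intercept: float = 0.0,
                clamp: bool = False) -> float:
    out = slope * value + intercept
    return max(0.0, out) if clamp else out


def det_step(coord, p: RecursionParams = RecursionParams()):
    """One deterministic transform of (az, alt, dist)."""
    az, alt, dist = coord
    if dist < 0:
        raise ValueError("dist must be >= 0")
    return (det_step_1d(az, p.az_slope),
            det_step_1d(alt, p.alt_slope, p.alt_intercept),
            det_step_1d(dist, p.dist_slope, p.dist_intercept, clamp=True))


def _in_window(value: float, window) -> bool:
    return window[0] <= value <= window[1]


def _az_dist_done(az: float, dist: float, p: RecursionParams) -> bool:
    if _in_window(az, p.az_window) and _in_window(dist, p.dist_window):
        return True
    return p.overshoot_terminates and dist < p.dist_window[0] and \
        _in_window(az, p.az_window)


def det_recursion(start, p: RecursionParams = RecursionParams()) -> RecursionResult:
    """Iterate the joint deterministic transform until the strike window.

    Termination gates on azimuth AND distance; altitude is carried
    along (it converges to ~18.1 deg) but is non-gating.
    """
    coord = tuple(float(c) for c in start)
    path = [coord]
    for n in range(p.max_iter):
        if _az_dist_done(coord[0], coord[2], p):
            return RecursionResult(n, np.array(path), True)
        coord = det_step(coord, p)
        path.append(coord)
    done = _az_dist_done(coord[0], coord[2], p)
    return RecursionResult(p.max_iter, np.array(path), done)


def det_recursion_1d(start: float, slope: float, intercept: float, window,
                     max_iter: int = 100, clamp: bool = False) -> RecursionResult:
    """1-D deterministic recursion (azimuth-only or distance-only)."""
    value = float(start)
    path = [value]
    for n in range(max_iter):
        if _in_window(value, window):
            return RecursionResult(n, np.array(path), True)
        value = det_step_1d(value, slope, intercept, clamp)
        path.append(value)
    return RecursionResult(max_iter, np.array(path), _in_window(value, window))


def gv_step(value: float, slope: float, intercept: float,
            sigma_slope: float, sigma_intercept: float,
            rng: np.random.Generator, clamp: bool = False) -> float:
    """One graded-variance transform.

    Draw from Normal(slope*value + intercept, sigma_slope*|value| +
    sigma_intercept).  |value| keeps the sd positive after azimuth sign
    flips; distances are clamped at >= 0 when ``clamp`` is set.
    """
    sd = sigma_slope * abs(value) + sigma_intercept
    out = rng.normal(slope * value + intercept, sd)
    return max(0.0, out) if clamp else out


def gv_recursion_1d(start: float, slope: float, intercept: float,
                    sigma_slope: float, sigma_intercept: float, window,
                    rng: np.random.Generator, max_iter: int = 100,
                    clamp: bool = False) -> RecursionResult:
    value = float(start)
    path = [value]
    for n in range(max_iter):
        if _in_window(value, window):
            return RecursionResult(n, np.array(path), True)
        value = gv_step(value, slope, intercept, sigma_slope, sigma_intercept,
                        rng, clamp)
        path.append(value)
    return RecursionResult(max_iter, np.array(path), _in_window(value, window))


def _gv_counts(start: float, reps: int, slope: float, intercept: float,
               sigma_slope: float, sigma_intercept: float, window,
               rng: np.random.Generator, max_iter: int, clamp: bool):
    """Bout counts of `reps` independent 1-D graded-variance runs (vectorised)."""
    values = np.full(reps, float(start))
    counts = np.zeros(reps, dtype=int)
    active = ~((values >= window[0]) & (values <= window[1]))
    for _ in range(max_iter):
        if not active.any():
            break
        n_act = int(active.sum())
        sd = sigma_slope * np.abs(values[active]) + sigma_intercept
        new = rng.normal(slope * values[active] + intercept, sd)
        if clamp:
            new = np.maximum(new, 0.0)
        values[active] = new
        counts[active] += 1
        done = (new >= window[0]) & (new <= window[1])
        idx = np.flatnonzero(active)
        active[idx[done]] = False
        assert n_act >= int(active.sum())
    return counts, active  # active still True => hit max_iter

def default_dist_grid() -> np.ndarray:
    """Start distances 0.1 to 10 mm in 0.1 mm steps."""
    return np.round(np.arange(1, 101) * 0.1, 10)


def default_az_grid() -> np.ndarray:
    """Start azimuths 10 to 200 deg in 2 deg steps."""
    return np.arange(10.0, 201.0, 2.0)


def gv_experiment(p: RecursionParams = RecursionParams(),
                  dist_grid=None, az_grid=None, reps: int = 500,
                  seed: int = 0):
    """Paired deterministic vs graded-variance benchmark on 1-D grids.

    For every start value the deterministic recursion runs once and the
    stochastic recursion ``reps`` times; the per-start median stochastic
    bout count is compared to the deterministic count.  Child RNG
    streams are spawned per start value so any execution order yields
    identical results.

    Returns
    -------
    table : DataFrame
        columns: variable ('az'|'dist'), start, det_bouts, stoch_median,
        stoch_mean, n_max_iter (runs that never terminated, reported,
        never dropped).
    summary : dict
        per variable: fraction of starts where the stochastic median
        ties or beats the deterministic count, median paired difference,
        and a Wilcoxon signed-rank test of (stochastic median - det)
        with alternative 'less'.
    """
    if dist_grid is None:
        dist_grid = default_dist_grid()
    if az_grid is None:
        az_grid = default_az_grid()
    grids = {
        "az": (az_grid, p.az_slope, 0.0, p.sigma_az_slope,
               p.sigma_az_intercept, p.az_window, False),
        "dist": (dist_grid, p.dist_slope, p.dist_intercept,
                 p.sigma_dist_slope, p.sigma_dist_intercept,
                 p.dist_window, True),
    }
    rows = []
    ss = np.random.SeedSequence(seed)
    for var, (grid, slope, icpt, s_slope, s_icpt, window, clamp) in grids.items():
        children = ss.spawn(len(grid))
        for start, child in zip(grid, children):
            det = det_recursion_1d(start, slope, icpt, window, p.max_iter, clamp)
            rng = np.random.default_rng(child)
            counts, active = _gv_counts(start, reps, slope, icpt, s_slope,
                                        s_icpt, window, rng, p.max_iter, clamp)
            rows.append({"variable": var, "start": float(start),
                         "det_bouts": det.n_bouts,
                         "stoch_median": float(np.median(counts)),
                         "stoch_mean": float(np.mean(counts)),
                         "n_max_iter": int(active.sum())})
    table = pd.DataFrame(rows)
    summary = {}
    for var in grids:
        sub = table[table.variable == var]
        diff = sub.stoch_median.to_numpy() - sub.det_bouts.to_numpy()
        try:
            w = stats.wilcoxon(diff, alternative="less", zero_method="zsplit")
            wres = {"statistic": float(w.statistic), "pvalue": float(w.pvalue)}
        except ValueError:  # all differences zero
            wres = {"statistic": float("nan"), "pvalue": 1.0}
        summary[var] = {
            "frac_tie_or_better": float(np.mean(diff <= 0)),
            "median_diff": float(np.median(diff)),
            "wilcoxon": wres,
            "n_max_iter_total": int(sub.n_max_iter.sum()),
        }
    return table, summary


def _mean_slopes_from_samples(model, n_samples: int, rng: np.random.Generator):
    """Per-coordinate linear (post ~ pre) fits on joint model samples."""
    joint = model.sample_joint(n_samples, rng)
    d = joint.shape[1] // 2
    fits = []
    for i in range(d):
        slope, icpt = np.polyfit(joint[:, i], joint[:, d + i], 1)
        fits.append((float(slope), float(icpt)))
    return fits


def mixture_recursion(model, starts, reps: int = 200, zone=None,
                      max_iter: int = 100, overshoot_terminates: bool = False,
                      n_mean_samples: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Paired stochastic (mixture-model) vs deterministic recursion.

    The stochastic arm simulates post-bout (az, alt, dist) conditionally
    from a fitted :class:`~pursuit3d.mixture.MixtureTransform`; the
    deterministic arm uses the mean linear transform fit to
    ``n_mean_samples`` joint samples drawn from the same model, so any
    performance difference isolates the stochasticity.  Both arms share
    an identical deterministic initiation step.  Termination is by the
    strike-zone windows (azimuth and distance gate, altitude is
    tracked by the transform but non-gating).

    Returns a tidy DataFrame: one row per (start, arm, rep).
    """
    from .simulator import StrikeZone  # local import: simulator builds on us
    if zone is None:
        zone = StrikeZone()
    az_win = (zone.az_mean - zone.angular_k * zone.az_sd,
              zone.az_mean + zone.angular_k * zone.az_sd)
    dist_win = (max(zone.dist_mean - zone.dist_k * zone.dist_sd, 0.0),
                zone.dist_mean + zone.dist_k * zone.dist_sd)

    def done(coord):
        ok_dist = _in_window(coord[2], dist_win) or (
            overshoot_terminates and coord[2] < dist_win[0])
        return _in_window(coord[0], az_win) and ok_dist

    starts = np.atleast_2d(np.asarray(starts, dtype=float))
    if starts.shape[1] != 3:
        raise ValueError("starts must be (n, 3): az, alt, dist")
    root = np.random.SeedSequence(seed)
    fits = _mean_slopes_from_samples(
        model, n_mean_samples, np.random.default_rng(root.spawn(1)[0]))

    def det_arm_step(coord):
        az = fits[0][0] * coord[0] + fits[0][1]
        alt = fits[1][0] * coord[1] + fits[1][1]
        dist = max(0.0, fits[2][0] * coord[2] + fits[2][1])
        return np.array([az, alt, dist])

    rows = []
    children = root.spawn(len(starts))
    for si, (start, child) in enumerate(zip(starts, children)):
        # deterministic arm: single run
        coord = det_arm_step(start)  # shared deterministic initiation
        n = 1
        while not done(coord) and n < max_iter:
            coord = det_arm_step(coord)
            n += 1
        rows.append({"start_id": si, "arm": "deterministic", "rep": 0,
                     "n_bouts": n, "terminated": done(coord)})
        rng = np.random.default_rng(child)
        for rep in range(reps):
            coord = det_arm_step(start)  # identical initiation bout
            n = 1
            while not done(coord) and n < max_iter:
                post = model.conditional_sample(coord, 1, rng)[0]
                coord = np.array([post[0], post[1], max(0.0, post[2])])
                n += 1
            rows.append({"start_id": si, "arm": "stochastic", "rep": rep,
                         "n_bouts": n, "terminated": done(coord)})
    return pd.DataFrame(rows)


def speed_gain(bout_reduction: int = 1, hunt_lengths=(4, 7)):
    """Percent capture-speed gain from shaving bouts off a hunt.

    For hunts of ``hunt_lengths`` bouts (defaults: the quartiles of
    successful hunt length), removing ``bout_reduction`` bouts speeds
    capture by reduction/length; returned as (low%, high%) integers.
    """
    lo, hi = sorted(hunt_lengths)
    if bout_reduction >= lo and bout_reduction != 0:
        raise ValueError("hunt lengths must exceed the reduction")
    return (round(100.0 * bout_reduction / hi),
            round(100.0 * bout_reduction / lo))
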