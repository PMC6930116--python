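# pursuit3d

Simulation and modelling of 3D prey capture in larval zebrafish: the
egocentric bout kinematics of pursuit, six bout-choice controllers
competing in a virtual prey-capture environment with energy accounting,
and the deterministic versus graded-variance stochastic recursive
pursuit algorithms — all runnable on synthetic paramecium trajectories,
with no recorded data required.

## Who this is for

Computational ethologists and behavioural modellers who want a
reproducible, parameterised implementation of the zebrafish hunting
algorithm: to probe how position perception, velocity extrapolation and
motor stochasticity each contribute to capture success, or to reuse the
egocentric-coordinate and bout machinery for other pursuit systems.

## The model

A hunting fish perceives its prey in a spherical frame at its mouth —
azimuth `az` (positive right), altitude `alt` (positive above), distance
`dist` — together with the egocentric rates (δaz/δt, δalt/δt,
δdist/δt). Locomotion is discrete: each swim bout displaces the fish by
`bout_dist` along an egocentric axis (`bout_az`, `bout_alt`) and rotates
it by (Δyaw, Δpitch). Three rules generate the behaviour:

1. **Position control.** Each bout variable is a linear function of the
   pre-bout prey position, e.g. `bout_az = 1.43·az + 0.3°` and
   `bout_alt = 1.70·alt − 15.13°` (the negative offset keeps prey
   above the fish, where it strikes).
2. **Velocity modulation.** Prey rates bias every bout variable, e.g.
   `bout_az += 0.251 s · δaz/δt`. Dividing the velocity coefficients by
   the mean bout duration (0.176 s) recovers the position coefficients
   (0.251/0.176 = 1.43, 0.300/0.176 = 1.70): the fish effectively
   transforms a Euler-projected *future* prey position.
3. **Graded stochasticity.** Abstracted to prey coordinates, each bout
   applies a contraction `az' = 0.53·az`, `alt' = 0.54·alt + 8.34°`,
   `dist' = 0.84·dist − 0.0125 mm`, with Gaussian noise whose sd grows
   with the pre-bout coordinate: `σ_az = 0.36·|az| + 7.62°`,
   `σ_dist = 0.137·dist + 0.034 mm`. The altitude recursion has fixed
   point 8.34/(1 − 0.54) = 18.1°, the strike altitude.

Pursuit terminates when the prey enters the strike zone (mean 0.9° az,
17.4° alt, 0.870 mm dist). The package's virtual environment pits six
controllers — noisy replay, position-only regression, velocity
regression, random pool choice, ideal pool choice without and with
velocity projection — against shared synthetic prey, scoring strikes,
bouts to capture, and mechanical energy (translational kinetic plus
yaw/pitch rotational, 1 mg fish, 0.53 mm head-to-centre-of-mass).

## Worked example

```python
>>> from pursuit3d import fixed_point, projected_coefficient
>>> round(fixed_point(0.54, 8.34), 1)          # strike altitude, deg
18.1
>>> round(projected_coefficient(0.251), 2)     # projected azimuth coefficient
1.43

>>> from pursuit3d.recursion import gv_experiment
>>> table, summary = gv_experiment(reps=100, seed=2024)
>>> summary["dist"]["frac_tie_or_better"], summary["dist"]["median_diff"]
(1.0, -1.0)
```

On the standard start grids (distance 0.1–10 mm in 0.1 mm steps,
azimuth 10–200° in 2° steps) the graded-variance recursion's median
bout count ties or beats the deterministic recursion at every distance
start and 96% of azimuth starts, typically by one bout — noise injected
into a contraction speeds capture rather than degrading it.

Running the four-controller cohort on 200 shared synthetic hunts:

```sh
pursuit3d simulate --models random_choice,regression_position,regression_velocity,ideal_velocity \
    --n 200 --seed 0 --out results/simulate
```

prints (abridged):

```
random_choice          strikes=  4/200  mean energy=4.07e-11 J  median bouts=7
regression_position    strikes= 53/200  mean energy=1.28e-11 J  median bouts=7
regression_velocity    strikes= 57/200  mean energy=1.32e-11 J  median bouts=7
ideal_velocity         strikes=200/200  mean energy=5.45e-11 J  median bouts=2
```

Reading: random bouts almost never capture; adding position perception
rescues success; velocity perception improves on position alone at
essentially no extra energy; ideal pool choice with velocity projection
captures fastest but spends about four times the energy per hunt of the
regression strategies.

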