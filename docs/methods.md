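# Methods

This note documents the models implemented in `pursuit3d`, the
assumptions behind the synthetic-data generators, the numerical choices
that were genuinely open, and what the tests do and do not establish
about real behaviour. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate conventions

World frame: right-handed, +z up, millimetres. At yaw = pitch = 0 the
fish faces +x with up = +z. Positive yaw turns the heading toward the
fish's **right** (so a positive Δyaw and a positive prey azimuth share
a sign), positive pitch tilts it up. Roll is assumed zero throughout:
the fish frame is determined by position, yaw and pitch alone, and
altitude is body-referenced (measured from the pitched body axis), not
gravity-referenced. Angles are stored in degrees everywhere; radians
appear only inside trigonometric calls. Prey velocity entering the
controllers is the instantaneous egocentric rate at bout onset
(central finite difference at the 62.5 Hz sampling rate, one-sided at
trajectory edges); a pre-bout averaging window is deliberately not the
default since bouts are decisions taken on the current percept.

A bout displaces the fish by `bout_dist` along the spherical direction
(`bout_az`, `bout_alt`) expressed in the **pre-bout** frame, then
applies Δyaw and Δpitch (pitch clamped to ±90°); the rotation never
bends the displacement. This ordering is a contract, not physics: real
bouts rotate and translate simultaneously, but only the endpoint
matters to every consumer in this package.

## Synthetic data: what it emulates, what it does not

The generators replace recorded hunts with processes matched to the
summary structure of the behaviour. All are pure functions of
(parameters, seed).

**Prey trajectories.** A 3-D Ornstein–Uhlenbeck velocity process
(correlation time 0.5 s) with Poisson tumbles (0.2 s⁻¹) that
re-orient the velocity isotropically while preserving speed, and
reflecting walls in a 20 mm cube sampled at 62.5 Hz. A single OU
process has a Maxwell stationary speed distribution, which cannot
simultaneously produce the two observed speed-tail fractions (74% of
frames above 3 body lengths s⁻¹ and 27% above 6, at 0.2 mm body
length): fixing the first forces the second to ≈0.17. Real paramecium
populations are heterogeneous in vigour, so each trajectory draws its
own per-component speed scale from a log-normal across-individual law.
The two constants (median scale 0.578 mm s⁻¹, log-sd 0.312) were
solved once from the two tail equations by quadrature and are frozen
in the defaults; the calibration test regenerates 200 × 10 s
trajectories and checks both fractions to ±0.05. The body length
(0.2 mm) is itself an assumption, exposed in config. What the
generator does **not** emulate: gravitaxis, wall-following,
helical swimming paths, and any fish–prey interaction (prey do not
flee). Passing tests therefore show the algorithms behave as designed
on motion with the right speed structure, not that they reproduce
capture statistics on real prey.

**Encounters.** Hunt initial conditions place the fish uniformly in
the central half of the tank, level (pitch 0) with uniform random yaw,
and draw the prey's egocentric coordinates from the measured Gaussians
(azimuth 0.7 ± 48.4°, altitude 19.9 ± 19.7°, distance 3.4 ± 1.6 mm,
distance truncated above 0.2 mm, redrawn if outside the tank). The
truncation raises the expected distance to ≈3.49 mm; the
generator-consistency test checks sample means against that truncated
law, not the raw 3.4.

**Bout timing.** Durations are log-normal matched to the observed
median (0.176 s) and IQR (0.144–0.208 s): σ is set from the log-IQR,
so the fitted quartiles land at 0.146/0.212 s, inside the test
tolerance of ±0.01 s. Inter-bout gaps are 0.05 s plus an exponential
with mean 0.30 s — the inter-bout mean (0.35 s total) is **not**
measured and is flagged as an assumption. A schedule contains 7 bouts
by default: model hunts get the bout budget of an upper-quartile real
hunt (successful hunts last 5 bouts, IQR 4–7) and are scored
"exhausted" beyond it. This budget matters: with an unbounded
schedule, per-hunt energy comparisons across controllers reflect
schedule length rather than strategy.

**Bout pool.** The synthetic pursuit repertoire (default 1782 bouts)
is generated by sampling encounter-distributed percepts with Gaussian
prey rates (rate sds 36.3/31.3 ° s⁻¹ chosen so mean absolute angular
rates match the observed 29/25 ° s⁻¹; radial sd 1.0 mm s⁻¹ assumed),
applying the velocity-regression transform, and perturbing each bout
variable with the graded noise laws (yaw/pitch noise scaled by the
ratio of their regression slopes to the az/alt slopes). The altitude
noise law reuses the azimuth law's constants, since only the azimuth
law is quantified.

## Controllers

Coefficients live in config, not code. Position slopes default to the
projected coefficients (velocity slope / 0.176 s) because the direct
position-only fits are not quantified; offsets are the published
values (0.3°, 0.48°, −15.13°, −1.79°), the distance transform is
0.105·dist + 0.053·δdist/δt with zero intercept. Initiation bouts use
the pursuit coefficients (a separate initiation set is a config hook);
this is a known limitation since initiation transforms differ from
pursuit in reality.

Pool-choice controllers pre-filter candidates by duration — no shorter
than the scheduled bout, not extending past the next onset — applied
to random choice as well as ideal choice; an emptied filter falls back
to the unfiltered pool with a warning. Ideal scoring simulates the
candidate from a canonical origin-aligned state (scoring is entirely
egocentric, so no world state is needed), optionally Euler-projects
the prey to the candidate's end time, and sums squared zone-normalised
deviations of post-bout (az, alt, dist) from the strike-zone means.
Ties break at the lowest pool index. The vectorised pool scorer is
checked against exhaustive scalar scoring in the tests. The "replay"
controller replays recorded fish states when trajectory files provide
them; in fully synthetic runs it falls back to the velocity regression
with graded noise — a stand-in for a real fish, labelled as such.

## Virtual environment

The strike test runs at every bout end **and** every inter-bout frame,
since prey can drift into the zone while the fish is quiescent; it
does not run during a bout or before the first bout ends. Zone
windows: ±1.96 sd angular (a 95% interval), ±2 sd radial. Only the
azimuth sd (7.2°) is measured; the altitude sd (7.0°) and distance sd
(0.30 mm) are assumptions exposed in config. Energy per bout is
½m(bout_dist/T)² + ½I(ω_yaw² + ω_pitch²) with point-mass inertia
I = m·r² (m = 1 mg, r = 0.53 mm), a deliberate single-point
abstraction of the body.

Cohorts spawn child seed streams per hunt so every controller sees
identical trajectories, encounters and schedules; comparisons are
paired, and any execution order yields identical results.

## Recursive algorithms

The 1-D experiments treat azimuth and distance independently on the
standard grids (azimuth 10–200° step 2°, distance 0.1–10 mm step
0.1 mm), with termination windows ±10° and 0.1–1 mm; the acceptance
run uses 100 repetitions per start (the full protocol is 500, also
supported — the scaled-down run leaves the direction and effect size
unchanged, only the attained p-values move). Distance overshoot below
the lower window edge does **not** terminate by default (the window is
two-sided); because the transform is clamped at zero, such runs can
park near zero and exhaust `max_iter` — they are counted and reported,
never dropped, and stay below 1% of runs on the default grids. A
config switch (`overshoot_terminates`) makes undershoot terminal.

The joint (mixture-model) recursion gates termination on the
strike-zone azimuth and distance windows; altitude is transformed and
tracked but non-gating, since it converges unconditionally to its
18.1° fixed point and no altitude termination window is quantified.
Both arms share one deterministic initiation step, and the
deterministic comparator uses per-coordinate linear fits to 10,000
joint samples drawn from the same generative model, isolating the
effect of stochasticity. A known negative result, found and documented
here: with a **symmetric Gaussian** graded-noise law substituted for
the fitted generative model, the stochastic arm's median bout count
ties — does not strictly beat — the deterministic arm from
encounter-distributed starts (its mean is worse, via azimuth jitter
out of the window and distance undershoot). A strict stochastic
advantage in the joint recursion requires asymmetric or multi-modal
conditional structure of the kind a real-data mixture can carry; the
1-D graded-variance benefit, by contrast, is robust and reproduced
here.

## Conditional mixture model

The generative pre→post model is a finite Gaussian mixture over the
joint (pre, post) vector with EM fitting (scikit-learn's engine, run
one iteration at a time so the log-likelihood trace is recorded and
asserted non-decreasing), multiple seeded restarts, and BIC/AIC model
selection. Conditioning on the pre block is exact Gaussian algebra —
responsibilities re-weighted by the pre-marginal likelihood,
per-component conditional means and covariances — never rejection or
approximation; the tests cross-check it against a brute-force
rejection sampler. A finite mixture was chosen over a nonparametric
process because every property exercised downstream (heteroskedastic,
multi-modal conditional simulation) is representable by a finite
mixture with an identical conditional-simulation interface, while
keeping the fit deterministic given a seed. Resolution caveat: a
K-component tiling of a continuously graded noise law floors the
recoverable conditional sd at the within-component variation, so
noise-law recovery uses a 16-component fit on 20,000 pairs; coarser
tilings bias the recovered noise intercept upward by several percent.

## Problem sizes and runtime

Defaults chosen for the package's own test turnaround: cohorts of 200
hunts (protocol size 225 is the `--n` default in the CLI), 100
graded-variance repetitions per grid start in the acceptance run (500
supported), 10,000-draw sampling checks, 5,000-pair parameter
recovery, and 20,000-pair mixture training. The full suite runs in
well under a minute on one CPU apart from the mixture-resolution test
(~15 s) and the cohort fixture (~5 s).

## Known limitations

* Synthetic prey and encounters reproduce summary statistics, not real
  trajectories; the published percentage improvements between
  controllers (65%/14%/17%) depend on the recorded prey paths and are
  not reproduced here — only the ordering is.
* Initiation bouts share pursuit coefficients.
* Altitude noise and strike-zone altitude/distance sds are assumptions.
* The energy model is a point mass; no drag, no tail kinematics.
* Aborted hunts are out of scope: hunts strike or exhaust the schedule.
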