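# Methods

## Task and arena

The agent navigates a square, depth-constrained arena (default 4 m x
4 m, coordinates `[-2, 2]^2`; `x` horizontal, `z` vertical/depth,
headings counter-clockwise from `+x`). Circular obstacles ("corals") of
radius 0.15 m are placed uniformly at random; start and target are
sampled uniformly within randomly chosen opposite quadrants, rejection-
sampled so neither lies within a coral disk plus a 0.1 m clearance
(1000-retry cap, then a placement error). Arena walls are visible to the
ray-cast by default — boundary cells respond to any boundary, and the
agent must stay inside — exposed as a config switch. The agent is a
point; corals are not motion-blocking. Collisions are *counted* (a
trajectory sample whose distance to any coral center is below the
radius), never hard-stopped, matching the sample-counting collision
metric. All generation is seeded and bit-reproducible.

## Sensing

Egocentric distances are measured in 24 angular bins of 15 deg (bin 0
straight ahead, counter-clockwise), truncated at the 1.4 m maximal
receptive field. A coral of radius `r` at center distance `d` subtends
the aperture `2*arctan(r/d)`; a bin is affected when its center
direction falls inside the aperture, and its distance is the exact
ray–circle surface distance (ties between corals and walls resolve to
the nearest). The forward distance `d0` is bin 0's value. The target is
"visible" within `r_vis = 0.3 m`.

## Control law

Each simulation step (`dt = 1 ms`, a standard neural-simulation step):

1. **Heading command.** Strategy-dependent and fixed at trial start:
   null — uniform within +-45 deg of the true initial bearing; azimuth —
   the true initial bearing; hp — while `|P_z - G_z| >= 0.2 m` climb or
   dive at `+-pi/2` toward the target depth, inside the band swim along
   the binary horizontal prior `theta_HP in {0, pi}` (sign of the
   target's initial horizontal offset; never updated mid-trial). When
   the target is visible the command points directly at it and the
   attractor term `G = g - p` is added to the commanded velocity
   (clamped to `v_max`), producing the fast, direct final approach.
2. **Speed law.** Inside the critical distance (`d0 < D = 0.4 m`) the
   commanded speed updates as `min((s + v_eps) * d_hat, s)` with
   `d_hat = clip((d0 - eps)/(D - eps), 0, 1)`, `eps = 0.03 m`,
   `v_eps = 0.05 m/s`; otherwise it accelerates as
   `min(s + d_c * tau2, v_max)` with `d_c = 3 m/s^2`. The law acts on
   the scalar commanded speed; the per-axis formulation is exposed as
   `axis_speed_update` but the trial loop composes speed with heading
   (`v = s [cos, sin]`), because applying the acceleration branch per
   axis would push both components toward `+v_max` regardless of
   heading.
3. **Steering.** Per-bin clearances (clear bins saturate at 1.4 m,
   rear bins masked) are low-pass filtered with `tau1 = 20 ms` —
   continuously, so the filter's short memory damps left/right
   flip-flop in front of symmetric obstacles. When blocked, a
   winner-take-all (deterministic argmax, lowest index on ties; the
   functional stand-in for a basal-ganglia/thalamus selection circuit)
   picks the clearest frontal bin, mapped to the signed angle clipped
   to `[-pi/2, pi/2]`, and the steering angle blends
   `theta_steer = 0.9 * theta_new + 0.1 * theta_old`. When the path is
   clear the steering angle relaxes to zero with time constant `tau2`
   rather than per-step: the blend constants are per-control-update
   quantities, and an instantaneous snap-back makes the agent re-face
   the obstacle it just avoided (a stalling limit cycle we observed at
   per-step relaxation).
4. **Error-based update.** Commanded velocity (strategy heading +
   steering rotation + attractor) is tracked by the actual velocity and
   heading through first-order `tau2 = 100 ms` dynamics, heading error
   wrapped to the shortest arc. Position integrates the actual
   velocity; speed is clamped to `v_max = 0.5 m/s`. The trial ends at
   target capture (`|p - g| < 0.05 m`) or `t_max = 45 s`.

## Noise

Noise (sigma in {0, 0.1, 0.3}, meters) perturbs the *sensed* positional
state — the effective input to the boundary and pressure populations —
not the physical position. The sensed error follows an
Ornstein–Uhlenbeck process with the `tau1` synaptic time constant and
stationary std sigma, because the positional estimate reaches the
sensory populations through synaptic filtering and therefore cannot
flicker at the integration step. Two rejected alternatives and why:
noise on the physical position makes the per-millisecond summed path
length pure random-walk arc (distance normalization saturates), and
white per-step sensed jitter lets the agent drive through corals it
mis-localizes for a single step. Moderate noise (sigma = 0.1) breaks
the symmetric-obstacle traps of the fully deterministic controller and
*raises* success rates; strategy-comparison experiments therefore run
at sigma = 0.1 by default, which also plays the role that intrinsic
spiking variability plays at full scale. Limitation: at sigma = 0.3
(sensed error twice the coral radius) this rate-mode model degrades
more than the published spiking model, which apparently tolerates the
highest noise level better.

## Neural substrate

A minimal population-coding (NEF-style) layer: ensembles of LIF
(membrane tau 20 ms, refractory 2 ms — conventional defaults) or
spiking rectified-linear neurons with unit-norm encoders; gain/bias
solved from (max rate, intercept) so each neuron is silent at its
intercept and fires at its max rate at full encoder alignment.
Functions of represented variables use regularized least-squares
decoders (ridge `0.1 * max activity`, 500 evaluation points), fixed
before simulation. The recurrent integrator uses identity feedback with
the input scaled by the discrete-exact factor `dt / (1 - exp(-dt/tau2))`
so that rate mode reduces exactly to `p <- p + v dt`. Rate mode
evaluates static tuning curves (deterministic oracle); spiking mode
integrates threshold dynamics and decodes synaptically filtered spike
trains. In a spiking trial the commanded velocity passes through a
1500-neuron LIF population at the observed 0.1–4 spikes/s rates
(encode → spike → `tau2`-filtered decode) before the error-based
tracking, so executed kinematics inherit spiking variability; agreement
with rate mode is ~6–8% RMS of `v_max` after a 0.5 s spin-up.

## Tuning parameters

Peak rates and receptive-field sizes are drawn from skew-normal
distributions clipped to the observed ranges (rates 0.1–4 spikes/s,
fields (0, 1.4] m). The published fit parameters are not tabulated, so
the defaults (rate: location 0.5, scale 1.2, shape 4; field: location
0.25, scale 0.45, shape 3) are configuration chosen to reproduce the
published low-rate, right-skewed summaries; tests assert only clip
bounds and shape properties. Population budget: 17.85% of the 10,000
total are BVCs (the recorded 35/196 proportion → 1785), kinematic
populations ~1500 each; the HP count is not reported and defaults to
1500, with the remainder in the position/step-size ensembles. Variants:
`hp_max` = LIF everywhere, rate cap 400 spikes/s, 10x population
(worst-case spiking-event load 1000x the tuned model's — the
neuromorphic energy proxy); `hp_default` = same counts with generic
simulator defaults (standard-normal-style intercepts, uniform 200–400
spikes/s rates).

## A* baseline

Occupancy grid at 0.05 m resolution (a cell is occupied iff its center
lies in a known coral disk; no inflation — the agent is a point).
Optimal 8-connected search under octile costs with the Euclidean
heuristic; deterministic tie-breaks (lower heuristic, then lower
row-major index). Global mode plans once on the full map; local mode
accretes corals entering the 1.4 m sensing radius and replans at 20 Hz,
pausing one control tick whenever its map changes (replanning latency)
— the mechanism separating its normalized time from its normalized
distance. Both agents traverse lattice segments between cell centers
(entry/exit jogs through the start/goal cell centers), and the distance
metric uses the exactly accounted traveled arc length. Observed
consequence of planner optimality: the local agent's realized path
length equals the global optimum in every tested environment, so the
local-vs-global difference lives almost entirely in time.

## Metrics and statistics

Per-trial: reached flag; normalized time `(t - t_min)/(t_max - t_min)`
with `t_min` the straight-line time at `v_max`; normalized distance
`(L - L_straight)/(v_max t_max - L_straight)`; collision rate = fraction
of samples inside a coral disk; total score = reached-gated mean of the
three complements (failures fold to 0). Trajectory repeatability:
pairwise dynamic time warping (Euclidean local cost, full DP, no
warping window) on linearly resampled routes (200 samples by default —
full-resolution 45,000-sample DP is quadratic and adds nothing at this
scale); 10 repeats give 45 pairs. Statistics: bootstrap success SE
(100 resamples), Welch two-sided t-tests (unequal variances across
strategies), Cohen's d with pooled within-group variance on
environment-paired data, one-way ANOVA partial eta^2 via the
sum-of-squares decomposition, percentile bootstrap CIs (10,000
resamples), Holm–Bonferroni via statsmodels.

## Problem sizes

Experiments run at desk scale by design: strategy comparisons use 20
seeded environments x 1 repeat in rate mode (1/5 kinematic population
scale for the spiking path), the similarity analysis 1 environment x 10
repeats, the arena-size sweep 5 environments per size with coral count
scaled by area (constant density) and duration scaled by side length.
Full-scale plans (50 environments, spiking mode) are expressible
through the same `ExperimentPlan`/CLI surface but are slow and not part
of the default runs.

## Known limitations

Sensory transduction (retina/tectum, lateral line, swim bladder) is
black-boxed, as in the modeled system. The basal-ganglia/thalamus
circuit is reduced to a functional winner-take-all with a documented
hook for a full circuit. Rate mode at sigma = 0 exhibits deterministic
trapping (the model's own noise-benefit result, not a bug); sigma = 0.3
under-performs relative to the published spiking model. The synthetic
arenas have uniform coral density and static obstacles only; nothing
here speaks to moving obstacles, currents, or 3-D volumetric arenas.
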