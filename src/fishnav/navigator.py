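"""The navigating agent: sensing, control law, and trial simulation.

One control/physics step (default 1 ms) proceeds as:

1. *Visual scene*: egocentric distances to the nearest boundary surface
   (coral perimeters and arena walls) in 24 angular bins of 15 deg,
   truncated at the 1.4 m sensory range; plus a target-visibility flag
   (true within r_vis = 0.3 m).
2. *Strategy heading*: a fixed directional command -- random within
   +-45 deg of the true bearing (null), the true initial bearing
   (azimuth), or the hydrostatic-pressure program (climb/dive at +-pi/2
   until the agent's depth is within 0.2 m of the target depth, then swim
   along the fixed binary horizontal prior theta_HP in {0, pi}). The
   prior never updates mid-trial. When the target becomes visible the
   heading command points straight at it (the goal attractor's "fast and
   direct movement").
3. *Speed law*: the forward distance d0 modulates speed -- multiplicative
   slow-down by the relative distance (d0 - eps)/(D - eps) inside the
   critical distance D = 0.4 m, acceleration back to v_max outside it.
4. *Steering*: when the forward path is blocked (d0 < D) a winner-take-all
   over the low-pass-filtered per-bin clearances (restricted to the
   frontal +-90 deg) picks the clearest direction; the steering angle
   blends 90% of that command with 10% of the previous one and rotates
   the commanded velocity. The steering angle relaxes back to zero when
   the path clears, so the allocentric strategy heading is restored.
5. *Error-based update*: actual velocity and heading track their
   potential values through first-order tau2 = 100 ms dynamics (heading
   error wrapped to the shortest arc); position integrates velocity.

Gaussian noise of scale sigma (meters, stationary std) perturbs the
*sensed* positional state -- the effective input to the boundary and
pressure populations -- not the physical position, so it randomizes
sensing and steering without inflating the traveled path. The error is
an Ornstein-Uhlenbeck process with the tau1 synaptic time constant
(the positional estimate reaches the sensory populations through
synaptic filtering, so its error wanders smoothly). Moderate noise
breaks the symmetric obstacle traps the deterministic controller can
fall into.

In spiking mode the commanded velocity additionally passes through a
spiking LIF population (encode -> spike -> filtered decode), so the
executed kinematics inherit spiking variability; rate mode is the
deterministic oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import metrics_stats as ms
from .arena import Environment, wrap_angle
from .ephys_tuning import NeuronModelSpec, sample_bvc_tuning
from .nef_substrate import Ensemble, SpikingChannel, lowpass_step

__all__ = [
    "ControlParams",
    "AgentState",
    "VisualScene",
    "HPBias",
    "SimulationDiverged",
    "compose_velocity",
    "visual_scene",
    "bvc_drive",
    "attractor_term",
    "relative_distance",
    "axis_speed_update",
    "fold_potential",
    "steer",
    "rotate",
    "hp_bias",
    "error_update",
    "run_trial",
]


def save_trial(
    traj: "ms.Trajectory",
    result: "ms.TrialResult",
    path,
    env_path: str | None = None,
) -> None:
    """Write a trajectory CSV (t, x, z, collision_flag) with a JSON
    metadata sidecar (strategy, seed, metrics, optional environment file
    reference) next to it."""
    import json
    from pathlib import Path

    path = Path(path)
    traj.to_frame().to_csv(path, index=False)
    meta = {
        "reached": result.reached,
        "time_norm": result.time_norm,
        "dist_norm": result.dist_norm,
        "collision_rate": result.collision_rate,
        "total_score": result.total_score,
        "env_path": env_path,
        **result.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1, default=float))


class SimulationDiverged(RuntimeError):
    """Raised when the agent state becomes non-finite; carries the
    trajectory logged so far in ``.trajectory``."""

    def __init__(self, msg: str, trajectory=None):
        super().__init__(msg)
        self.trajectory = trajectory


@dataclass(frozen=True)
class ControlParams:
    """All control constants of the navigation model (SI units)."""

    tau1: float = 0.02  # synaptic time constant, kinematic conjugation [s]
    tau2: float = 0.1  # synaptic time constant, integration/tracking [s]
    v_max: float = 0.5  # maximal speed [m/s]
    eps: float = 0.03  # minimum safety distance [m]
    D: float = 0.4  # critical slow-down distance [m]
    d_c: float = 3.0  # deceleration (here: acceleration) coefficient [m/s^2]
    alpha: float = 0.9  # steering blend: weight of the new command
    r_vis: float = 0.3  # target visibility radius [m]
    depth_threshold: float = 0.2  # HP depth band [m]
    n_bvc_bins: int = 24  # angular bins (360 deg / 15 deg)
    bvc_range: float = 1.4  # maximal BVC receptive field [m]
    t_max: float = 45.0  # simulation cap [s]
    v_eps: float = 0.05  # small speed boost in the slow-down law [m/s]
    noise_sigma: float = 0.0  # sensed-position noise scale [m]
    dt: float = 0.001  # simulation step [s]
    capture_radius: float = 0.05  # target capture distance [m]

    def __post_init__(self) -> None:
        if not 0 < self.eps < self.D:
            raise ValueError("need 0 < eps < D")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.v_max <= 0 or self.dt <= 0:
            raise ValueError("v_max and dt must be positive")


@dataclass
class AgentState:
    """Kinematic state at time t."""

    p: np.ndarray  # position (x, z) [m]
    v: np.ndarray  # velocity [m/s]
    theta: float  # heading [rad], CCW from +x
    s: float  # speed [m/s]
    t: float = 0.0


@dataclass
class VisualScene:
    """Egocentric sensory snapshot: per-bin boundary distances (inf where
    clear), forward distance d0, and target visibility."""

    d: np.ndarray  # (n_bins,), bin 0 straight ahead
    target_visible: bool
    target_vector: np.ndarray

    @property
    def d0(self) -> float:
        return float(self.d[0])


@dataclass(frozen=True)
class HPBias:
    """Hydrostatic-pressure program: a fixed binary horizontal prior
    (theta_HP in {0, pi}: target initially to the right/left) plus the
    target depth. The prior is set once at trial start and never updated."""

    theta_hp: float  # 0.0 or pi
    target_depth: float

    def __post_init__(self) -> None:
        if self.theta_hp not in (0.0, math.pi):
            raise ValueError("theta_hp must be 0 or pi")


# ----------------------------------------------------------------------
# Elementary control operations


def compose_velocity(s: float, theta: float) -> np.ndarray:
    """Velocity vector (s*cos(theta), s*sin(theta)) from speed and heading."""
    if s < 0:
        raise ValueError("speed must be >= 0")
    return np.array([s * math.cos(theta), s * math.sin(theta)])


def attractor_term(p: np.ndarray, g: np.ndarray, r_vis: float = 0.3) -> np.ndarray:
    """Goal attractor G = g - p when the target is within the visibility
    radius, else zero."""
    p = np.asarray(p, dtype=float)
    g = np.asarray(g, dtype=float)
    delta = g - p
    if float(np.linalg.norm(delta)) < r_vis:
        return delta
    return np.zeros(2)


def relative_distance(d: float, eps: float = 0.03, D: float = 0.4) -> float:
    """Relative distance (d - eps)/(D - eps), clipped to [0, 1]."""
    if not eps < D:
        raise ValueError("need eps < D")
    return float(np.clip((d - eps) / (D - eps), 0.0, 1.0))


def axis_speed_update(v_a: float, d: float, params: ControlParams) -> float:
    """Per-axis speed update from the forward distance d.

    Inside the critical distance D the magnitude is scaled down by the
    relative distance (with a small v_eps boost so it can recover);
    outside, the component accelerates by d_c * tau2 up to v_max.
    """
    if d < params.D:
        dhat = relative_distance(d, params.eps, params.D)
        new_mag = min((abs(v_a) + params.v_eps) * dhat, abs(v_a))
        return math.copysign(new_mag, v_a) if v_a != 0 else 0.0
    return min(v_a + params.d_c * params.tau2, params.v_max)


def fold_potential(v_a_new: float, v_max: float = 0.5) -> float:
    """Fold a speed component into [0, v_max], preserving its sign."""
    return math.copysign(min(max(abs(v_a_new), 0.0), v_max), v_a_new)


def steer(theta_new: float, theta_old: float, alpha: float = 0.9) -> float:
    """Blend the winner-take-all steering command with the previous one:
    alpha * theta_new + (1 - alpha) * theta_old."""
    return alpha * theta_new + (1 - alpha) * theta_old


def rotate(v: np.ndarray, theta: float) -> np.ndarray:
    """Rotate a 2-D vector CCW by theta."""
    c, s = math.cos(theta), math.sin(theta)
    v = np.asarray(v, dtype=float)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def hp_bias(p_z: float, g_z: float, bias: HPBias, threshold: float = 0.2) -> float:
    """Heading command of the hydrostatic-pressure program.

    While the depth mismatch |P_z - G_z| is at least ``threshold`` the
    agent climbs or dives (+-pi/2) toward the target depth; once inside
    the depth band it swims along the fixed horizontal prior theta_HP.
    """
    if abs(p_z - g_z) >= threshold:
        return math.pi / 2 if g_z > p_z else -math.pi / 2
    return bias.theta_hp


def error_update(actual, potential, tau2: float = 0.1, dt: float = 0.001):
    """First-order tracking d(actual)/dt = (potential - actual)/tau2.

    Applied to velocities directly and to headings with the error wrapped
    to the shortest arc (-pi, pi].
    """
    actual_arr = np.asarray(actual, dtype=float)
    potential_arr = np.asarray(potential, dtype=float)
    a = 1.0 - math.exp(-dt / tau2)
    if actual_arr.ndim == 0:
        err = wrap_angle(float(potential_arr) - float(actual_arr))
        return float(actual_arr) + a * err
    return actual_arr + a * (potential_arr - actual_arr)


# ----------------------------------------------------------------------
# Scene computation


try:  # compiled ray-cast kernel; the numpy path below is the reference
    from numba import njit

    @njit(cache=False, fastmath=False)
    def _scene_kernel(centers, r, xmin, xmax, zmin, zmax, walls, px, pz,
                      heading, rel_angles, max_range):  # pragma: no cover
        nb = rel_angles.shape[0]
        out = np.empty(nb)
        n = centers.shape[0]
        for b in range(nb):
            ang = heading + rel_angles[b]
            ux = math.cos(ang)
            uz = math.sin(ang)
            best = np.inf
            for i in range(n):
                dx = centers[i, 0] - px
                dz = centers[i, 1] - pz
                t_ca = dx * ux + dz * uz
                disc = r * r - (dx * dx + dz * dz - t_ca * t_ca)
                if disc < 0.0:
                    continue
                root = math.sqrt(disc)
                t0 = t_ca - root
                if t0 >= 0.0:
                    t = t0
                elif t_ca + root >= 0.0:
                    t = 0.0
                else:
                    continue
                if t < best:
                    best = t
            if walls:
                if ux > 1e-12:
                    tw = (xmax - px) / ux
                elif ux < -1e-12:
                    tw = (xmin - px) / ux
                else:
                    tw = np.inf
                if tw < best:
                    best = max(tw, 0.0)
                if uz > 1e-12:
                    tw = (zmax - pz) / uz
                elif uz < -1e-12:
                    tw = (zmin - pz) / uz
                else:
                    tw = np.inf
                if tw < best:
                    best = max(tw, 0.0)
            out[b] = best if best <= max_range else np.inf
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _scene_distances(
    centers: np.ndarray,
    r: float,
    bounds: tuple[float, float, float, float],
    walls: bool,
    p: np.ndarray,
    heading: float,
    rel_angles: np.ndarray,
    max_range: float,
) -> np.ndarray:
    """Per-bin surface distances (inf = clear)."""
    if _HAVE_NUMBA:
        xmin, xmax, zmin, zmax = bounds
        return _scene_kernel(
            np.ascontiguousarray(centers.reshape(-1, 2)), r,
            xmin, xmax, zmin, zmax, walls,
            float(p[0]), float(p[1]), float(heading),
            rel_angles, max_range,
        )
    return _scene_distances_numpy(
        centers, r, bounds, walls, p, heading, rel_angles, max_range
    )


def _scene_distances_numpy(
    centers: np.ndarray,
    r: float,
    bounds: tuple[float, float, float, float],
    walls: bool,
    p: np.ndarray,
    heading: float,
    rel_angles: np.ndarray,
    max_range: float,
) -> np.ndarray:
    """Vectorised per-bin surface distances (inf = clear)."""
    dirs = heading + rel_angles
    u = np.column_stack([np.cos(dirs), np.sin(dirs)])  # (B, 2)
    dist = np.full(len(rel_angles), np.inf)
    if centers.size:
        delta = centers - p  # (n, 2)
        t_ca = u @ delta.T  # (B, n)
        d2 = np.einsum("ij,ij->i", delta, delta)  # (n,)
        disc = r * r - (d2[None, :] - t_ca**2)
        hit = disc >= 0
        root = np.sqrt(np.where(hit, disc, 0.0))
        t0 = t_ca - root
        t1 = t_ca + root
        t = np.where(t0 >= 0, t0, np.where(t1 >= 0, 0.0, np.inf))
        t = np.where(hit, t, np.inf)
        dist = t.min(axis=1)
    if walls:
        xmin, xmax, zmin, zmax = bounds
        with np.errstate(divide="ignore", invalid="ignore"):
            tx = np.where(
                u[:, 0] > 0, (xmax - p[0]) / u[:, 0],
                np.where(u[:, 0] < 0, (xmin - p[0]) / u[:, 0], np.inf),
            )
            tz = np.where(
                u[:, 1] > 0, (zmax - p[1]) / u[:, 1],
                np.where(u[:, 1] < 0, (zmin - p[1]) / u[:, 1], np.inf),
            )
        dist = np.minimum(dist, np.maximum(np.minimum(tx, tz), 0.0))
    return np.where(dist <= max_range, dist, np.inf)


def visual_scene(
    env: Environment, state: AgentState, params: ControlParams
) -> VisualScene:
    """Egocentric visual snapshot from the agent's current state."""
    rel = _rel_angles(params.n_bvc_bins)
    d = _scene_distances(
        env.coral_centers,
        env.config.coral_radius,
        env.bounds,
        env.config.walls_are_boundaries,
        state.p,
        state.theta,
        rel,
        params.bvc_range,
    )
    tv = env.target - state.p
    visible = bool(np.linalg.norm(tv) < params.r_vis)
    return VisualScene(d=d, target_visible=visible, target_vector=tv)


def _rel_angles(n_bins: int) -> np.ndarray:
    """Egocentric bin-center angles wrapped to (-pi, pi] (bin 0 ahead)."""
    return wrap_angle(np.arange(n_bins) * (2 * np.pi / n_bins))


def bvc_drive(
    scene: VisualScene,
    tuning: tuple[np.ndarray, np.ndarray] | None = None,
    bvc_range: float = 1.4,
) -> np.ndarray:
    """Per-bin input to the BVC array: a tuning function of the bin
    distance, maximal at boundary contact, decreasing with distance, zero
    beyond the receptive field. Clear bins map to zero.

    ``tuning`` may supply sampled (max_rates, field_sizes): each bin uses
    the population-mean linear ramp max_rate * max(0, 1 - d/field).
    """
    d = np.asarray(scene.d, dtype=float)
    if tuning is None:
        peak, fields = np.array([1.0]), np.array([bvc_range])
    else:
        peak, fields = (np.asarray(t, dtype=float) for t in tuning)
    drive = np.zeros_like(d)
    finite = np.isfinite(d)
    if np.any(finite):
        ramp = np.clip(1.0 - d[finite, None] / fields[None, :], 0.0, None)
        drive[finite] = (peak[None, :] * ramp).mean(axis=1)
    return drive


# ----------------------------------------------------------------------
# Strategies


@dataclass(frozen=True)
class Strategy:
    """Runtime strategy description consumed by run_trial."""

    kind: str  # null | azimuth | hp | hp_max | hp_default
    neuron_spec: NeuronModelSpec = field(default_factory=NeuronModelSpec)
    population_scale: float = 1.0
    rate_scale: float = 1.0

    @property
    def uses_hp(self) -> bool:
        return self.kind.startswith("hp")


def _initial_heading(
    strategy: Strategy, start: np.ndarray, target: np.ndarray, rng: np.random.Generator
) -> tuple[float, HPBias | None]:
    bearing = math.atan2(target[1] - start[1], target[0] - start[0])
    if strategy.kind == "null":
        return bearing + rng.uniform(-math.pi / 4, math.pi / 4), None
    if strategy.kind == "azimuth":
        return bearing, None
    if strategy.uses_hp:
        theta_hp = 0.0 if target[0] >= start[0] else math.pi
        bias = HPBias(theta_hp=theta_hp, target_depth=float(target[1]))
        return theta_hp, bias
    raise ValueError(f"unknown strategy kind {strategy.kind!r}")


def _spiking_velocity_channel(
    strategy: Strategy, params: ControlParams, seed: int
) -> SpikingChannel:
    """Velocity population for spiking mode: LIF neurons at the low rates
    observed in the recordings, scaled by the strategy's rate/population
    multipliers."""
    n = max(int(1500 * strategy.population_scale
                * strategy.neuron_spec.population_multiplier), 20)
    rng = np.random.default_rng(seed)
    rates, _ = sample_bvc_tuning(n, strategy.neuron_spec, seed)
    rates = rates * strategy.rate_scale
    ens = Ensemble(
        n_neurons=n,
        dim=2,
        kind="lif",
        radius=params.v_max * 1.5,
        max_rates=rates,
        intercepts=rng.uniform(-0.95, 0.95, n),
        seed=seed,
    )
    return SpikingChannel(ens, synapse=params.tau2)


def run_trial(
    env: Environment,
    strategy: Strategy | str,
    params: ControlParams | None = None,
    mode: str = "rate",
    seed: int | None = None,
) -> tuple[ms.Trajectory, ms.TrialResult]:
    """Simulate one navigation trial until target capture or t_max.

    Returns the logged trajectory and the normalized trial metrics.
    Deterministic in rate mode with noise_sigma = 0; otherwise seeded.
    """
    if isinstance(strategy, str):
        strategy = Strategy(kind=strategy)
    params = params or ControlParams()
    if mode not in ("rate", "spiking"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    dt = params.dt
    n_steps = int(round(params.t_max / dt))
    centers = env.coral_centers
    r = env.config.coral_radius
    bounds = env.bounds
    walls = env.config.walls_are_boundaries
    rel = _rel_angles(params.n_bvc_bins)
    frontal = np.abs(rel) <= math.pi / 2 + 1e-12
    g = env.target
    p = env.start.astype(float).copy()

    theta0, bias = _initial_heading(strategy, p, g, rng)
    theta_act = theta0
    v_act = compose_velocity(params.v_max, theta0)
    s_cmd = params.v_max
    theta_steer = 0.0
    wta_state = np.zeros(params.n_bvc_bins)
    channel = (
        _spiking_velocity_channel(strategy, params, seed or 0)
        if mode == "spiking"
        else None
    )

    log_t = np.empty(n_steps + 1)
    log_xy = np.empty((n_steps + 1, 2))
    log_col = np.zeros(n_steps + 1, dtype=bool)
    log_t[0], log_xy[0] = 0.0, p
    reached = False
    t_reach = None
    n_logged = 1
    vmax = params.v_max
    xmin, xmax, zmin, zmax = bounds
    sigma = params.noise_sigma
    # sensed-position error: Ornstein-Uhlenbeck with the tau1 synaptic time
    # constant and stationary std sigma (the positional state reaches the
    # sensory populations through synaptic filtering, so its error wanders
    # smoothly rather than flickering at the integration step)
    sense_err = np.zeros(2)
    ou_decay = math.exp(-dt / params.tau1)
    ou_diff = math.sqrt(max(1.0 - ou_decay**2, 0.0))

    for k in range(n_steps):
        if sigma > 0:
            sense_err = ou_decay * sense_err + sigma * ou_diff * rng.standard_normal(2)
            p_sense = p + sense_err
            p_sense[0] = min(max(p_sense[0], xmin + 1e-6), xmax - 1e-6)
            p_sense[1] = min(max(p_sense[1], zmin + 1e-6), zmax - 1e-6)
        else:
            p_sense = p
        d_bins = _scene_distances(
            centers, r, bounds, walls, p_sense, theta_act, rel, params.bvc_range
        )
        d0 = float(d_bins[0])

        delta_g = g - p_sense
        dist_g = math.hypot(delta_g[0], delta_g[1])
        visible = dist_g < params.r_vis

        # strategy heading command
        if visible:
            theta_base = math.atan2(delta_g[1], delta_g[0])
        elif bias is not None:
            theta_base = hp_bias(
                p_sense[1], bias.target_depth, bias, params.depth_threshold
            )
        else:
            theta_base = theta0

        # speed law on the commanded speed
        blocked = d0 < params.D
        if blocked:
            dhat = relative_distance(d0, params.eps, params.D)
            s_pot = min((s_cmd + params.v_eps) * dhat, s_cmd)
        else:
            s_pot = min(s_cmd + params.d_c * params.tau2, vmax)
        s_pot = fold_potential(s_pot, vmax)

        # steering via winner-take-all over the continuously filtered
        # frontal clearances (the filter keeps a short memory, damping
        # left/right flip-flop in front of symmetric obstacles)
        util = np.where(np.isfinite(d_bins), d_bins, params.bvc_range)
        util[~frontal] = -1.0
        wta_state = lowpass_step(wta_state, util, params.tau1, dt)
        if blocked:
            idx = int(np.argmax(wta_state))
            theta_new = float(np.clip(rel[idx], -math.pi / 2, math.pi / 2))
            theta_steer = steer(theta_new, theta_steer, params.alpha)
        else:
            # relax the steering back to the base heading over ~tau2, so a
            # committed turn persists long enough to skirt the obstacle
            theta_steer = float(lowpass_step(theta_steer, 0.0, params.tau2, dt))

        v_allo = compose_velocity(s_pot, theta_base)
        v_pot = rotate(v_allo, theta_steer) if theta_steer != 0.0 else v_allo
        if visible:
            v_pot = v_pot + delta_g  # goal attractor G(t)
            nv = math.hypot(v_pot[0], v_pot[1])
            if nv > vmax:
                v_pot *= vmax / nv

        if channel is not None:
            # the spiking population represents the potential velocity;
            # the error-based tau2 dynamics then track its decode
            v_pot_dec = channel.step(v_pot, dt)
            v_act = error_update(v_act, v_pot_dec, params.tau2, dt)
        else:
            v_act = error_update(v_act, v_pot, params.tau2, dt)
        nv = math.hypot(v_act[0], v_act[1])
        if nv > vmax:
            v_act = v_act * (vmax / nv)
        theta_pot = math.atan2(v_pot[1], v_pot[0])
        theta_act = float(error_update(theta_act, theta_pot, params.tau2, dt))
        s_cmd = nv if nv <= vmax else vmax

        p = p + v_act * dt
        p[0] = min(max(p[0], xmin + 1e-6), xmax - 1e-6)
        p[1] = min(max(p[1], zmin + 1e-6), zmax - 1e-6)
        if not (np.isfinite(p).all() and np.isfinite(v_act).all()):
            traj = ms.Trajectory(
                t=log_t[:n_logged], xy=log_xy[:n_logged], collided=log_col[:n_logged]
            )
            raise SimulationDiverged("agent state became non-finite", traj)

        tcur = (k + 1) * dt
        log_t[n_logged] = tcur
        log_xy[n_logged] = p
        if centers.size:
            dmin = np.min(np.einsum("ij,ij->i", centers - p, centers - p))
            log_col[n_logged] = dmin < r * r
        n_logged += 1

        if math.hypot(g[0] - p[0], g[1] - p[1]) < params.capture_radius:
            reached = True
            t_reach = tcur
            break

    traj = ms.Trajectory(
        t=log_t[:n_logged], xy=log_xy[:n_logged], collided=log_col[:n_logged], dt=dt
    )
    straight = env.straight_distance
    crate = float(np.mean(traj.collided)) if n_logged else 0.0
    if reached:
        tn = ms.time_to_target_norm(t_reach, straight, vmax, params.t_max)
        dn = ms.distance_norm(traj.path_length, straight, vmax, params.t_max)
    else:
        tn = dn = None
    result = ms.TrialResult(
        reached=int(reached),
        time_norm=tn,
        dist_norm=dn,
        collision_rate=crate,
        t_reach=t_reach,
        meta={"strategy": strategy.kind, "mode": mode, "seed": seed},
    )
    result.total_score = ms.total_score(result)
    return traj, result
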