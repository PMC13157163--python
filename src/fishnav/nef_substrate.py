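"""Minimal population-coding substrate (Neural Engineering Framework style).

Variables are represented by populations of neurons with heterogeneous
tuning curves; functions of represented variables are computed by
regularized least-squares decoders; signals between populations pass
through first-order synaptic low-pass filters. Two execution modes share
one parameterization:

* *rate* mode evaluates the static tuning curves each step -- fully
  deterministic, and the oracle the spiking mode is checked against;
* *spiking* mode integrates the neuron dynamics (LIF voltage with
  refractory period, or spiking rectified-linear accumulation) and
  decodes filtered spike trains.

Per-neuron gain/bias are solved from (max_rate, intercept) so that the
rate is 0 at the intercept and max_rate at full encoder alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Ensemble",
    "Connection",
    "EnsembleArray",
    "Network",
    "compute_decoders",
    "lowpass_step",
    "integrator_step",
    "winner_take_all",
    "simulate",
    "SpikingChannel",
]


def _lif_rate(J: np.ndarray, tau_rc: float, tau_ref: float) -> np.ndarray:
    """Steady-state LIF rate for normalized drive J (threshold at J=1)."""
    out = np.zeros_like(J, dtype=float)
    above = J > 1 + 1e-12
    Ja = J[above]
    out[above] = 1.0 / (tau_ref + tau_rc * np.log1p(1.0 / (Ja - 1.0)))
    return out


def _relu_rate(J: np.ndarray) -> np.ndarray:
    return np.maximum(J, 0.0)


@dataclass
class Ensemble:
    """A population representing a ``dim``-dimensional variable.

    Encoders are unit vectors; gains and biases are derived from sampled
    (max_rate, intercept) pairs so the tuning-curve contract holds:
    rate = 0 at the intercept, rate = max_rate where encoder.x = radius.
    """

    n_neurons: int
    dim: int = 1
    kind: str = "lif"  # or "spiking_rectified_linear"
    radius: float = 1.0
    max_rates: np.ndarray | None = None
    intercepts: np.ndarray | None = None
    encoders: np.ndarray | None = None
    tau_rc: float = 0.02
    tau_ref: float = 0.002
    seed: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("ensemble needs at least one neuron")
        rng = np.random.default_rng(self.seed)
        n, d = self.n_neurons, self.dim
        if self.max_rates is None:
            self.max_rates = rng.uniform(200.0, 400.0, n)
        self.max_rates = np.asarray(self.max_rates, dtype=float)
        if self.intercepts is None:
            self.intercepts = rng.uniform(-1.0, 1.0, n)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if self.encoders is None:
            if d == 1:
                self.encoders = rng.choice([-1.0, 1.0], size=(n, 1))
            else:
                e = rng.normal(size=(n, d))
                self.encoders = e / np.linalg.norm(e, axis=1, keepdims=True)
        self.encoders = np.asarray(self.encoders, dtype=float).reshape(n, d)
        norms = np.linalg.norm(self.encoders, axis=1, keepdims=True)
        self.encoders = self.encoders / norms
        self._solve_gain_bias()

    def _solve_gain_bias(self) -> None:
        x_int = self.intercepts
        r_max = self.max_rates
        if self.kind == "spiking_rectified_linear":
            # rate(J) = max(J, 0); J = gain*(e.x)/radius + bias
            self.gains = r_max / (1.0 - x_int)
            self.biases = -self.gains * x_int
        elif self.kind == "lif":
            # J at which the LIF fires at r_max
            with np.errstate(over="ignore"):
                J_max = 1.0 / (
                    1.0 - np.exp((self.tau_ref - 1.0 / r_max) / self.tau_rc)
                )
            self.gains = (J_max - 1.0) / (1.0 - x_int)
            self.biases = 1.0 - self.gains * x_int
        else:
            raise ValueError(f"unknown neuron kind {self.kind!r}")

    # --- static (rate-mode) responses -------------------------------
    def currents(self, x: np.ndarray) -> np.ndarray:
        """Normalized drive J for represented value(s) x: (..., dim)."""
        x = np.asarray(x, dtype=float)
        proj = x @ self.encoders.T / self.radius
        return self.gains * proj + self.biases

    def rates(self, x: np.ndarray) -> np.ndarray:
        J = self.currents(x)
        if self.kind == "lif":
            return _lif_rate(J, self.tau_rc, self.tau_ref)
        return _relu_rate(J)

    # --- spiking dynamics -------------------------------------------
    def init_state(self) -> dict[str, np.ndarray]:
        return {
            "voltage": np.zeros(self.n_neurons),
            "refractory": np.zeros(self.n_neurons),
        }

    def step_spikes(
        self, J: np.ndarray, state: dict[str, np.ndarray], dt: float
    ) -> np.ndarray:
        """Advance neuron dynamics one step; returns spike amplitudes
        (1/dt where a spike occurred, so filtered output is in rate units)."""
        if self.kind == "spiking_rectified_linear":
            v = state["voltage"]
            v += np.maximum(J, 0.0) * dt
            spikes = np.floor(v)
            v -= spikes
            return spikes / dt
        v = state["voltage"]
        ref = state["refractory"]
        dv = (J - v) * (dt / self.tau_rc)
        active = ref <= 0
        v[:] = np.where(active, v + dv, v)
        ref[:] = np.maximum(ref - dt, 0.0)
        spiked = v > 1.0
        out = np.zeros(self.n_neurons)
        out[spiked] = 1.0 / dt
        v[spiked] = 0.0
        ref[spiked] = self.tau_ref
        return out


def compute_decoders(
    e: Ensemble,
    f=None,
    regularization: float = 0.1,
    n_points: int = 500,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Regularized least-squares decoders for function ``f`` of the
    represented variable (identity when ``f`` is None).

    Evaluation points are drawn uniformly from the representational ball;
    the ridge parameter is ``(regularization * max activity)**2 * n_points``,
    so any ``regularization > 0`` keeps the system well posed.
    """
    if rng is None:
        rng = np.random.default_rng(e.seed)
    if e.dim == 1:
        pts = np.linspace(-e.radius, e.radius, n_points)[:, None]
    else:
        u = rng.normal(size=(n_points, e.dim))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        radii = rng.uniform(size=(n_points, 1)) ** (1.0 / e.dim)
        pts = u * radii * e.radius
    A = e.rates(pts)  # (n_points, n_neurons)
    targets = pts if f is None else np.asarray([np.atleast_1d(f(p)) for p in pts])
    targets = targets.reshape(n_points, -1)
    sigma = regularization * A.max() if A.max() > 0 else regularization
    G = A.T @ A + n_points * sigma**2 * np.eye(e.n_neurons)
    decoders = np.linalg.solve(G, A.T @ targets)
    return decoders  # (n_neurons, out_dim)


def lowpass_step(state, input_, tau: float, dt: float):
    """Exact discrete step of a first-order synaptic low-pass filter."""
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be positive")
    state = np.asarray(state, dtype=float)
    input_ = np.asarray(input_, dtype=float)
    a = 1.0 - np.exp(-dt / tau)
    out = state + a * (input_ - state)
    return float(out) if out.ndim == 0 else out


def integrator_step(pos_state, velocity_input, tau2: float, dt: float):
    """One step of the recurrent neural integrator dp/dt = v.

    The recurrence uses identity feedback with the input scaled by the
    synaptic time constant tau2 (changing units m/s -> m); with perfect
    decoders this reduces exactly to p <- p + v*dt (the input scaling is
    the discrete-exact mapping tau_eff = dt / (1 - exp(-dt/tau2)), which
    tends to tau2's continuous-time role as dt -> 0).
    """
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    pos_state = np.asarray(pos_state, dtype=float)
    v = np.asarray(velocity_input, dtype=float)
    a = 1.0 - np.exp(-dt / tau2)
    tau_eff = dt / a
    out = pos_state + a * tau_eff * v  # == pos_state + v * dt
    return float(out) if out.ndim == 0 else out


def winner_take_all(
    utilities: np.ndarray,
    smoothed: np.ndarray | None = None,
    tau: float | None = None,
    dt: float | None = None,
) -> tuple[int, np.ndarray]:
    """Select the channel with maximal (optionally low-pass filtered)
    utility; ties break deterministically to the lowest index.

    Returns (selected index, filtered utilities). This is the functional
    stand-in for a basal-ganglia/thalamus action-selection circuit: the
    hook point for swapping in a full published circuit is here.
    """
    utilities = np.asarray(utilities, dtype=float)
    if utilities.size == 0:
        raise ValueError("winner_take_all needs at least one utility")
    if smoothed is not None and tau is not None and dt is not None:
        utilities = lowpass_step(smoothed, utilities, tau, dt)
    idx = int(np.argmax(utilities))  # argmax takes the first maximum
    return idx, np.atleast_1d(utilities)


# ----------------------------------------------------------------------
# Small network-graph layer, enough to wire relays and integrators.


class Connection:
    """Decoded connection between two network members.

    Decoders are computed once, before simulation starts, and stay fixed
    for its whole duration.
    """

    def __init__(self, source, target, function=None, synapse=0.005, transform=1.0):
        if synapse is not None and synapse < 0:
            raise ValueError("synapse must be >= 0")
        self.source, self.target = source, target
        self.function, self.synapse, self.transform = function, synapse, transform
        self.decoders: np.ndarray | None = None


class EnsembleArray:
    """Array of independent 1-D ensembles, one per channel (the BVC
    representation: 24 directional channels)."""

    def __init__(self, n_channels: int, n_neurons_per: int, seed: int = 0, **kw):
        self.n_channels = n_channels
        self.channels = [
            Ensemble(n_neurons_per, dim=1, seed=seed + i, **kw)
            for i in range(n_channels)
        ]

    def rates(self, x: np.ndarray) -> list[np.ndarray]:
        return [ch.rates(np.atleast_1d(xi)[:, None]) for ch, xi in zip(self.channels, x)]


class Network:
    """A tiny fixed-step simulator over nodes, ensembles and connections."""

    def __init__(self, dt: float = 0.001):
        self.dt = dt
        self.members: dict[str, object] = {}
        self.node_fns: dict[str, object] = {}
        self.connections: list[Connection] = []
        self.probes: list[str] = []

    def add_node(self, name: str, fn) -> str:
        """fn(t) -> value, or a constant."""
        self.members[name] = "node"
        self.node_fns[name] = fn
        return name

    def add_ensemble(self, name: str, ens: Ensemble) -> str:
        self.members[name] = ens
        return name

    def connect(self, source, target, function=None, synapse=0.005, transform=1.0):
        conn = Connection(source, target, function, synapse, transform)
        self.connections.append(conn)
        return conn

    def probe(self, name: str) -> str:
        if name not in self.members:
            raise ValueError(f"cannot probe unknown member {name!r}")
        self.probes.append(name)
        return name


def simulate(
    network: Network,
    duration: float,
    dt: float | None = None,
    mode: str = "rate",
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Run a network for ``duration`` seconds; returns probed time series
    (key "time" plus one series per probed member).

    Rate mode is deterministic; spiking mode is reproducible under a fixed
    seed (used only to build any unseeded ensembles -- the neuron dynamics
    themselves are deterministic threshold crossings).
    """
    dt = dt or network.dt
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < 0:
        raise ValueError("duration must be >= 0")
    n_steps = int(round(duration / dt))
    if not network.probes:
        raise ValueError("no probes connected")
    if mode not in ("rate", "spiking"):
        raise ValueError(f"unknown mode {mode!r}")

    for conn in network.connections:
        src = network.members[conn.source]
        if isinstance(src, Ensemble) and conn.decoders is None:
            conn.decoders = compute_decoders(src, conn.function)

    def member_dim(name: str) -> int:
        m = network.members[name]
        if isinstance(m, Ensemble):
            return m.dim
        fn = network.node_fns[name]
        v = np.atleast_1d(np.asarray(fn(0.0) if callable(fn) else fn, dtype=float))
        return v.size

    # "values" holds the represented value of each member: node outputs for
    # nodes, filtered input for ensembles (the NEF state variable).
    values = {name: np.zeros(member_dim(name)) for name in network.members}
    inputs = {name: np.zeros(member_dim(name)) for name in network.members}
    filt = {id(c): np.zeros(member_dim(c.target)) for c in network.connections}
    spike_states = {
        name: m.init_state()
        for name, m in network.members.items()
        if isinstance(m, Ensemble)
    }
    spike_filters = {
        name: np.zeros(network.members[name].n_neurons) for name in spike_states
    }

    out = {name: np.zeros((n_steps, member_dim(name))) for name in network.probes}
    times = np.arange(1, n_steps + 1) * dt

    for k in range(n_steps):
        t = times[k]
        for name, fn in network.node_fns.items():
            values[name] = np.atleast_1d(
                np.asarray(fn(t) if callable(fn) else fn, dtype=float)
            )
        for name, m in network.members.items():
            if not isinstance(m, Ensemble):
                continue
            values[name] = inputs[name]
            if mode == "spiking":
                x = inputs[name]
                J = m.gains * (x @ m.encoders.T / m.radius) + m.biases
                spikes = m.step_spikes(J, spike_states[name], dt)
                spike_filters[name] = lowpass_step(
                    spike_filters[name], spikes, 0.005, dt
                )
        new_inputs = {name: np.zeros_like(v) for name, v in inputs.items()}
        for conn in network.connections:
            src = network.members[conn.source]
            if isinstance(src, Ensemble):
                if mode == "rate":
                    acts = src.rates(values[conn.source][None, :])
                    signal = (acts @ conn.decoders)[0]
                else:
                    signal = spike_filters[conn.source] @ conn.decoders
            else:
                signal = values[conn.source]
                if conn.function is not None:
                    signal = np.atleast_1d(conn.function(signal))
            signal = np.atleast_1d(conn.transform * signal)
            if conn.synapse:
                filt[id(conn)] = lowpass_step(filt[id(conn)], signal, conn.synapse, dt)
                signal = filt[id(conn)]
            new_inputs[conn.target] = new_inputs[conn.target] + signal
        inputs = new_inputs
        for name in network.probes:
            out[name][k] = values[name]
    result = {"time": times}
    result.update(out)
    return result


class SpikingChannel:
    """Encode-spike-decode pipeline for one represented variable.

    Wraps an Ensemble so a controller can push a value in each step and
    read back the synaptically filtered spiking decode -- the mechanism by
    which the navigator's kinematic signals acquire spiking variability.
    """

    def __init__(
        self,
        ensemble: Ensemble,
        synapse: float = 0.005,
        regularization: float = 0.1,
    ):
        self.ens = ensemble
        self.synapse = synapse
        self.decoders = compute_decoders(ensemble, None, regularization)
        self.state = ensemble.init_state()
        self.filtered = np.zeros(ensemble.n_neurons)

    def step(self, x: np.ndarray, dt: float) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        J = self.ens.gains * (x @ self.ens.encoders.T / self.ens.radius) + self.ens.biases
        spikes = self.ens.step_spikes(J, self.state, dt)
        self.filtered = lowpass_step(self.filtered, spikes, self.synapse, dt)
        return self.filtered @ self.decoders

    def rate_decode(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return (self.ens.rates(x) @ self.decoders)[0]
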