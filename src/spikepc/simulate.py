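"""Clock-driven Euler simulation of predictive-coding spiking networks.

The simulation advances, on a common time grid, (i) the reference dynamical
system ``dx/dt = A x + c(t)``, (ii) the membrane voltages, (iii) the
filtered rates ``r`` and the readout ``x_hat = Gamma r``.  Spiking is
greedy: by default at most one neuron — the one with the largest
suprathreshold margin — fires per time step, which is the faithful
discrete-time minimiser of the spike-placement cost and avoids the
"ping-pong" artifact of letting opposing neurons fire simultaneously.  The
permissive all-suprathreshold policy is retained for studying that artifact.

Voltage noise is injected with a fixed per-step standard deviation
``sigma_V`` (``noise_mode="per-step"``), the convention used throughout for
quoting noise levels; a diffusion-style ``sqrt(dt)`` scaling is available.

The inner loop lives in :mod:`spikepc._core` and costs O(N J) per step.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import _core
from .model_spec import ConfigurationError, LinearSystemSpec, NetworkParams

__all__ = [
    "SimState",
    "SimResult",
    "PerturbationPlan",
    "step",
    "select_spikes",
    "run",
    "make_command",
    "verify_voltage_identity",
    "SimulationDiverged",
]

_POLICIES = {"one-per-step": 0, "all-suprathreshold": 1}


class SimulationDiverged(RuntimeError):
    """Voltages left the finite range: the large-N approximation broke down
    (e.g. too-fast dynamics or vanishing kernels and costs)."""


# --------------------------------------------------------------------------
# state containers
# --------------------------------------------------------------------------

@dataclass
class SimState:
    """Instantaneous simulation state (used by the reference stepper and to
    warm-start runs)."""

    t: float
    x: np.ndarray       # (J,) reference state
    V: np.ndarray       # (N,) voltages
    r: np.ndarray       # (N,) filtered rates, >= 0
    xhat: np.ndarray    # (J,) readout Gamma r
    spiked: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def copy(self) -> "SimState":
        return SimState(self.t, self.x.copy(), self.V.copy(), self.r.copy(),
                        self.xhat.copy(), self.spiked.copy())


@dataclass
class SimResult:
    """Spike raster plus optional dense traces of a single run.

    ``spike_times`` are sorted (ties broken by neuron id); traces are
    post-step samples every ``trace_stride`` steps.
    """

    spike_times: np.ndarray
    spike_neurons: np.ndarray
    dt: float
    duration: float
    seed: Optional[int]
    traces: Optional[dict] = None          # time, V, r, xhat, x
    snapshots: Optional[dict] = None       # pre-spike x, xhat, V_k, r_k
    final_state: Optional[SimState] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_spikes(self) -> int:
        return self.spike_times.shape[0]

    def raster(self) -> np.ndarray:
        """(n_spikes, 2) array of (neuron id, spike time)."""
        return np.column_stack([self.spike_neurons.astype(float), self.spike_times])

    def spike_train(self, i: int) -> np.ndarray:
        return self.spike_times[self.spike_neurons == i]

    def rates(self, window: Optional[tuple[float, float]] = None) -> np.ndarray:
        """Mean firing rate (Hz) per neuron over ``window`` (default: full run)."""
        t0, t1 = window if window is not None else (0.0, self.duration)
        sel = (self.spike_times >= t0) & (self.spike_times < t1)
        n = int(self.meta.get("N", self.spike_neurons.max(initial=-1) + 1))
        counts = np.bincount(self.spike_neurons[sel], minlength=n)
        return counts / (t1 - t0)


@dataclass
class PerturbationPlan:
    """Timed interventions applied during a run.

    * ``clamps``: (t0, t1, neurons, value) — hold V of ``neurons`` at
      ``value``; they cannot spike (sudden inactivation).
    * ``suppressions``: (t0, t1, neurons) — neurons cannot spike but evolve.
    * ``forced_spikes``: (t, neuron) — emit a spike regardless of threshold.

    ``delay_spike`` composes a suppression with a forced spike, reproducing
    the single-spike-delay perturbation used to probe network chaos.
    """

    clamps: list = field(default_factory=list)
    suppressions: list = field(default_factory=list)
    forced_spikes: list = field(default_factory=list)

    @staticmethod
    def delay_spike(neuron: int, t_spike: float, delay: float = 1e-3
                    ) -> "PerturbationPlan":
        return PerturbationPlan(
            suppressions=[(t_spike - 1e-12, t_spike + delay, [neuron])],
            forced_spikes=[(t_spike + delay, neuron)],
        )

    def merge(self, other: "PerturbationPlan") -> "PerturbationPlan":
        return PerturbationPlan(
            clamps=self.clamps + other.clamps,
            suppressions=self.suppressions + other.suppressions,
            forced_spikes=self.forced_spikes + other.forced_spikes,
        )

    def validate(self, duration: float) -> None:
        for t0, t1, _, *rest in [c for c in self.clamps] :
            if not (0 <= t0 < t1):
                raise ConfigurationError("bad clamp interval")
        for t, _ in self.forced_spikes:
            if not 0 <= t <= duration:
                raise ConfigurationError("forced spike outside run window")


# --------------------------------------------------------------------------
# reference single step (numpy; oracle for the compiled path)
# --------------------------------------------------------------------------

def select_spikes(V: np.ndarray, T: np.ndarray, policy: str = "one-per-step",
                  rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Indices of neurons that fire given voltages and thresholds.

    ``one-per-step``: the argmax of the margin ``V - T`` among suprathreshold
    neurons (exact ties broken uniformly at random) — the greedy cost
    minimiser, since the cost decrease of a spike is ``2 (V_i - T_i)``.
    ``all-suprathreshold``: every neuron above threshold.
    """
    V = np.asarray(V, float)
    T = np.asarray(T, float)
    if V.shape != T.shape:
        raise ConfigurationError("V and T must have the same length")
    if policy not in _POLICIES:
        raise ConfigurationError(f"unknown spike policy {policy!r}")
    above = np.flatnonzero(V > T)
    if above.size == 0:
        return above
    if policy == "all-suprathreshold":
        return above
    m = (V - T)[above]
    ties = above[m == m.max()]
    if ties.size == 1:
        return ties
    rng = rng or np.random.default_rng()
    return np.array([ties[rng.integers(ties.size)]])


def step(state: SimState, net: NetworkParams, system: LinearSystemSpec,
         dt: float, rng: Optional[np.random.Generator] = None,
         c: Optional[np.ndarray] = None, policy: str = "one-per-step",
         noise: Optional[np.ndarray] = None) -> SimState:
    """Advance the coupled system by one Euler step (reference path).

    Mirrors the compiled loop operation-for-operation: Euler on x, Euler on
    V (leak, feedforward, slow recurrent drive, optional per-step noise),
    decay of r and x_hat, spike selection, instantaneous fast kicks.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    s = state.copy()
    G = net.Gamma
    if c is None:
        c = system.command_at(np.array([state.t]))[0]
    s.x = s.x + dt * (system.A @ s.x + c)
    u = c + system.A @ s.xhat + net.lambda_d * s.xhat
    dV = net.lambda_V * (net.v_rest - s.V) + net.gain * (G.T @ u)
    s.V = s.V + dt * dV
    if noise is not None:
        s.V = s.V + net.gain * net.sigma_V_vec() * noise
    s.r = s.r * (1 - net.lambda_d * dt)
    s.xhat = s.xhat * (1 - net.lambda_d * dt)
    spiked = select_spikes(s.V, net.T, policy, rng)
    for k in spiked:
        s.V = s.V - net.gain * (G.T @ G[:, k])
        s.V[k] -= net.gain[k] * net.costs.mu
        s.r[k] += 1.0
        s.xhat = s.xhat + G[:, k]
    s.spiked = spiked
    s.t = state.t + dt
    return s


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------

def _param_hash(net: NetworkParams, dt: float, duration: float) -> str:
    h = hashlib.sha256()
    for a in (net.Gamma, net.T, net.gain, net.v_rest, net.sigma_V_vec()):
        h.update(np.ascontiguousarray(a).tobytes())
    h.update(np.array([net.lambda_V, net.lambda_d, net.costs.nu, net.costs.mu,
                       dt, duration]).tobytes())
    return h.hexdigest()[:16]


def run(net: NetworkParams,
        system: LinearSystemSpec,
        duration: float,
        dt: float = 1e-4,
        seed: Optional[int] = 0,
        plan: Optional[PerturbationPlan] = None,
        command: Optional[Callable[[np.ndarray], np.ndarray]] = None,
        policy: str = "one-per-step",
        noise_mode: str = "per-step",
        record_traces: bool = False,
        trace_stride: int = 1,
        record_snapshots: bool = False,
        initial_state: Optional[SimState] = None,
        warm_start_rates: bool = False,
        max_chunk: int = 40_000,
        meta: Optional[dict] = None) -> SimResult:
    """Simulate the network for ``duration`` seconds.

    Deterministic given (inputs, seed): the voltage-noise stream and the
    tie-break stream are drawn from two independent child generators of
    ``seed``, so changing the spiking policy does not shift the noise.

    ``warm_start_rates`` initialises ``r`` by a non-negative least-squares
    fit of ``Gamma r = x0`` so the network starts out representing the
    system's initial state instead of zero.
    """
    if dt <= 0 or duration <= 0:
        raise ConfigurationError("dt and duration must be > 0")
    if policy not in _POLICIES:
        raise ConfigurationError(f"unknown spike policy {policy!r}")
    if noise_mode not in ("per-step", "sqrt-dt"):
        raise ConfigurationError(f"unknown noise mode {noise_mode!r}")
    G = net.Gamma
    if G is None:
        raise ConfigurationError("NetworkParams.Gamma required for simulation")
    J, N = G.shape
    if system.J != J:
        raise ConfigurationError("system dimension does not match kernels")
    n_steps = int(round(duration / dt))
    cmd = command if command is not None else system.command_at

    # --- initial state
    if initial_state is not None:
        st = initial_state.copy()
    else:
        x0 = system.x0.astype(float).copy()
        r0 = np.zeros(N)
        if warm_start_rates and np.any(x0):
            from scipy.optimize import nnls
            r0, _ = nnls(G, x0)
        xhat0 = G @ r0
        V0 = net.gain * (G.T @ (x0 - xhat0) - net.costs.mu * r0) + net.v_rest
        st = SimState(0.0, x0, V0, r0, xhat0)

    sigma_step = net.gain * net.sigma_V_vec()
    if noise_mode == "sqrt-dt":
        sigma_step = sigma_step * np.sqrt(dt)
    have_noise = bool(np.any(sigma_step > 0))
    root = np.random.default_rng(seed)
    noise_rng, tie_rng = root.spawn(2)

    # --- perturbation schedule -> chunk boundaries
    plan = plan or PerturbationPlan()
    plan.validate(duration)
    edges = {0, n_steps}
    clamps = [(int(round(t0 / dt)), int(round(t1 / dt)),
               np.asarray(idx, dtype=np.int64), float(v))
              for (t0, t1, idx, v) in plan.clamps]
    sups = [(int(round(t0 / dt)), int(round(t1 / dt)),
             np.asarray(idx, dtype=np.int64))
            for (t0, t1, idx) in plan.suppressions]
    forced = sorted((max(0, min(n_steps - 1, int(round(t / dt)))), int(i))
                    for (t, i) in plan.forced_spikes)
    for s0, s1, *_ in clamps + sups:
        edges.add(max(0, min(n_steps, s0)))
        edges.add(max(0, min(n_steps, s1)))
    edges = sorted(edges)

    # --- output buffers
    if record_traces:
        n_rows = (n_steps + trace_stride - 1) // trace_stride
        tr_V = np.empty((n_rows, N)); tr_r = np.empty((n_rows, N))
        tr_xhat = np.empty((n_rows, J)); tr_x = np.empty((n_rows, J))
        stride = trace_stride
    else:
        tr_V = np.empty((0, N)); tr_r = np.empty((0, N))
        tr_xhat = np.empty((0, J)); tr_x = np.empty((0, J))
        stride = 0
    all_steps: list[np.ndarray] = []
    all_neurons: list[np.ndarray] = []
    snaps_x: list[np.ndarray] = []; snaps_xh: list[np.ndarray] = []
    snaps_V: list[np.ndarray] = []; snaps_r: list[np.ndarray] = []

    A = np.ascontiguousarray(system.A)
    GT = np.ascontiguousarray(G.T)
    empty_noise = np.empty((0, 0))
    for e0, e1 in zip(edges[:-1], edges[1:]):
        clamp_mask = np.zeros(N, dtype=np.bool_)
        clamp_value = 0.0
        for s0, s1, idx, v in clamps:
            if s0 <= e0 < s1:
                clamp_mask[idx] = True
                clamp_value = v
        sup_mask = np.zeros(N, dtype=np.bool_)
        for s0, s1, idx in sups:
            if s0 <= e0 < s1:
                sup_mask[idx] = True
        pos = e0
        while pos < e1:
            S = min(max_chunk, e1 - pos)
            t_grid = (np.arange(pos, pos + S) + 0.0) * dt
            c_arr = np.ascontiguousarray(cmd(t_grid))
            if c_arr.shape != (S, J):
                raise ConfigurationError(
                    f"command returned {c_arr.shape}, expected {(S, J)}")
            noise = (noise_rng.standard_normal((S, N)) if have_noise
                     else empty_noise)
            tie_u = tie_rng.random(S)
            cap = S if _POLICIES[policy] == 0 else max(8 * S, N)
            spk_step = np.empty(cap, dtype=np.int64)
            spk_neuron = np.empty(cap, dtype=np.int64)
            f_here = [(fs - pos, fn) for fs, fn in forced if pos <= fs < pos + S]
            f_steps = np.array([a for a, _ in f_here], dtype=np.int64)
            f_neurons = np.array([b for _, b in f_here], dtype=np.int64)
            if record_snapshots:
                sx = np.empty((cap, J)); sxh = np.empty((cap, J))
                sV = np.empty(cap); sr = np.empty(cap)
            else:
                sx = np.empty((0, J)); sxh = np.empty((0, J))
                sV = np.empty(0); sr = np.empty(0)
            n_spk, status, last = _core._sim_chunk(
                st.x, st.V, st.r, st.xhat,
                GT, A, net.lambda_d, net.lambda_V, net.costs.mu,
                net.T, net.gain, net.v_rest,
                c_arr, dt, sigma_step, noise, tie_u,
                _POLICIES[policy], clamp_mask, clamp_value, sup_mask,
                f_steps, f_neurons, spk_step, spk_neuron,
                record_snapshots, sx, sxh, sV, sr,
                stride, tr_V, tr_r, tr_xhat, tr_x, pos,
            )
            all_steps.append(spk_step[:n_spk].copy())
            all_neurons.append(spk_neuron[:n_spk].copy())
            if record_snapshots:
                snaps_x.append(sx[:n_spk].copy()); snaps_xh.append(sxh[:n_spk].copy())
                snaps_V.append(sV[:n_spk].copy()); snaps_r.append(sr[:n_spk].copy())
            if status == _core.DIVERGED:
                raise SimulationDiverged(
                    f"non-finite/unbounded voltage at t={(pos + last) * dt:.6f} s; "
                    "the network is outside the regime where the derived "
                    "voltage dynamics are valid")
            if status == _core.OVERFLOW:
                raise SimulationDiverged(
                    f"spike buffer overflow at t={(pos + last) * dt:.6f} s "
                    "(runaway firing; likely ping-pong under the permissive "
                    "policy — increase spike costs)")
            pos += S
    st.t = n_steps * dt

    steps = np.concatenate(all_steps) if all_steps else np.empty(0, np.int64)
    neurons = np.concatenate(all_neurons) if all_neurons else np.empty(0, np.int64)
    order = np.lexsort((neurons, steps))
    times = (steps[order] + 1.0) * dt   # spikes land at the end of their step
    result = SimResult(
        spike_times=times,
        spike_neurons=neurons[order],
        dt=dt, duration=duration, seed=seed,
        final_state=st,
        meta=dict(meta or {}, N=N, J=J, policy=policy,
                  param_hash=_param_hash(net, dt, duration)),
    )
    if record_traces:
        result.traces = {
            "time": np.arange(tr_V.shape[0]) * (dt * trace_stride) + dt,
            "V": tr_V, "r": tr_r, "xhat": tr_xhat, "x": tr_x,
        }
    if record_snapshots:
        result.snapshots = {
            "x": np.concatenate(snaps_x)[order] if snaps_x else np.empty((0, J)),
            "xhat": np.concatenate(snaps_xh)[order] if snaps_xh else np.empty((0, J)),
            "V": np.concatenate(snaps_V)[order] if snaps_V else np.empty(0),
            "r": np.concatenate(snaps_r)[order] if snaps_r else np.empty(0),
        }
    return result


# --------------------------------------------------------------------------
# command protocols
# --------------------------------------------------------------------------

def make_command(protocol: str, params: Optional[dict] = None,
                 J: int = 1, seed: Optional[int] = None
                 ) -> Callable[[np.ndarray], np.ndarray]:
    """Build a command-signal generator ``c(t)`` for one of the stock
    protocols.

    Stochastic protocols (``noisy-step``, ``white-noise-filtered``) hold a
    private random generator and must be evaluated on contiguous,
    non-overlapping time chunks in order (as :func:`run` does); rebuild the
    command for every trial.

    protocols
    ---------
    noisy-step
        Piecewise-constant stimulus ``amplitude`` on ``[t_on, t_off)`` with
        optional shared Gaussian sensory noise of per-step s.d. ``noise_sd``
        (noise only while the stimulus is on, broadcast to all J components
        — the replicated-variable convention).
    push-pull-2d
        Reach force for the 2-D point-mass arm: a single sine cycle
        ``F sin(2 pi (t - t_start)/t_reach)`` along ``direction``, applied
        to the velocity components (2, 3) of the 4-D state: acceleration
        then symmetric deceleration, zero net impulse.
    differentiator-drive
        Smooth scalar drive (sum of raised-cosine bumps given by ``bumps``:
        list of (t0, width, height)) multiplied by per-component ``weights``.
    oscillator-kick
        ``amplitude`` on component ``component`` during
        ``[t_kick, t_kick + width)``, zero elsewhere.
    white-noise-filtered
        Gaussian white noise (``mean``, per-step s.d. ``sd``) passed through
        an exponential filter of time constant ``tau`` (the GLM drive),
        broadcast through ``weights``.
    """
    p = dict(params or {})

    if protocol == "noisy-step":
        amp = p.get("amplitude", 1.0)
        t_on, t_off = p.get("t_on", 0.0), p.get("t_off", 0.5)
        noise_sd = p.get("noise_sd", 0.0)
        rng = np.random.default_rng(seed)

        def cmd(t: np.ndarray) -> np.ndarray:
            t = np.atleast_1d(t)
            on = (t >= t_on) & (t < t_off)
            base = np.where(on, float(amp), 0.0)
            if noise_sd > 0:
                base = base + noise_sd * rng.standard_normal(t.shape[0]) * on
            return np.repeat(base[:, None], J, axis=1)
        return cmd

    if protocol == "push-pull-2d":
        F = p.get("force", 1.0)
        theta = p.get("direction", 0.0)
        t0 = p.get("t_start", 0.1)
        reach = p.get("t_reach", 0.4)
        if J != 4:
            raise ConfigurationError("push-pull-2d needs a 4-D arm state")

        def cmd(t: np.ndarray) -> np.ndarray:
            t = np.atleast_1d(t)
            c = np.zeros((t.shape[0], 4))
            win = (t >= t0) & (t < t0 + reach)
            prof = F * np.sin(2 * np.pi * (t - t0) / reach) * win
            c[:, 2] = prof * np.cos(theta)
            c[:, 3] = prof * np.sin(theta)
            return c
        return cmd

    if protocol == "differentiator-drive":
        bumps = p.get("bumps", [(0.2, 0.2, 1.0), (0.6, 0.3, -0.8)])
        weights = np.asarray(p.get("weights", np.ones(J)), float)

        def base(t: np.ndarray) -> np.ndarray:
            out = np.zeros_like(t)
            for (b0, w, h) in bumps:
                inside = (t >= b0) & (t < b0 + w)
                out += h * 0.5 * (1 - np.cos(2 * np.pi * (t - b0) / w)) * inside
            return out

        def cmd(t: np.ndarray) -> np.ndarray:
            t = np.atleast_1d(t)
            return base(t)[:, None] * weights[None, :]
        return cmd

    if protocol == "oscillator-kick":
        amp = p.get("amplitude", 50.0)
        t_kick = p.get("t_kick", 0.1)
        width = p.get("width", 0.05)
        comp = int(p.get("component", J - 1))

        def cmd(t: np.ndarray) -> np.ndarray:
            t = np.atleast_1d(t)
            c = np.zeros((t.shape[0], J))
            c[:, comp] = amp * ((t >= t_kick) & (t < t_kick + width))
            return c
        return cmd

    if protocol == "white-noise-filtered":
        mean = p.get("mean", 0.0)
        sd = p.get("sd", 1.0)
        tau = p.get("tau", 0.1)
        weights = np.asarray(p.get("weights", np.ones(J)), float)
        rng = np.random.default_rng(seed)
        state = {"y": float(p.get("y0", mean)), "t": 0.0}

        def cmd(t: np.ndarray) -> np.ndarray:
            t = np.atleast_1d(t)
            if t.shape[0] < 2:
                return np.full((t.shape[0], J), state["y"]) * weights[None, :]
            dt_loc = t[1] - t[0]
            draws = mean + sd * rng.standard_normal(t.shape[0])
            y = np.empty(t.shape[0])
            yv = state["y"]
            a = dt_loc / tau
            for i in range(t.shape[0]):
                yv += a * (draws[i] - yv)
                y[i] = yv
            state["y"] = yv
            return y[:, None] * weights[None, :]
        return cmd

    raise ConfigurationError(f"unknown command protocol {protocol!r}")


# --------------------------------------------------------------------------
# voltage-identity verification
# --------------------------------------------------------------------------

def verify_voltage_identity(result: SimResult, net: NetworkParams) -> float:
    """Maximum deviation between the ODE-integrated voltage and its
    definition as a penalised prediction error.

    The derived LIF dynamics only reproduce
    ``V_i = Gamma_i . (x - x_hat) - mu r_i`` up to terms that are O(1/N)
    smaller than the rest (plus Euler error); the returned number, the max
    over neurons and recorded samples of the discrepancy (rescaling
    adjusted, i.e. in raw cost units), quantifies exactly what was
    neglected.  Requires dense traces recorded with ``sigma_V = 0``.
    """
    if result.traces is None:
        raise ConfigurationError("verify_voltage_identity needs recorded traces")
    if np.any(net.sigma_V_vec() != 0):
        raise ConfigurationError("identity check requires a noiseless run")
    tr = result.traces
    G = net.Gamma
    err = G.T @ (tr["x"].T - tr["xhat"].T)      # (N, n_samples)
    V_def = err - net.costs.mu * tr["r"].T
    V_raw = (tr["V"].T - net.v_rest[:, None]) / net.gain[:, None]
    return float(np.max(np.abs(V_raw - V_def)))
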