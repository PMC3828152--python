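"""Poisson-rate baselines, analytic rates, Cramér–Rao bound, N-scaling.

The point of these references is the central efficiency claim: a
predictive-coding spiking network tracks its variable with an error set by
the *kernel* size (standard deviation ~ 1/N at fixed single-neuron rates),
whereas any population of independent Poisson units with the same rates is
limited by shot noise (~ 1/sqrt(N), the Cramér–Rao rate for Poisson
spiking).  The matched Poisson network makes the comparison concrete: same
instantaneous firing rates, same slow/decoder dynamics, fast connections
removed and the greedy threshold rule replaced by stochastic thinning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .model_spec import (ConfigurationError, CostSpec, DecoderSpec,
                         KernelEnsembleConfig, LinearSystemSpec,
                         build_connectivity, make_kernels, scale_network)
from .simulate import SimResult, run

__all__ = ["ScalingResult", "analytic_homogeneous_rate",
           "matched_poisson_network", "cramer_rao_poisson",
           "scaling_experiment"]


@dataclass
class ScalingResult:
    sizes: np.ndarray
    net_err: np.ndarray          # (n_sizes, reps) decoding errors
    poisson_err: np.ndarray
    net_slope: float
    net_slope_ci: tuple
    poisson_slope: float
    poisson_slope_ci: tuple


def analytic_homogeneous_rate(x: float, N: int, kernel_norm: float,
                              lambda_d: float, leak: float = 0.0) -> float:
    """Per-neuron rate (Hz) of the homogeneous signed-kernel network at a
    constant represented value ``x``.

    The population must replenish the decoder leak: pooled rate
    ``(lambda_d - leak) |x| / kernel_norm``, shared equally by the N/2
    neurons whose kernel sign matches ``sign(x)``; the opposite half is
    silent.  (``leak`` is the target system's own decay rate, 0 for the
    perfect integrator.)
    """
    pop = (lambda_d - leak) * abs(x) / kernel_norm
    return pop / (N / 2)


def matched_poisson_network(decoder: DecoderSpec, system: LinearSystemSpec,
                            duration: float, dt: float = 1e-4,
                            seed: int = 0,
                            command: Optional[Callable] = None,
                            x0: Optional[np.ndarray] = None,
                            max_chunk: int = 20_000) -> SimResult:
    """Poisson spike-generator control for a homogeneous scalar network.

    The deterministic rate dynamics (slow connections + decoder in the
    mean) integrate the target ODE exactly; each neuron then draws spikes
    per step as Bernoulli(rate*dt) at the instantaneous rate needed to
    track that trajectory:

        demand(t) = (A y + c(t) + lambda_d y) / gamma   (signed, pooled)

    split across the N/2 neurons of the matching sign.  At constant y this
    reduces to the analytic homogeneous rate.  The decoded estimate
    (returned in ``traces['xhat']``) degrades relative to the spiking
    network because nothing cancels the Poisson shot noise.
    """
    G = decoder.Gamma
    if decoder.J != 1:
        raise ConfigurationError("matched Poisson baseline is defined for "
                                 "scalar homogeneous ensembles")
    gamma = np.abs(G[0])
    signs = np.sign(G[0])
    if not np.allclose(gamma, gamma[0]):
        raise ConfigurationError("homogeneous-compatible kernels required")
    g = float(gamma[0])
    N = decoder.N
    n_half = (signs > 0).sum()
    lam_d = decoder.lambda_d
    a = float(system.A[0, 0])
    cmd = command if command is not None else system.command_at
    n_steps = int(round(duration / dt))
    rng = np.random.default_rng(seed)

    from scipy.signal import lfilter

    y = float(system.x0[0] if x0 is None else np.asarray(x0).ravel()[0])
    spikes_t = []
    spikes_i = []
    tr_x = np.empty(n_steps)
    tr_xhat = np.empty(n_steps)
    decay = 1.0 - lam_d * dt
    zi = np.zeros(1)
    pos = 0
    warned = False
    while pos < n_steps:
        S = min(max_chunk, n_steps - pos)
        t_grid = np.arange(pos, pos + S) * dt
        c = np.asarray(cmd(t_grid))[:, 0]
        # deterministic rate dynamics (scalar Euler)
        ys = np.empty(S)
        demand = np.empty(S)
        for s in range(S):
            demand[s] = (a * y + c[s] + lam_d * y) / g
            y += dt * (a * y + c[s])
            ys[s] = y
        rate = np.abs(demand) / n_half
        if np.any(rate * dt > 0.1) and not warned:
            warnings.warn("rate*dt exceeds 0.1: Bernoulli thinning is a poor "
                          "Poisson approximation at this dt", stacklevel=2)
            warned = True
        active = (signs[None, :] * demand[:, None]) > 0
        fired = active & (rng.random((S, N)) < (rate * dt)[:, None])
        ss, ii = np.nonzero(fired)
        spikes_t.append((pos + ss + 1) * dt)
        spikes_i.append(ii)
        jumps = fired @ G[0]                    # pooled readout kick per step
        xh, zi = lfilter([1.0], [1.0, -decay], jumps, zi=zi)
        tr_x[pos:pos + S] = ys
        tr_xhat[pos:pos + S] = xh
        pos += S
    res = SimResult(
        spike_times=np.concatenate(spikes_t) if spikes_t else np.empty(0),
        spike_neurons=(np.concatenate(spikes_i).astype(int)
                       if spikes_i else np.empty(0, int)),
        dt=dt, duration=duration, seed=seed,
        meta={"N": N, "J": 1, "baseline": "matched-poisson"},
    )
    res.traces = {"time": (np.arange(n_steps) + 1) * dt,
                  "x": tr_x[:, None], "xhat": tr_xhat[:, None]}
    return res


def cramer_rao_poisson(tuning: Callable[[float], np.ndarray], x: float,
                       window_T: float, eps: float = 1e-4) -> float:
    """Cramér–Rao variance lower bound for estimating ``x`` from the spike
    counts of independent Poisson neurons observed for ``window_T`` seconds.

    ``tuning(x)`` returns the per-neuron rates f_i(x); the bound is
    ``1 / (T * sum_i f_i'(x)^2 / f_i(x))`` with derivatives by central
    difference.  Returns ``inf`` when no neuron's rate varies with x.
    """
    if window_T <= 0:
        raise ConfigurationError("window must be positive")
    f = np.asarray(tuning(x), float)
    fp = (np.asarray(tuning(x + eps), float)
          - np.asarray(tuning(x - eps), float)) / (2 * eps)
    mask = f > 0
    info = window_T * float(np.sum(fp[mask] ** 2 / f[mask]))
    return np.inf if info == 0 else 1.0 / info


def _ols_slope_ci(logN: np.ndarray, logerr: np.ndarray, reps_err: np.ndarray,
                  n_boot: int = 500, seed: int = 0) -> tuple[float, tuple]:
    slope = np.polyfit(logN, logerr, 1)[0]
    rng = np.random.default_rng(seed)
    boots = []
    n_sizes, reps = reps_err.shape
    for _ in range(n_boot):
        m = np.log(np.array([
            reps_err[i, rng.integers(0, reps, reps)].mean()
            for i in range(n_sizes)]))
        boots.append(np.polyfit(logN, m, 1)[0])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(slope), (float(lo), float(hi))


def scaling_experiment(sizes: Sequence[int] = (26, 50, 100, 200, 400),
                       reps: int = 10,
                       base_cfg: Optional[KernelEnsembleConfig] = None,
                       base_costs: CostSpec = CostSpec(nu=5e-5, mu=3e-5),
                       base_sigma_V: float = 0.002 * (0.02**2 + 3e-5),
                       lambda_d: float = 10.0,
                       x_const: float = 2.0,
                       duration: float = 1.5,
                       settle: float = 0.5,
                       dt: float = 1e-4,
                       seed: int = 0) -> ScalingResult:
    """Decoding error vs network size for the spiking network and the
    matched Poisson baseline.

    For each size, the reference ensemble (defaults: the homogeneous
    integrator working point, N=400 with kernel 0.02) is rescaled so that
    single-neuron
    rates stay fixed (kernels ~ 1/N, costs and noise ~ 1/N^2), the network
    holds a constant value ``x_const`` (warm-started rates, no input), and
    the RMSE of the readout against the constant reference is measured
    after ``settle``.  Log-log OLS slopes with bootstrap CIs quantify the
    ~1/N (network) vs ~1/sqrt(N) (Poisson) precision laws.
    """
    sizes = sorted(int(s) for s in sizes)
    if len(sizes) < 3:
        raise ConfigurationError("need >= 3 sizes for a slope fit")
    if reps < 2:
        raise ConfigurationError("need >= 2 repetitions")
    if base_cfg is None:
        base_cfg = KernelEnsembleConfig("homogeneous-signed", N=400, J=1,
                                        norm=0.02)
    sysm = LinearSystemSpec(A=np.zeros((1, 1)), x0=[x_const])
    net_err = np.empty((len(sizes), reps))
    poi_err = np.empty((len(sizes), reps))
    from .readout import estimation_error
    for si, N in enumerate(sizes):
        cfg_N, costs_N, sig_N = scale_network(base_cfg, base_costs,
                                              base_sigma_V, N)
        dec = DecoderSpec(make_kernels(cfg_N), lambda_d=lambda_d)
        net = build_connectivity(dec, sysm, costs_N, sigma_V=sig_N)
        stride = 10
        for rep in range(reps):
            s = seed + 1000 * si + rep
            res = run(net, sysm, duration=duration, dt=dt, seed=s,
                      warm_start_rates=True, record_traces=True,
                      trace_stride=stride)
            tr = res.traces
            net_err[si, rep] = estimation_error(
                np.full_like(tr["xhat"], x_const), tr["xhat"],
                time=tr["time"], window=(settle, duration))
            resp = matched_poisson_network(dec, sysm, duration=duration,
                                           dt=dt, seed=s + 500_000)
            trp = resp.traces
            poi_err[si, rep] = estimation_error(
                np.full_like(trp["xhat"], x_const), trp["xhat"],
                time=trp["time"], window=(settle, duration))
    logN = np.log(np.asarray(sizes, float))
    ns, nci = _ols_slope_ci(logN, np.log(net_err.mean(axis=1)), net_err,
                            seed=seed)
    ps, pci = _ols_slope_ci(logN, np.log(poi_err.mean(axis=1)), poi_err,
                            seed=seed + 1)
    return ScalingResult(np.asarray(sizes), net_err, poi_err,
                         ns, nci, ps, pci)
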