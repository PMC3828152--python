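"""Decoding spike rasters into dynamical-variable estimates.

Decoding is the fixed linear readout the networks are built around: each
spike of neuron ``i`` contributes its kernel ``Gamma_i`` times a decaying
exponential ``exp(-lambda_d (t - t_spike))`` — a simplified postsynaptic
potential.  Because the readout is linear in the raster, subpopulations can
be decoded and compared, including the trial-shuffled construction in which
every neuron's train is taken from a *different* repeat of the same
stimulus: that destroys the spike-by-spike coordination and reduces the
population to what independent Poisson processes with the same rates could
convey.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model_spec import ConfigurationError

__all__ = ["DecodeResult", "decode", "estimation_error", "subsample_decode",
           "poisson_shuffled_error_prediction"]


@dataclass
class DecodeResult:
    """Error-vs-population-size curve from :func:`subsample_decode`."""

    K: np.ndarray             # numbers of recorded neurons
    rmse: np.ndarray          # decoding error per K
    mode: str                 # 'simultaneous' | 'trial-shuffled'
    baseline: Optional[np.ndarray] = None   # analytic Poisson prediction


def decode(spike_times: np.ndarray, spike_neurons: np.ndarray,
           Gamma: np.ndarray, lambda_d: float,
           grid: np.ndarray) -> np.ndarray:
    """Decode a raster onto a time grid: ``x_hat(t) = sum Gamma_i K(t-t_s)``.

    Exact (event-based) evaluation of the exponential readout at the grid
    points; linear in the raster.  Returns shape (len(grid), J).
    """
    Gamma = np.atleast_2d(np.asarray(Gamma, float))
    grid = np.asarray(grid, float)
    if grid.ndim != 1 or (grid.size > 1 and np.any(np.diff(grid) <= 0)):
        raise ConfigurationError("grid must be strictly increasing")
    J, N = Gamma.shape
    spike_neurons = np.asarray(spike_neurons, int)
    if spike_neurons.size and (spike_neurons.max() >= N or spike_neurons.min() < 0):
        raise ConfigurationError("spike neuron id outside kernel matrix")
    order = np.argsort(spike_times, kind="stable")
    ts = np.asarray(spike_times, float)[order]
    ns = spike_neurons[order]
    out = np.zeros((grid.size, J))
    if ts.size == 0:
        return out
    # walk the grid, carrying the decayed state and folding in new spikes
    state = np.zeros(J)
    t_prev = -np.inf
    si = 0
    for gi, t in enumerate(grid):
        if np.isfinite(t_prev):
            state = state * np.exp(-lambda_d * (t - t_prev))
        hi = np.searchsorted(ts, t, side="right")
        if hi > si:
            w = np.exp(-lambda_d * (t - ts[si:hi]))
            state = state + (Gamma[:, ns[si:hi]] * w[None, :]).sum(axis=1)
            si = hi
        out[gi] = state
        t_prev = t
    return out


def estimation_error(x: np.ndarray, xhat: np.ndarray,
                     time: Optional[np.ndarray] = None,
                     window: Optional[tuple[float, float]] = None) -> float:
    """RMSE between trajectories: root of the time-averaged squared
    Euclidean distance, optionally restricted to ``window`` (seconds)."""
    x = np.atleast_2d(np.asarray(x, float))
    xhat = np.atleast_2d(np.asarray(xhat, float))
    if x.shape[0] == 1 and x.shape[1] > 1 and xhat.shape[0] > 1:
        x = x.T
    if xhat.shape[0] == 1 and xhat.shape[1] > 1 and x.shape[0] > 1:
        xhat = xhat.T
    if x.shape != xhat.shape:
        raise ConfigurationError("traces must be aligned")
    sel = slice(None)
    if window is not None:
        if time is None:
            raise ConfigurationError("window requires a time vector")
        sel = (time >= window[0]) & (time < window[1])
        if not np.any(sel):
            raise ConfigurationError("empty error window")
    d = x[sel] - xhat[sel]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=-1))))


def _refit_weights(sub_traces: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares readout weights for a recorded subset.

    sub_traces: (n_samples, K) filtered rates; target: (n_samples, J).
    """
    W, *_ = np.linalg.lstsq(sub_traces, target, rcond=None)
    return W  # (K, J)


def subsample_decode(results: Sequence, Gamma: np.ndarray, lambda_d: float,
                     x_ref: np.ndarray, grid: np.ndarray,
                     K_values: Sequence[int], mode: str = "simultaneous",
                     refit: bool = True,
                     refit_window: Optional[tuple[float, float]] = None,
                     eval_window: Optional[tuple[float, float]] = None,
                     seed: int = 0) -> DecodeResult:
    """Decoding error as a function of the number of recorded neurons K.

    ``simultaneous``: the K neurons come from the first trial.
    ``trial-shuffled``: neuron ``k`` of the subset is read from trial ``k``
    (requires at least K trials), mimicking sequential single-unit
    recordings combined post hoc.

    For each subset, readout weights are re-fitted by least squares of the
    subset's filtered rates against the reference trajectory on
    ``refit_window`` (the charitable subset decoder; ``refit=False`` uses
    the raw kernel columns instead).  Errors are evaluated on
    ``eval_window``.
    """
    if mode not in ("simultaneous", "trial-shuffled"):
        raise ConfigurationError(f"unknown subsample mode {mode!r}")
    Gamma = np.atleast_2d(Gamma)
    J, N = Gamma.shape
    rng = np.random.default_rng(seed)
    K_values = [int(k) for k in K_values]
    if max(K_values) > N:
        raise ConfigurationError("K exceeds population size")
    if mode == "trial-shuffled" and len(results) < max(K_values):
        raise ConfigurationError("need at least K trials for shuffled decoding")

    # per-neuron filtered-rate traces, per trial (computed lazily per neuron)
    def neuron_trace(res, i):
        t = res.spike_train(i)
        if t.size == 0:
            return np.zeros(grid.size)
        out = np.zeros(grid.size)
        si = 0
        state = 0.0
        tprev = grid[0]
        idx = np.searchsorted(t, grid, side="right")
        prev = 0
        for gi, tg in enumerate(grid):
            state *= np.exp(-lambda_d * (tg - tprev))
            if idx[gi] > prev:
                state += np.exp(-lambda_d * (tg - t[prev:idx[gi]])).sum()
                prev = idx[gi]
            out[gi] = state
            tprev = tg
        return out

    errs = []
    x_ref = np.atleast_2d(x_ref)
    if x_ref.shape[0] == J:
        x_ref = x_ref.T
    fit_sel = np.ones(grid.size, bool) if refit_window is None else (
        (grid >= refit_window[0]) & (grid < refit_window[1]))
    for K in K_values:
        if K == 0:
            errs.append(estimation_error(x_ref, np.zeros_like(x_ref),
                                         time=grid, window=eval_window))
            continue
        subset = rng.choice(N, size=K, replace=False)
        traces = np.column_stack([
            neuron_trace(results[0] if mode == "simultaneous" else results[k],
                         subset[k])
            for k in range(K)])
        if refit:
            W = _refit_weights(traces[fit_sel], x_ref[fit_sel])
        else:
            W = Gamma[:, subset].T
        xh = traces @ W
        errs.append(estimation_error(x_ref, xh, time=grid, window=eval_window))
    return DecodeResult(K=np.asarray(K_values), rmse=np.asarray(errs), mode=mode)


def poisson_shuffled_error_prediction(K: np.ndarray, N: int, rate: float,
                                      kernel_norm: float, lambda_d: float
                                      ) -> np.ndarray:
    """Analytic decoding error for K independent Poisson neurons.

    For a homogeneous scalar representation in which the K recorded neurons
    (rate ``rate`` each, kernel ``kernel_norm``) are statistically
    independent, an unbiased subset readout rescales the weights by N/K; the
    leaky-integrated Poisson shot noise then has standard deviation

        sd(K) = (N / sqrt(K)) * kernel_norm * sqrt(rate / (2 lambda_d)) .

    This is the reference curve that trial-shuffled network decoding follows
    and the simultaneously recorded network beats.
    """
    K = np.asarray(K, float)
    with np.errstate(divide="ignore"):
        return N * kernel_norm * np.sqrt(rate / (2 * lambda_d)) / np.sqrt(K)
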