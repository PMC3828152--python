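"""Spike-train statistics and effective-connectivity (GLM) estimation.

Predictive-coding networks fire irregularly at the single-cell level while
the population output is quasi-deterministic, so the analyses here come in
two flavours: single-unit variability measures that look Poisson (ISI
coefficient of variation, CV2, Fano factors, flat cross-correlograms at
coarse bins, vanishing noise correlations) and population-level structure
that reveals the coordination (the ~1 ms "integration cycle" comb in finely
binned correlograms, tight excitation/inhibition current balance, and the
fast-inhibition / slow-excitation lateral filters recovered by a Poisson
GLM).

Naming note: both "CV" and "CV2" circulate in this literature.  Here ``cv``
is the classic sd/mean of the inter-spike intervals and ``cv2`` is the
local pairwise measure  mean over consecutive interval pairs of
``2 |I_{k+1} - I_k| / (I_{k+1} + I_k)``, which is robust to slow rate
drift.  Population-level numbers quoted by the analyses are the per-neuron
values averaged over the population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .model_spec import ConfigurationError, NetworkParams

__all__ = [
    "StatsReport", "GLMFit", "TuningCurve",
    "isi_stats", "fano", "correlogram", "noise_correlations",
    "tuning_curve_integrator", "ei_currents", "population_period",
    "jitter_spikes", "fit_glm", "simulate_glm",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class StatsReport:
    """Per-neuron and population spike statistics of one condition."""

    cv: np.ndarray
    cv2: np.ndarray
    fano: Optional[np.ndarray] = None
    isi_hist: Optional[dict] = None
    noise_corr: Optional[np.ndarray] = None
    mean_abs_noise_corr: Optional[float] = None
    mean_noise_corr: Optional[float] = None
    period_ms: Optional[float] = None
    extras: dict = field(default_factory=dict)

    def population_cv(self) -> float:
        return float(np.nanmean(self.cv))

    def population_cv2(self) -> float:
        return float(np.nanmean(self.cv2))


@dataclass
class GLMFit:
    """Estimated GLM: per-neuron bias, feedforward kernel and pairwise
    lateral filters, all discretised on ``n_bins`` bins of ``bin_s``."""

    bias: np.ndarray                 # (n_neurons,)
    feedforward: np.ndarray          # (n_neurons, n_bins)
    lateral: np.ndarray              # (n_neurons, n_neurons, n_bins)
    bin_s: float
    loglik: float
    converged: bool
    n_iter: int


@dataclass
class TuningCurve:
    grid: np.ndarray                 # stimulus values (or condition tuples)
    response: np.ndarray             # (n_grid, n_neurons) mean response
    sem: np.ndarray
    protocol: str


# --------------------------------------------------------------------------
# single-train statistics
# --------------------------------------------------------------------------

def isi_stats(train: np.ndarray, n_hist_bins: int = 30) -> dict:
    """CV, CV2 and a log-spaced ISI histogram of one spike train.

    Returns NaN markers (not zeros) when the train is too short: CV needs at
    least two intervals, CV2 at least two consecutive interval pairs.
    """
    t = np.sort(np.asarray(train, float))
    isi = np.diff(t)
    out = {"n_spikes": t.size, "cv": np.nan, "cv2": np.nan,
           "isi_mean": np.nan, "hist": None, "bin_edges": None}
    if isi.size >= 2:
        out["cv"] = float(np.std(isi) / np.mean(isi))
        out["isi_mean"] = float(np.mean(isi))
        pair = 2.0 * np.abs(isi[1:] - isi[:-1]) / (isi[1:] + isi[:-1])
        out["cv2"] = float(np.mean(pair))
    if isi.size >= 1:
        lo = max(isi.min(), 1e-5)
        edges = np.geomspace(lo, isi.max() + 1e-12, n_hist_bins + 1)
        out["hist"], out["bin_edges"] = np.histogram(isi, edges)
    return out


def fano(counts: np.ndarray) -> np.ndarray:
    """Fano factors from a (n_trials, n_neurons) spike-count matrix.

    variance/mean of the counts across trials, NaN where the mean count is
    zero (undefined, not zero).
    """
    counts = np.asarray(counts, float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ConfigurationError("need a (trials >= 2, neurons) count matrix")
    m = counts.mean(axis=0)
    v = counts.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(m > 0, v / m, np.nan)
    return f


def correlogram(train_a: np.ndarray, train_b: np.ndarray,
                bin_s: float = 5e-3, max_lag_s: float = 0.1,
                exclude_zero: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Spike-probability cross-correlogram.

    For each spike of the reference train ``train_a``, counts spikes of
    ``train_b`` at signed lags, normalised by the number of reference
    spikes: the probability of a ``b`` spike in each lag bin given an ``a``
    spike.  ``exclude_zero`` removes the self-pair at lag 0 for
    autocorrelograms.  Returns (lag bin centres, probability per bin).
    """
    if bin_s <= 0:
        raise ConfigurationError("bin must be > 0")
    a = np.sort(np.asarray(train_a, float))
    b = np.sort(np.asarray(train_b, float))
    n_bins = 2 * int(np.ceil(max_lag_s / bin_s))
    edges = (np.arange(n_bins + 1) - n_bins / 2) * bin_s
    centers = 0.5 * (edges[:-1] + edges[1:])
    if a.size == 0 or b.size == 0:
        warnings.warn("empty spike train: flat zero correlogram", stacklevel=2)
        return centers, np.zeros(n_bins)
    counts = np.zeros(n_bins)
    lo = np.searchsorted(b, a + edges[0])
    hi = np.searchsorted(b, a + edges[-1])
    for i in range(a.size):
        lags = b[lo[i]:hi[i]] - a[i]
        if exclude_zero:
            lags = lags[lags != 0.0]
        if lags.size:
            idx = np.floor((lags - edges[0]) / bin_s).astype(int)
            idx = idx[(idx >= 0) & (idx < n_bins)]
            np.add.at(counts, idx, 1)
    return centers, counts / a.size


def noise_correlations(counts: np.ndarray, min_trials: int = 100) -> dict:
    """Trial-to-trial spike-count correlations at a fixed stimulus.

    ``counts``: (n_trials, n_neurons) spike counts in the analysis window,
    one row per repeat of the identical stimulus.  Pairs whose counts are
    constant across trials are skipped (correlation undefined).

    Returns the pairwise Pearson matrix together with three summaries of the
    off-diagonal entries:

    * ``mean_corr`` — the pair-averaged signed correlation.  Its magnitude
      ``abs_mean_corr`` is the estimator to compare against a small ceiling:
      averaging first pools ~N^2/2 nearly independent estimates, so the
      sampling noise of the summary is ~ (1/sqrt(trials)) / N, far below the
      per-pair noise.
    * ``mean_abs_corr`` — average of |rho| per pair.  With finitely many
      trials this is dominated by the per-pair sampling floor
      ``sqrt(2/pi) / sqrt(trials - 1)`` (reported as ``null_floor``) even
      for perfectly uncorrelated neurons; it is provided for calibration
      against an independent-Poisson surrogate, not as the headline number.
    """
    counts = np.asarray(counts, float)
    n_trials, n_neurons = counts.shape
    if n_trials < min_trials:
        raise ConfigurationError(f"need >= {min_trials} trials, got {n_trials}")
    sd = counts.std(axis=0)
    keep = np.flatnonzero(sd > 0)
    C = np.full((n_neurons, n_neurons), np.nan)
    if keep.size >= 2:
        C[np.ix_(keep, keep)] = np.corrcoef(counts[:, keep].T)
    np.fill_diagonal(C, 1.0)
    iu = np.triu_indices(n_neurons, k=1)
    off = C[iu]
    off = off[np.isfinite(off)]
    return {
        "matrix": C,
        "mean_corr": float(np.mean(off)) if off.size else np.nan,
        "abs_mean_corr": float(abs(np.mean(off))) if off.size else np.nan,
        "mean_abs_corr": float(np.mean(np.abs(off))) if off.size else np.nan,
        "null_floor": float(np.sqrt(2 / np.pi) / np.sqrt(n_trials - 1)),
        "n_pairs": int(off.size),
    }


# --------------------------------------------------------------------------
# population-level structure
# --------------------------------------------------------------------------

def population_period(spike_times: np.ndarray,
                      window: Optional[tuple[float, float]] = None,
                      bin_s: float = 1e-4, max_lag_s: float = 5e-3,
                      min_lag_s: float = 2e-4) -> dict:
    """Dominant period (ms) of the pooled-population spike train.

    Pools all spikes, computes the fine-binned autocorrelogram over a
    stationary epoch and returns the lag of its first dominant peak beyond
    ``min_lag_s`` (the fast-connection dead time right after a spike),
    together with the reciprocal of the pooled rate — in the homogeneous
    "integration cycle" regime the two coincide.
    """
    t = np.sort(np.asarray(spike_times, float))
    if window is not None:
        t = t[(t >= window[0]) & (t < window[1])]
        span = window[1] - window[0]
    else:
        span = t[-1] - t[0] if t.size > 1 else 0.0
    if t.size < 50:
        raise ConfigurationError("too few spikes for a period estimate")
    lags, prob = correlogram(t, t, bin_s=bin_s, max_lag_s=max_lag_s,
                             exclude_zero=True)
    pos = lags > min_lag_s
    # 3-bin smoothing collects the mass of a comb line that straddles a bin
    # edge, then the *first* dominant local maximum is the fundamental (the
    # raw argmax often lands on a harmonic whose line happens to fall mid-bin)
    p = prob[pos]
    lg = lags[pos]
    sm = np.convolve(p, np.ones(3), mode="same")
    peak_lag = float(lg[np.argmax(sm)])
    thresh = 0.6 * sm.max()
    for i in range(1, sm.size - 1):
        if sm[i] >= thresh and sm[i] >= sm[i - 1] and sm[i] >= sm[i + 1]:
            peak_lag = float(lg[i])
            break
    pooled_rate = t.size / span
    return {
        "period_ms": peak_lag * 1e3,
        "pooled_rate_hz": pooled_rate,
        "rate_reciprocal_ms": 1e3 / pooled_rate,
        "lags_ms": lags * 1e3,
        "autocorr": prob,
    }


def jitter_spikes(spike_times: np.ndarray, sd_s: float = 1e-3,
                  seed: int = 0) -> np.ndarray:
    """Add Gaussian timing jitter to each spike (destroys the millisecond
    population comb without affecting slow response properties)."""
    rng = np.random.default_rng(seed)
    return np.sort(spike_times + sd_s * rng.standard_normal(len(spike_times)))


def ei_currents(result, net: NetworkParams, system, neuron: int,
                smoothing_s: float = 2e-3,
                include_self_reset: bool = False) -> dict:
    """Excitatory / inhibitory decomposition of one neuron's total input.

    Reconstructs, on the trace grid, every synaptic contribution to the
    neuron — feedforward ``F_i . c(t)``, fast per-spike kicks
    ``Omega_f[i, j]`` (current impulses spread over one step) and slow input
    ``Omega_s[i, :] r(t)`` — splits positive (excitatory) from negative
    (inhibitory) terms *before* summation, and smooths both with an
    exponential window (default 2 ms).  The neuron's own reset kick is a
    reset, not a synaptic input, and is excluded unless requested.
    E + I equals the smoothed net input by construction.

    Works best with ``trace_stride=1`` (needs ``r`` on the grid and spike
    times resolved to steps).  Stochastic commands must be rebuilt with the
    run's seed for an exact feedforward reconstruction.
    """
    if result.traces is None:
        raise ConfigurationError("ei_currents needs recorded traces")
    if not 0 <= neuron < net.N:
        raise ConfigurationError("invalid neuron id")
    tr = result.traces
    time = tr["time"]
    dt = float(np.median(np.diff(time)))
    G = net.Gamma
    gi = G[:, neuron]
    c = system.command_at(time - dt)            # command at step start
    ff = c @ gi                                 # feedforward current
    slow_w = (system.A + net.lambda_d * np.eye(net.J)).T @ gi
    slow = tr["xhat"] @ slow_w                  # Omega_s r through readout
    # fast kicks: spikes at step -> impulse kick/dt at that sample
    fast_pos = np.zeros(time.size)
    fast_neg = np.zeros(time.size)
    idx = np.clip(np.round(result.spike_times / dt).astype(int) - 1,
                  0, time.size - 1)
    for s_idx, j in zip(idx, result.spike_neurons):
        if j == neuron and not include_self_reset:
            continue
        w = net.Omega_f[neuron, j] / dt
        if w >= 0:
            fast_pos[s_idx] += w
        else:
            fast_neg[s_idx] += w
    E = np.clip(ff, 0, None) + np.clip(slow, 0, None) + fast_pos
    I = np.clip(ff, None, 0) + np.clip(slow, None, 0) + fast_neg

    from scipy.signal import lfilter
    a = dt / smoothing_s
    smooth = lambda y: lfilter([a], [1, -(1 - a)], y)
    return {"time": time, "E": smooth(E), "I": smooth(I),
            "net": smooth(E + I)}


def population_rate(spike_times: np.ndarray, t_grid: np.ndarray,
                    tau_s: float = 0.1) -> np.ndarray:
    """Exponential-window estimate of the pooled firing rate on a grid."""
    out = np.zeros(t_grid.size)
    ts = np.sort(spike_times)
    si = 0
    state = 0.0
    tprev = t_grid[0]
    for gi, tg in enumerate(t_grid):
        state *= np.exp(-(tg - tprev) / tau_s)
        hi = np.searchsorted(ts, tg, side="right")
        if hi > si:
            state += np.exp(-(tg - ts[si:hi]) / tau_s).sum()
            si = hi
        out[gi] = state / tau_s
        tprev = tg
    return out


# --------------------------------------------------------------------------
# tuning curves
# --------------------------------------------------------------------------

def tuning_curve_integrator(run_trial: Callable[[float, int], np.ndarray],
                            grid: Sequence[float], n_trials: int = 20,
                            protocol: str = "integrator-sustained"
                            ) -> TuningCurve:
    """Mean sustained response per stimulus level.

    ``run_trial(stimulus, seed)`` must return the per-neuron spike count (or
    rate) for one presentation; this helper loops levels x trials and
    aggregates.  For the integrator protocol (brief input, then measure the
    delay epoch) the curves are rectified-linear in the stimulus.
    """
    grid = np.asarray(list(grid), float)
    if grid.size == 0:
        raise ConfigurationError("empty stimulus grid")
    resp = []
    sems = []
    for gi, g in enumerate(grid):
        trials = np.array([run_trial(float(g), 10_000 * gi + s)
                           for s in range(n_trials)])
        resp.append(trials.mean(axis=0))
        sems.append(trials.std(axis=0, ddof=1) / np.sqrt(n_trials)
                    if n_trials > 1 else np.zeros(trials.shape[1]))
    return TuningCurve(grid=grid, response=np.array(resp),
                       sem=np.array(sems), protocol=protocol)


# --------------------------------------------------------------------------
# GLM effective connectivity
# --------------------------------------------------------------------------

def _lagged_design(signal: np.ndarray, n_bins: int) -> np.ndarray:
    """(T, n_bins) matrix whose column k is the signal delayed by k+0 bins.

    Column 0 is the same-bin regressor for the input drive; for spike
    regressors the caller passes the train shifted by one bin so that
    filters are strictly causal.
    """
    T = signal.shape[0]
    X = np.zeros((T, n_bins))
    for k in range(n_bins):
        X[k:, k] = signal[:T - k]
    return X


def simulate_glm(bias: np.ndarray, feedforward: np.ndarray,
                 lateral: np.ndarray, drive: np.ndarray, bin_s: float,
                 seed: int = 0) -> np.ndarray:
    """Sample spike counts from the GLM itself (ground truth for recovery
    tests): ``rate_i(t) = exp(bias_i + (ff_i * drive)(t) + sum_j (w_ij * n_j)(t))``
    with strictly causal lateral coupling.  Returns (T, n_neurons) counts.
    """
    rng = np.random.default_rng(seed)
    n_neurons, n_bins = feedforward.shape
    T = drive.shape[0]
    counts = np.zeros((T, n_neurons), dtype=np.int64)
    # running sums of lateral/ff contributions, updated causally
    ff_drive = np.stack([np.convolve(drive, feedforward[i])[:T]
                         for i in range(n_neurons)])
    lat = np.zeros((T, n_neurons))
    for t in range(T):
        lam = np.exp(bias + ff_drive[:, t] + lat[t])
        counts[t] = rng.poisson(lam * bin_s)
        spk = np.flatnonzero(counts[t])
        for j in spk:
            w = lateral[:, j] * counts[t, j]     # (n_neurons, n_bins)
            hi = min(T, t + 1 + n_bins)
            lat[t + 1:hi] += w[:, :hi - t - 1].T
    return counts


def fit_glm(counts: np.ndarray, drive: np.ndarray, bin_s: float,
            n_bins: int = 500, ridge: float = 0.0,
            max_iter: int = 200) -> GLMFit:
    """Maximum-likelihood Poisson GLM with per-bin filters.

    Each recorded neuron is modelled as an inhomogeneous Poisson process
    whose log-rate is a bias plus the input convolved with a feedforward
    kernel plus every (strictly causal) lateral filter applied to the other
    neurons' spike trains.  Filters are parameterised per time bin (no basis
    functions) and estimated by quasi-Newton ascent of the concave Poisson
    log-likelihood; an optional ridge penalty stabilises short recordings.

    counts : (T, n_neurons) spike counts per bin;  drive : (T,) input.
    """
    from scipy.optimize import minimize

    counts = np.asarray(counts, float)
    drive = np.asarray(drive, float)
    T, n_neurons = counts.shape
    if T <= n_bins * (n_neurons + 1):
        raise ConfigurationError("recording too short for the filter length")
    Xff = _lagged_design(drive, n_bins)
    Xlat = [_lagged_design(np.concatenate([[0.0], counts[:-1, j]]), n_bins)
            for j in range(n_neurons)]
    X = np.column_stack([np.ones(T), Xff] + Xlat)    # (T, 1 + (n+1)*n_bins)

    ff = np.zeros((n_neurons, n_bins))
    lat = np.zeros((n_neurons, n_neurons, n_bins))
    bias = np.zeros(n_neurons)
    total_ll = 0.0
    ok = True
    iters = 0
    for i in range(n_neurons):
        y = counts[:, i]

        def negll(beta):
            eta = X @ beta
            lam = np.exp(np.clip(eta, -30, 30)) * bin_s
            f = float(np.sum(lam) - y @ eta) + 0.5 * ridge * beta[1:] @ beta[1:]
            g = X.T @ (lam - y)
            g[1:] += ridge * beta[1:]
            return f, g

        beta0 = np.zeros(X.shape[1])
        beta0[0] = np.log(max(y.mean(), 1e-4) / bin_s)
        sol = minimize(negll, beta0, jac=True, method="L-BFGS-B",
                       options={"maxiter": max_iter})
        ok &= bool(sol.success)
        iters = max(iters, sol.nit)
        beta = sol.x
        bias[i] = beta[0]
        ff[i] = beta[1:1 + n_bins]
        for j in range(n_neurons):
            lat[i, j] = beta[1 + (j + 1) * n_bins: 1 + (j + 2) * n_bins]
        eta = X @ beta
        lam = np.exp(np.clip(eta, -30, 30)) * bin_s
        total_ll += float(y @ eta - np.sum(lam))
    if not ok:
        warnings.warn("GLM optimisation did not fully converge; filters "
                      "returned with diagnostics", stacklevel=2)
    return GLMFit(bias=bias, feedforward=ff, lateral=lat, bin_s=bin_s,
                  loglik=total_ll, converged=ok, n_iter=iters)
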