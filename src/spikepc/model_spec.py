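"""Target dynamics, decoder and cost specification, and network derivation.

The central object of this package is a recurrent network of leaky
integrate-and-fire (LIF) neurons whose *entire* connectivity is derived from
three ingredients:

1. a linear dynamical system  ``dx/dt = A x + c(t)``  (J variables),
2. a linear spike decoder  ``x_hat = Gamma r`` with leak ``lambda_d``, where
   ``r`` is the exponentially filtered spike train of each neuron, and
3. a spike-cost specification (linear cost ``nu``, quadratic cost ``mu``).

A neuron fires only when firing decreases the squared tracking error
``||x - x_hat||^2`` plus the spike costs.  Working out this greedy rule
yields an ordinary LIF network: the membrane voltage of neuron ``i`` is the
projection of the prediction error onto its decoding kernel (penalised by
its own rate),

    V_i = Gamma_i . (x - x_hat) - mu * r_i ,

the threshold is

    T_i = (||Gamma_i||^2 + nu + mu) / 2 ,

and the recurrent connectivity splits into a *fast* part applied on every
spike and a *slow* part acting on the filtered rates:

    Omega_f = -(Gamma^T Gamma + mu I)          (fast; self-term = reset)
    Omega_s =  Gamma^T (A + lambda_d I) Gamma  (slow; implements A and
                                                compensates the decoder leak)

with feedforward weights ``F = Gamma^T``.  This module houses those
derivations plus the kernel ensembles and the network-size / physical-unit
rescalings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "LinearSystemSpec",
    "DecoderSpec",
    "CostSpec",
    "NetworkParams",
    "KernelEnsembleConfig",
    "build_connectivity",
    "compute_thresholds",
    "rescale_physical",
    "make_kernels",
    "scale_network",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Inconsistent model configuration (dimension mismatch, bad mode...)."""


# --------------------------------------------------------------------------
# specification types
# --------------------------------------------------------------------------

@dataclass
class LinearSystemSpec:
    """Target linear dynamical system ``dx/dt = A x + c(t)``.

    Parameters
    ----------
    A
        State transition matrix, shape (J, J), units 1/s.
    command
        Command/input generator ``c(t)``.  Called with a 1-D array of times
        (seconds), must return an array of shape (len(t), J) in units of
        dx/dt.  ``None`` means no input.
    x0
        Initial state, shape (J,).
    """

    A: np.ndarray
    command: Optional[Callable[[np.ndarray], np.ndarray]] = None
    x0: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        if self.A.shape[0] != self.A.shape[1]:
            raise ConfigurationError(f"A must be square, got {self.A.shape}")
        if self.x0 is None:
            self.x0 = np.zeros(self.A.shape[0])
        self.x0 = np.asarray(self.x0, dtype=float).ravel()
        if self.x0.shape[0] != self.A.shape[0]:
            raise ConfigurationError("x0 length does not match A")

    @property
    def J(self) -> int:
        return self.A.shape[0]

    def command_at(self, t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.command is None:
            return np.zeros((t.shape[0], self.J))
        c = np.asarray(self.command(t), dtype=float)
        if c.ndim == 1:
            c = c[:, None] * np.ones((1, self.J)) if self.J > 1 else c[:, None]
        if c.shape != (t.shape[0], self.J):
            raise ConfigurationError(
                f"command returned shape {c.shape}, expected {(t.shape[0], self.J)}"
            )
        return c


@dataclass
class DecoderSpec:
    """Linear leaky decoder: kernels Gamma (J x N) and leak lambda_d (1/s).

    Column ``i`` of ``Gamma`` is the output kernel of neuron ``i``: the jump
    that one of its spikes causes in the readout, which then decays at rate
    ``lambda_d`` (a simplified postsynaptic potential).
    """

    Gamma: np.ndarray
    lambda_d: float = 10.0

    def __post_init__(self) -> None:
        self.Gamma = np.atleast_2d(np.asarray(self.Gamma, dtype=float))
        if not np.all(np.isfinite(self.Gamma)):
            raise ConfigurationError("Gamma must be finite")
        if self.lambda_d <= 0:
            raise ConfigurationError("lambda_d must be > 0")
        if self.N < 1:
            raise ConfigurationError("need at least one neuron")

    @property
    def J(self) -> int:
        return self.Gamma.shape[0]

    @property
    def N(self) -> int:
        return self.Gamma.shape[1]

    def kernel_norms(self) -> np.ndarray:
        return np.linalg.norm(self.Gamma, axis=0)


@dataclass
class CostSpec:
    """Spike costs: linear ``nu`` (raises thresholds only) and quadratic
    ``mu`` (raises thresholds, deepens resets, penalises high-rate neurons)."""

    nu: float = 0.0
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.nu < 0 or self.mu < 0:
            raise ConfigurationError("costs must be non-negative")


@dataclass
class NetworkParams:
    """Fully derived LIF network.

    ``V`` evolves as ``dV/dt = -lambda_V (V - v_rest) + gain*(F c + Omega_s r)``
    with instantaneous kicks ``gain * Omega_f[:, k]`` whenever neuron ``k``
    spikes, thresholds ``T`` and per-step voltage noise of s.d. ``sigma_V``.
    With the default identity rescaling (``gain = 1``, ``v_rest = 0``) the
    voltage is in raw (kernel-squared) units; :func:`rescale_physical` maps it
    affinely onto a mV range without changing the spike trains.
    """

    F: np.ndarray                 # (N, J) feedforward weights
    Omega_f: np.ndarray           # (N, N) fast connectivity (on spikes)
    Omega_s: np.ndarray           # (N, N) slow connectivity (on rates)
    T: np.ndarray                 # (N,) thresholds
    lambda_V: float               # voltage leak (1/s)
    lambda_d: float               # decoder leak (1/s)
    costs: CostSpec = field(default_factory=CostSpec)
    sigma_V: float | np.ndarray = 0.0   # per-step voltage noise s.d. (raw
                                        # units; scalar or per-neuron vector)
    Gamma: Optional[np.ndarray] = None   # (J, N) decoding kernels
    gain: Optional[np.ndarray] = None    # (N,) per-neuron rescaling a_i
    v_rest: Optional[np.ndarray] = None  # (N,) per-neuron offsets/resting pot.

    def __post_init__(self) -> None:
        N = self.F.shape[0]
        if self.gain is None:
            self.gain = np.ones(N)
        if self.v_rest is None:
            self.v_rest = np.zeros(N)
        for name in ("F", "Omega_f", "Omega_s", "T", "gain", "v_rest"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def N(self) -> int:
        return self.F.shape[0]

    @property
    def J(self) -> int:
        return self.F.shape[1]

    def sigma_V_vec(self) -> np.ndarray:
        """Per-neuron per-step noise s.d. as an (N,) vector."""
        return np.broadcast_to(np.asarray(self.sigma_V, float),
                               (self.N,)).astype(float)

    def reset_potentials(self) -> np.ndarray:
        """Voltage immediately after a spike of the neuron itself.

        The self-term of the fast connectivity pulls the voltage from the
        threshold down by ``gain * (||Gamma_i||^2 + mu)``.
        """
        return self.T + self.gain * np.diag(self.Omega_f)


# --------------------------------------------------------------------------
# derivation
# --------------------------------------------------------------------------

def compute_thresholds(decoder: DecoderSpec, costs: CostSpec) -> np.ndarray:
    """Firing thresholds ``T_i = (||Gamma_i||^2 + nu + mu) / 2``.

    The linear cost ``nu`` only ever enters here: it shifts every threshold
    up by ``nu / 2`` and leaves the connectivity untouched.
    """
    return 0.5 * (np.sum(decoder.Gamma**2, axis=0) + costs.nu + costs.mu)


def build_connectivity(
    decoder: DecoderSpec,
    system: LinearSystemSpec,
    costs: CostSpec,
    lambda_V: Optional[float] = None,
    sigma_V: float | np.ndarray = 0.0,
) -> NetworkParams:
    """Derive the complete LIF network from decoder, dynamics and costs.

    Returns a :class:`NetworkParams` with

    * ``F = Gamma^T`` (feedforward),
    * ``Omega_f = -(Gamma^T Gamma + mu I)`` — fast connections, applied once
      per presynaptic spike; the diagonal is the self-reset,
    * ``Omega_s = Gamma^T (A + lambda_d I) Gamma`` — slow connections acting
      on filtered rates; they realise the target dynamics ``A`` and undo the
      decoder leak,
    * thresholds from :func:`compute_thresholds`.

    ``lambda_V`` defaults to ``lambda_d``: the voltage leak is a biological-
    realism term rather than part of the derivation, and equating the two
    leaks makes the rate-penalty bookkeeping exact (see docs/methods.md).
    """
    if decoder.J != system.J:
        raise ConfigurationError(
            f"decoder represents {decoder.J} variables but system has {system.J}"
        )
    G = decoder.Gamma
    if np.linalg.matrix_rank(G) < decoder.J:
        warnings.warn(
            "Gamma is rank-deficient: some represented dimensions are not "
            "spanned by any kernel and cannot be tracked",
            stacklevel=2,
        )
    Omega_f = -(G.T @ G + costs.mu * np.eye(decoder.N))
    Omega_s = G.T @ (system.A + decoder.lambda_d * np.eye(decoder.J)) @ G
    return NetworkParams(
        F=G.T.copy(),
        Omega_f=Omega_f,
        Omega_s=Omega_s,
        T=compute_thresholds(decoder, costs),
        lambda_V=decoder.lambda_d if lambda_V is None else float(lambda_V),
        lambda_d=decoder.lambda_d,
        costs=costs,
        sigma_V=sigma_V,
        Gamma=G.copy(),
    )


def rescale_physical(
    net: NetworkParams,
    target_threshold_mV: float = -50.0,
    target_reset_mV: float = -60.0,
) -> NetworkParams:
    """Affinely map every neuron's voltage range onto physical units.

    Chooses per-neuron gains ``a_i`` and offsets ``b_i`` such that the
    rescaled threshold is ``target_threshold_mV`` and the post-spike voltage
    is ``target_reset_mV`` for every neuron.  The affine map
    ``V' = a_i V + b_i`` preserves threshold crossings exactly, so with
    matched noise the rescaled network emits the same spike train.  The
    resting potential (the fixed point of the leak alone) is ``b_i``; in the
    absence of linear costs it sits midway between threshold and reset.
    """
    if not np.allclose(net.gain, 1.0) or not np.allclose(net.v_rest, 0.0):
        raise ConfigurationError("network is already rescaled")
    drop = -np.diag(net.Omega_f)  # ||Gamma_i||^2 + mu, per neuron
    if np.any(drop <= 0):
        raise ConfigurationError(
            "cannot rescale neurons with zero-norm kernels (no self-reset)"
        )
    span = target_threshold_mV - target_reset_mV
    if span <= 0:
        raise ConfigurationError("threshold must lie above reset")
    a = span / drop
    b = target_threshold_mV - a * net.T
    return replace(
        net,
        T=np.full(net.N, float(target_threshold_mV)),
        gain=a,
        v_rest=b,
        F=net.F.copy(),
        Omega_f=net.Omega_f.copy(),
        Omega_s=net.Omega_s.copy(),
    )


# --------------------------------------------------------------------------
# kernel ensembles
# --------------------------------------------------------------------------

@dataclass
class KernelEnsembleConfig:
    """Recipe for a decoding-kernel matrix Gamma (J x N).

    modes
    -----
    ``homogeneous-signed``
        Scalar variable (J = 1); a fraction ``sign_split`` of neurons carry
        kernel ``+norm`` and the rest ``-norm``.
    ``random-normalized``
        Columns drawn i.i.d. normal then normalised to ``norm``.
    ``sparse-binomial``
        Replicated-variable ensemble: each neuron gets a sign (split as in
        homogeneous mode) and each of its J entries is independently
        ``sign * norm`` with probability ``sparsity_p`` (else 0).  All-zero
        columns are redrawn so every neuron participates.
    ``replicated-integrator``
        Alias of ``sparse-binomial`` with the convention that the J
        dimensions are identical copies of one scalar variable whose readout
        is their mean.
    """

    mode: str
    N: int
    J: int = 1
    norm: float = 0.1
    sparsity_p: float = 0.5
    sign_split: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.norm <= 0:
            raise ConfigurationError("kernel norm must be > 0")
        if not 0.0 <= self.sparsity_p <= 1.0:
            raise ConfigurationError("sparsity_p must be in [0, 1]")


def make_kernels(cfg: KernelEnsembleConfig) -> np.ndarray:
    """Build the kernel matrix for one of the standard ensembles."""
    rng = np.random.default_rng(cfg.seed)
    n_pos = cfg.sign_split * cfg.N
    if cfg.mode == "homogeneous-signed":
        if abs(n_pos - round(n_pos)) > 1e-9:
            raise ConfigurationError(
                f"N={cfg.N} not divisible by sign split {cfg.sign_split}"
            )
        n_pos = int(round(n_pos))
        if cfg.J != 1:
            raise ConfigurationError("homogeneous-signed mode is scalar (J=1)")
        signs = np.concatenate([np.ones(n_pos), -np.ones(cfg.N - n_pos)])
        return (cfg.norm * signs)[None, :]
    if cfg.mode == "random-normalized":
        G = rng.standard_normal((cfg.J, cfg.N))
        G /= np.linalg.norm(G, axis=0, keepdims=True)
        return cfg.norm * G
    if cfg.mode in ("sparse-binomial", "replicated-integrator"):
        n_pos = int(round(n_pos))
        signs = np.concatenate([np.ones(n_pos), -np.ones(cfg.N - n_pos)])
        mask = rng.random((cfg.J, cfg.N)) < cfg.sparsity_p
        # a silent (all-zero) neuron contributes nothing; redraw its mask
        for i in np.flatnonzero(~mask.any(axis=0)):
            while not mask[:, i].any():
                mask[:, i] = rng.random(cfg.J) < max(cfg.sparsity_p, 1.0 / cfg.J)
        return cfg.norm * signs[None, :] * mask
    raise ConfigurationError(f"unknown kernel mode {cfg.mode!r}")


# --------------------------------------------------------------------------
# network-size scaling
# --------------------------------------------------------------------------

def scale_network(cfg: KernelEnsembleConfig, costs: CostSpec, sigma_V: float,
                  N_new: int) -> tuple[KernelEnsembleConfig, CostSpec, float]:
    """Rescale an ensemble recipe to a different network size.

    Keeping single-neuron firing rates and the readout fixed while changing
    N requires kernels ~ 1/N.  Costs enter the threshold next to
    ``||Gamma_i||^2 ~ 1/N^2``, so ``nu`` and ``mu`` scale as 1/N^2 to keep
    each neuron's threshold composition (kernel vs cost vs noise share)
    N-invariant; the per-step voltage noise scales likewise.  After the
    physical-unit rescaling the synaptic weights are then independent of N.
    """
    if N_new < 1:
        raise ConfigurationError("N_new must be >= 1")
    s = cfg.N / N_new
    cfg2 = replace(cfg, N=N_new, norm=cfg.norm * s)
    costs2 = CostSpec(nu=costs.nu * s**2, mu=costs.mu * s**2)
    return cfg2, costs2, sigma_V * s**2
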