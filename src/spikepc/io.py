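"""Configuration files and on-disk formats.

Network build configs are YAML (or JSON) documents with blocks::

    system:   {A: [[0.0]], x0: [0.0]}
    decoder:  {gamma_mode: homogeneous-signed, N: 400, J: 1, norm: 0.02,
               sparsity_p: 0.5, lambda_d: 10.0}   # or gamma: [[...]]
    costs:    {nu: 1.0e-5, mu: 3.0e-5}
    noise:    {sigma_V: 0.0, sigma_V_ratio: 0.002, jitter_ms: 0.0}
    sim:      {dt: 1.0e-4, duration: 1.0, seed: 0}
    command:  {protocol: noisy-step, params: {amplitude: 4.0}}

Matrices travel as CSV (one header row of column indices) or in a single
HDF5 container with groups /gamma, /omega_fast, /omega_slow, /thresholds.
Rasters are two-column TSV: neuron_id (0-based), spike_time_s.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .model_spec import (ConfigurationError, CostSpec, DecoderSpec,
                         KernelEnsembleConfig, LinearSystemSpec,
                         NetworkParams, build_connectivity, make_kernels)

__all__ = ["load_config", "build_from_config", "save_matrix_csv",
           "load_matrix_csv", "save_network_h5", "load_network_h5",
           "save_raster_tsv", "load_raster_tsv"]


def load_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return cfg


def build_from_config(cfg: dict) -> tuple[NetworkParams, LinearSystemSpec, dict]:
    """Instantiate (network, system, sim options) from a parsed config."""
    sysb = cfg.get("system", {})
    system = LinearSystemSpec(A=np.asarray(sysb.get("A", [[0.0]]), float),
                              x0=sysb.get("x0"))
    dec = cfg.get("decoder", {})
    if "gamma" in dec:
        G = np.asarray(dec["gamma"], float)
    else:
        kcfg = KernelEnsembleConfig(
            mode=dec.get("gamma_mode", "homogeneous-signed"),
            N=int(dec.get("N", 400)), J=int(dec.get("J", system.J)),
            norm=float(dec.get("norm", 0.02)),
            sparsity_p=float(dec.get("sparsity_p", 0.5)),
            sign_split=float(dec.get("sign_split", 0.5)),
            seed=int(dec.get("seed", 0)))
        G = make_kernels(kcfg)
    decoder = DecoderSpec(G, lambda_d=float(dec.get("lambda_d", 10.0)))
    cb = cfg.get("costs", {})
    costs = CostSpec(nu=float(cb.get("nu", 0.0)), mu=float(cb.get("mu", 0.0)))
    nb = cfg.get("noise", {})
    sigma = nb.get("sigma_V", 0.0)
    if nb.get("sigma_V_ratio") is not None:
        sigma = float(nb["sigma_V_ratio"]) * (np.sum(G**2, axis=0) + costs.mu)
    net = build_connectivity(decoder, system, costs,
                             lambda_V=cfg.get("lambda_V"), sigma_V=sigma)
    sim = dict(cfg.get("sim", {}))
    sim.setdefault("dt", 1e-4)
    sim.setdefault("duration", 1.0)
    sim.setdefault("seed", 0)
    sim["command"] = cfg.get("command")
    sim["jitter_ms"] = float(nb.get("jitter_ms", 0.0))
    return net, system, sim


# --- matrices --------------------------------------------------------------

def save_matrix_csv(path: Union[str, Path], M: np.ndarray) -> None:
    M = np.atleast_2d(M)
    header = ",".join(str(i) for i in range(M.shape[1]))
    np.savetxt(path, M, delimiter=",", header=header, comments="")


def load_matrix_csv(path: Union[str, Path]) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=",", skiprows=1))


def save_network_h5(path: Union[str, Path], net: NetworkParams) -> None:
    import h5py
    with h5py.File(path, "w") as f:
        f.create_dataset("gamma", data=net.Gamma)
        f.create_dataset("omega_fast", data=net.Omega_f)
        f.create_dataset("omega_slow", data=net.Omega_s)
        f.create_dataset("thresholds", data=net.T)
        f.attrs["lambda_V"] = net.lambda_V
        f.attrs["lambda_d"] = net.lambda_d
        f.attrs["nu"] = net.costs.nu
        f.attrs["mu"] = net.costs.mu
        f.create_dataset("sigma_V", data=net.sigma_V_vec())
        f.create_dataset("gain", data=net.gain)
        f.create_dataset("v_rest", data=net.v_rest)


def load_network_h5(path: Union[str, Path]) -> NetworkParams:
    import h5py
    with h5py.File(path, "r") as f:
        return NetworkParams(
            F=f["gamma"][()].T,
            Omega_f=f["omega_fast"][()],
            Omega_s=f["omega_slow"][()],
            T=f["thresholds"][()],
            lambda_V=float(f.attrs["lambda_V"]),
            lambda_d=float(f.attrs["lambda_d"]),
            costs=CostSpec(nu=float(f.attrs["nu"]), mu=float(f.attrs["mu"])),
            sigma_V=f["sigma_V"][()],
            Gamma=f["gamma"][()],
            gain=f["gain"][()],
            v_rest=f["v_rest"][()],
        )


# --- rasters ---------------------------------------------------------------

def save_raster_tsv(path: Union[str, Path], spike_neurons: np.ndarray,
                    spike_times: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("neuron_id\tspike_time_s\n")
        for i, t in zip(spike_neurons, spike_times):
            fh.write(f"{int(i)}\t{t:.7f}\n")


def load_raster_tsv(path: Union[str, Path]) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    if data.size == 0:
        return np.empty(0, int), np.empty(0)
    return data[:, 0].astype(int), data[:, 1]
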