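"""Numba inner loop for the clock-driven network simulation.

The recurrent matrices of a predictive-coding network are low rank plus
diagonal: ``Omega_f = -(Gamma^T Gamma + mu I)`` and
``Omega_s = Gamma^T (A + lambda_d I) Gamma``.  The inner loop therefore never
materialises an N x N product: the slow drive is computed through the J-dim
readout (``Omega_s r = Gamma^T (A + lambda_d I) x_hat``) and a spike of
neuron ``k`` is applied as the rank-one kick ``-Gamma^T Gamma[:, k]``.  Cost
per step is O(N J), which is what makes the long (hundreds of seconds)
persistence runs and the multi-hundred-trial statistics tractable.

All stochastic inputs (voltage noise, tie-break uniforms) are pre-generated
by the caller so that noise and tie-break streams stay separate and
reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by _sim_chunk
OK = 0
DIVERGED = 1
OVERFLOW = 2


@njit(cache=True)
def _sim_chunk(
    x, V, r, xhat,                  # state, modified in place
    GT, A, lam_d, lam_V, mu,        # model; GT = Gamma.T (N, J), contiguous
    T, gain, rest,                  # thresholds / physical rescaling
    c,                              # (S, J) command samples for this chunk
    dt,
    sigma_step, noise,              # (N,) per-step noise sd (gain-scaled), (S, N) draws
    tie_u,                          # (S,) uniforms for tie-breaking
    policy,                         # 0 = one-per-step, 1 = all-suprathreshold
    clamp_mask, clamp_value,        # (N,) bool, scalar
    suppress_mask,                  # (N,) bool: cannot spike this chunk
    forced_steps, forced_neurons,   # sorted step indices within chunk
    spk_step, spk_neuron,           # output buffers
    snap_on, snap_x, snap_xhat, snap_V, snap_r,   # spike snapshots
    trace_stride, tr_V, tr_r, tr_xhat, tr_x,      # traces (post-step samples)
    step0,                          # global index of first step in chunk
):
    N, J = GT.shape
    S = c.shape[0]
    n_spk = 0
    cap = spk_step.shape[0]
    fi = 0
    have_noise = noise.shape[0] > 0
    u = np.empty(J)
    decay = 1.0 - lam_d * dt

    for s in range(S):
        # reference system: Euler on dx/dt = A x + c(t)
        for j in range(J):
            acc = c[s, j]
            for j2 in range(J):
                acc += A[j, j2] * x[j2]
            u[j] = acc            # reuse as xdot temporarily
        for j in range(J):
            x[j] += dt * u[j]

        # total continuous drive through the readout:
        # F c + Omega_s r = Gamma^T (c + (A + lam_d I) x_hat)
        for j in range(J):
            acc = c[s, j] + lam_d * xhat[j]
            for j2 in range(J):
                acc += A[j, j2] * xhat[j2]
            u[j] = acc
        for i in range(N):
            drive = 0.0
            for j in range(J):
                drive += GT[i, j] * u[j]
            V[i] += dt * (lam_V * (rest[i] - V[i]) + gain[i] * drive)
            if have_noise:
                V[i] += sigma_step[i] * noise[s, i]
            if clamp_mask[i]:
                V[i] = clamp_value

        # filtered rates and readout decay together (x_hat == Gamma r)
        for i in range(N):
            r[i] *= decay
        for j in range(J):
            xhat[j] *= decay

        # --- spike selection -------------------------------------------
        forced_here = fi < forced_steps.shape[0] and forced_steps[fi] == s
        if forced_here:
            k = forced_neurons[fi]
            fi += 1
            if n_spk >= cap:
                return n_spk, OVERFLOW, s
            spk_step[n_spk] = step0 + s
            spk_neuron[n_spk] = k
            if snap_on:
                for j in range(J):
                    snap_x[n_spk, j] = x[j]
                    snap_xhat[n_spk, j] = xhat[j]
                snap_V[n_spk] = V[k]
                snap_r[n_spk] = r[k]
            n_spk += 1
            for i in range(N):
                dot = 0.0
                for j in range(J):
                    dot += GT[i, j] * GT[k, j]
                V[i] -= gain[i] * dot
            V[k] -= gain[k] * mu
            r[k] += 1.0
            for j in range(J):
                xhat[j] += GT[k, j]
        elif policy == 0:
            # greedy: the single neuron with the largest suprathreshold
            # margin fires (its spike yields the largest cost decrease)
            best = -1
            bestm = 0.0
            nties = 0
            for i in range(N):
                if clamp_mask[i] or suppress_mask[i]:
                    continue
                m = (V[i] - T[i]) / gain[i]   # margin in raw (cost) units
                if m > 0.0:
                    if best < 0 or m > bestm:
                        best = i
                        bestm = m
                        nties = 1
                    elif m == bestm:
                        nties += 1
            if best >= 0:
                if nties > 1:
                    # rare exact tie: pick uniformly among tied neurons
                    pick = int(tie_u[s] * nties)
                    if pick >= nties:
                        pick = nties - 1
                    seen = 0
                    for i in range(N):
                        if clamp_mask[i] or suppress_mask[i]:
                            continue
                        m = (V[i] - T[i]) / gain[i]
                        if m == bestm:
                            if seen == pick:
                                best = i
                                break
                            seen += 1
                k = best
                if n_spk >= cap:
                    return n_spk, OVERFLOW, s
                spk_step[n_spk] = step0 + s
                spk_neuron[n_spk] = k
                if snap_on:
                    for j in range(J):
                        snap_x[n_spk, j] = x[j]
                        snap_xhat[n_spk, j] = xhat[j]
                    snap_V[n_spk] = V[k]
                    snap_r[n_spk] = r[k]
                n_spk += 1
                for i in range(N):
                    dot = 0.0
                    for j in range(J):
                        dot += GT[i, j] * GT[k, j]
                    V[i] -= gain[i] * dot
                V[k] -= gain[k] * mu
                r[k] += 1.0
                for j in range(J):
                    xhat[j] += GT[k, j]
        else:
            # permissive: every suprathreshold neuron fires this step
            # (documented ping-pong risk); kicks applied after selection
            nfire = 0
            for i in range(N):
                if clamp_mask[i] or suppress_mask[i]:
                    continue
                if V[i] > T[i]:
                    if n_spk + nfire >= cap:
                        return n_spk, OVERFLOW, s
                    spk_step[n_spk + nfire] = step0 + s
                    spk_neuron[n_spk + nfire] = i
                    nfire += 1
            for q in range(nfire):
                k = spk_neuron[n_spk + q]
                if snap_on:
                    for j in range(J):
                        snap_x[n_spk + q, j] = x[j]
                        snap_xhat[n_spk + q, j] = xhat[j]
                    snap_V[n_spk + q] = V[k]
                    snap_r[n_spk + q] = r[k]
            for q in range(nfire):
                k = spk_neuron[n_spk + q]
                for i in range(N):
                    dot = 0.0
                    for j in range(J):
                        dot += GT[i, j] * GT[k, j]
                    V[i] -= gain[i] * dot
                V[k] -= gain[k] * mu
                r[k] += 1.0
                for j in range(J):
                    xhat[j] += GT[k, j]
            n_spk += nfire

        # --- traces ----------------------------------------------------
        if trace_stride > 0:
            g = step0 + s
            if g % trace_stride == 0:
                row = g // trace_stride
                if row < tr_V.shape[0]:
                    for i in range(N):
                        tr_V[row, i] = V[i]
                        tr_r[row, i] = r[i]
                    for j in range(J):
                        tr_xhat[row, j] = xhat[j]
                        tr_x[row, j] = x[j]

        # divergence guard (flags regimes where the large-N voltage
        # approximation breaks down)
        vmax = 0.0
        for i in range(N):
            av = abs(V[i])
            if av > vmax:
                vmax = av
        if not np.isfinite(vmax) or vmax > 1e12:
            return n_spk, DIVERGED, s

    return n_spk, OK, S - 1
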