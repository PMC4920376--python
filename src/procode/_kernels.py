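"""Compiled inner loops for the online simulations.

The learning rule is applied per time bin while the somatic potential is
integrated by forward Euler, so training a neuron for hundreds of
periods touches ~1e7 bins; these loops are JIT-compiled with numba.  All
kernels mutate the weight array in place and return the carried scalar
state so callers can chain periods/trials.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=False)
def _phi(u, phi_max):
    if u < 0.0:
        return 0.0
    if u > 1.0:
        return phi_max
    return phi_max * u


@njit(cache=False)
def train_one_period(
    w,
    psp,        # (n_bins, n_syn), C-contiguous
    psp_tilde,  # (n_bins, n_syn)
    gE,
    gI,
    gL,
    gD,
    EE,
    EI,
    cap,
    phi_max,
    alpha,
    eta,
    dt,
    U0,
):
    """Rate-mode learning over one period; returns the final U."""
    n_bins, n_syn = psp.shape
    gLD = gL + gD
    r = dt / cap
    U = U0
    for k in range(n_bins):
        row = psp[k]
        rowt = psp_tilde[k]
        Vw = np.dot(w, row)
        U = U + r * (-gL * U + gD * (Vw - U) + gE[k] * (EE - U) + gI[k] * (EI - U))
        Vs = gD * Vw / gLD
        rU = _phi(U, phi_max)
        rV = _phi(Vs, phi_max)
        cp = dt * eta * alpha * rU
        cd = dt * eta * rV
        for i in range(n_syn):
            w[i] += cp * rowt[i] - cd * row[i]
    return U


@njit(cache=False)
def train_one_period_spike(
    w, psp, psp_tilde, gE, gI, gL, gD, EE, EI, cap, phi_max, alpha, eta, dt, U0, seed
):
    """Spike-mode variant: the potentiation term uses a sampled
    postsynaptic spike train S(t)/dt instead of phi(U)."""
    np.random.seed(seed)
    n_bins, n_syn = psp.shape
    gLD = gL + gD
    r = dt / cap
    U = U0
    for k in range(n_bins):
        row = psp[k]
        rowt = psp_tilde[k]
        Vw = np.dot(w, row)
        U = U + r * (-gL * U + gD * (Vw - U) + gE[k] * (EE - U) + gI[k] * (EI - U))
        Vs = gD * Vw / gLD
        rU = _phi(U, phi_max)
        rV = _phi(Vs, phi_max)
        post = (1.0 / dt) if np.random.random() < rU * dt else 0.0
        cp = dt * eta * alpha * post
        cd = dt * eta * rV
        for i in range(n_syn):
            w[i] += cp * rowt[i] - cd * row[i]
    return U


@njit(cache=False)
def dendritic_rate(w, psp, gD_over_gLD, phi_max):
    """phi(V*_w) per bin for fixed weights (probe helper)."""
    n_bins = psp.shape[0]
    out = np.empty(n_bins)
    for k in range(n_bins):
        out[k] = _phi(gD_over_gLD * np.dot(w, psp[k]), phi_max)
    return out


@njit(cache=False)
def run_recurrent(
    W,          # (n, n) weights, diagonal held at 0 (no autapses)
    gE_groups,  # (n_bins, n_groups) somatic drive per group
    group_id,   # (n,) group index per neuron
    n_sweeps,   # repeat the schedule this many times
    am,         # (n,) slow PSP state, carried
    asym,       # (n,) fast PSP state, carried
    tilde,      # (n,) low-pass PSP state, carried
    U,          # (n,) somatic potentials, carried
    gL,
    gD,
    EE,
    cap,
    phi_max,
    alpha,
    eta,
    tau_lp,
    dt,
    dm,
    dsn,
    c_norm,
    seed,
    rates_out,  # (n_bins * n_sweeps, n_groups) group-mean phi(U), filled
):
    """All-to-all recurrent network with the plasticity rule always on.

    Network spikes are the only dendritic input; each neuron's somatic
    drive is ``gE_groups[:, group_id[i]]``.  Spikes take effect from the
    next bin (causal PSP).  States are mutated in place.
    """
    np.random.seed(seed)
    n = W.shape[0]
    n_bins = gE_groups.shape[0]
    n_groups = gE_groups.shape[1]
    gLD = gL + gD
    r = dt / cap
    q = np.exp(-dt / tau_lp) if tau_lp > 0.0 else 0.0
    psp = np.empty(n)
    counts = np.zeros(n_groups)
    for g in range(n):
        counts[group_id[g]] += 1.0
    for sweep in range(n_sweeps):
        for k in range(n_bins):
            # decay PSP states, then low-pass
            for j in range(n):
                am[j] *= dm
                asym[j] *= dsn
                psp[j] = am[j] - asym[j]
                tilde[j] = q * tilde[j] + (1.0 - q) * psp[j]
            row = sweep * n_bins + k
            for g in range(n_groups):
                rates_out[row, g] = 0.0
            for i in range(n):
                Vw = np.dot(W[i], psp)
                gE = gE_groups[k, group_id[i]]
                U[i] = U[i] + r * (-gL * U[i] + gD * (Vw - U[i]) + gE * (EE - U[i]))
                Vs = gD * Vw / gLD
                rU = _phi(U[i], phi_max)
                rV = _phi(Vs, phi_max)
                rates_out[row, group_id[i]] += rU
                cp = dt * eta * alpha * rU
                cd = dt * eta * rV
                for j in range(n):
                    if j != i:
                        W[i, j] += cp * tilde[j] - cd * psp[j]
            for g in range(n_groups):
                rates_out[row, g] /= counts[g]
            # sample spikes; they contribute from the next bin on
            for j in range(n):
                if np.random.random() < _phi(U[j], phi_max) * dt:
                    am[j] += c_norm
                    asym[j] += c_norm
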