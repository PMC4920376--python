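"""Two-compartment neuron model.

A passive dendritic compartment collects input through plastic synapses;
its potential ``V_w`` is a weighted sum of postsynaptic potentials (PSPs).
The somatic compartment is a conductance-based leaky integrator coupled to
the dendrite and, optionally, driven by excitatory/inhibitory conductances
``g_E``, ``g_I`` near the soma.  Somatic spiking is an inhomogeneous
Bernoulli (discretised Poisson) readout of the transfer function
``phi(U)``; spikes do not reset the potential.

Conventions
-----------
* time in ms on a uniform grid with step ``dt``, traces bin-left aligned;
* conductances in nS, capacitance in nF, firing rates in kHz;
* potentials are unitless with rest = 0 (a convenient mapping is
  0 -> -70 mV and 1 -> -55 mV, in which case the default reversal
  potentials E_E = 14/3 and E_I = -1/3 correspond to 0 mV and -75 mV).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "NeuronParams",
    "SpikeTrainSet",
    "ConductanceSchedule",
    "TraceBundle",
    "StabilityError",
    "psp_kernel",
    "psp_traces",
    "dendritic_potential",
    "integrate_soma",
    "steady_state_decomposition",
    "firing_rate",
    "sample_spikes",
    "compute_traces",
]


class StabilityError(ValueError):
    """Forward-Euler step too large for the given somatic conductances."""


@dataclass(frozen=True)
class NeuronParams:
    """Biophysical constants of the two-compartment neuron.

    Attributes
    ----------
    C : somatic capacitance (nF).
    g_L : somatic leak conductance (nS).
    g_D : dendro-somatic coupling conductance (nS).
    E_E, E_I : excitatory/inhibitory reversal potentials (unitless).
    phi_max : saturation of the firing-rate transfer function (kHz).
    tau_m, tau_s : decay/rise time constants of the PSP kernel (ms).
    """

    C: float = 1.0
    g_L: float = 100.0
    g_D: float = 1800.0
    E_E: float = 14.0 / 3.0
    E_I: float = -1.0 / 3.0
    phi_max: float = 0.06
    tau_m: float = 10.0
    tau_s: float = 10.0 / 3.0

    def __post_init__(self) -> None:
        for name in ("C", "g_L", "g_D", "phi_max"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.tau_m > self.tau_s > 0:
            raise ValueError("time constants must satisfy tau_m > tau_s > 0")
        if not self.E_I < 0 < self.E_E:
            raise ValueError("reversal potentials must satisfy E_I < 0 < E_E")

    @property
    def cap_ms(self) -> float:
        """Capacitance expressed in nS*ms, so that C/g is in ms."""
        return 1e3 * self.C

    @property
    def kappa_norm(self) -> float:
        """Normalisation c of the PSP kernel; the kernel integrates to 1."""
        return 1.0 / (self.tau_m - self.tau_s)


@dataclass
class SpikeTrainSet:
    """Multi-channel presynaptic spike times over one trial period.

    ``spike_times`` holds one strictly increasing array of times (ms) per
    channel, each within ``[0, duration)``.  With ``periodic=True`` the
    trains are interpreted as one period of an infinitely repeated
    pattern, and PSPs wrap across the period boundary.
    """

    spike_times: list
    duration: float
    periodic: bool = False

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        clean = []
        for ch, times in enumerate(self.spike_times):
            t = np.asarray(times, dtype=float)
            if t.ndim != 1:
                raise ValueError(f"channel {ch}: spike times must be 1-D")
            if t.size and (np.any(np.diff(t) <= 0)):
                raise ValueError(f"channel {ch}: spike times must be strictly increasing")
            if t.size and (t[0] < 0 or t[-1] >= self.duration):
                raise ValueError(f"channel {ch}: spike times must lie in [0, duration)")
            clean.append(t)
        self.spike_times = clean

    @property
    def n_channels(self) -> int:
        return len(self.spike_times)

    def counts(self, dt: float) -> np.ndarray:
        """Spike counts per (channel, bin) on a grid with step ``dt``."""
        n_bins = int(round(self.duration / dt))
        out = np.zeros((self.n_channels, n_bins), dtype=np.float64)
        for ch, t in enumerate(self.spike_times):
            if t.size:
                idx = np.minimum((t / dt).astype(np.int64), n_bins - 1)
                np.add.at(out[ch], idx, 1.0)
        return out


@dataclass
class ConductanceSchedule:
    """Somatic conductance time series ``g_E(t)``, ``g_I(t)`` (nS)."""

    g_E: np.ndarray
    g_I: np.ndarray
    dt: float = 0.1

    def __post_init__(self) -> None:
        self.g_E = np.asarray(self.g_E, dtype=float)
        self.g_I = np.asarray(self.g_I, dtype=float)
        if self.g_E.shape != self.g_I.shape or self.g_E.ndim != 1:
            raise ValueError("g_E and g_I must be 1-D arrays of equal length")
        if np.any(self.g_E < 0) or np.any(self.g_I < 0):
            raise ValueError("conductances must be non-negative")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @classmethod
    def zeros(cls, n_bins: int, dt: float = 0.1) -> "ConductanceSchedule":
        return cls(np.zeros(n_bins), np.zeros(n_bins), dt)


def _exp_filter(
    x: np.ndarray,
    q: float,
    b0: float,
    b1: float,
    periodic: bool = False,
    zi: np.ndarray | None = None,
    return_state: bool = False,
):
    """First-order recursion ``y[k] = q y[k-1] + b0 x[k] + b1 x[k-1]``.

    Filters along the last axis.  With ``periodic=True`` the initial
    state is the exact steady state of the infinitely repeated input,
    which is available in closed form because the recursion is linear
    and its free state decays by ``q`` per step.
    """
    x = np.asarray(x, dtype=float)
    b = np.array([b0, b1])
    a = np.array([1.0, -q])
    zi_shape = x.shape[:-1] + (1,)
    if zi is None:
        zi = np.zeros(zi_shape)
    if periodic and q > 0.0:
        _, zf = lfilter(b, a, x, axis=-1, zi=np.zeros(zi_shape))
        qn = q ** x.shape[-1]
        zi = zf / (1.0 - qn)
    y, zf = lfilter(b, a, x, axis=-1, zi=zi)
    if return_state:
        return y, zf
    return y


def psp_kernel(t, params: NeuronParams) -> np.ndarray:
    """Spike-response kernel ``kappa(t) = c H(t)(e^{-t/tau_m} - e^{-t/tau_s})``.

    ``c`` is fixed so that the kernel integrates to one over all time;
    the Heaviside factor makes the kernel vanish for ``t < 0``.
    """
    t = np.asarray(t, dtype=float)
    out = params.kappa_norm * (
        np.exp(-np.clip(t, 0.0, None) / params.tau_m)
        - np.exp(-np.clip(t, 0.0, None) / params.tau_s)
    )
    return np.where(t < 0, 0.0, out)


def psp_traces(spikes: SpikeTrainSet, dt: float, params: NeuronParams) -> np.ndarray:
    """Per-channel PSP time series, shape ``(n_channels, n_bins)``.

    Implemented as two exponential state variables per channel (exact
    discrete update of the double-exponential kernel), which is
    mathematically identical to explicit convolution with ``kappa``.  A
    spike in bin ``j`` contributes from bin ``j+1`` on (causal
    convolution with the spike snapped to its bin-left time).  For
    periodic trains the states start at their periodic steady state, so
    a spike late in one period shapes the start of the next.
    """
    counts = spikes.counts(dt)
    c = params.kappa_norm
    dm = np.exp(-dt / params.tau_m)
    ds = np.exp(-dt / params.tau_s)
    a = _exp_filter(counts, dm, 0.0, c * dm, periodic=spikes.periodic)
    b = _exp_filter(counts, ds, 0.0, c * ds, periodic=spikes.periodic)
    return a - b


def dendritic_potential(
    weights: Sequence[float],
    spikes: SpikeTrainSet,
    dt: float,
    params: NeuronParams,
) -> np.ndarray:
    """Dendritic potential ``V_w(t) = sum_i w_i PSP_i(t)`` on the grid."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (spikes.n_channels,):
        raise ValueError(
            f"weights have length {w.size}, expected {spikes.n_channels} channels"
        )
    return w @ psp_traces(spikes, dt, params)


def integrate_soma(
    params: NeuronParams,
    V_w: np.ndarray,
    sched: ConductanceSchedule,
    dt: float,
    U0: float = 0.0,
) -> np.ndarray:
    """Forward-Euler trajectory of the somatic potential.

    Integrates ``C dU/dt = -g_L U + g_D (V_w - U) + g_E (E_E - U) +
    g_I (E_I - U)`` with ``U[0] = U0``.  Raises :class:`StabilityError`
    when ``dt * g_tot / C >= 1`` somewhere on the grid (explicit Euler
    would be unstable).
    """
    V_w = np.asarray(V_w, dtype=float)
    g_E, g_I = sched.g_E, sched.g_I
    if V_w.shape != g_E.shape:
        raise ValueError("V_w and conductance schedule must share the grid")
    cap = params.cap_ms
    g_tot_max = params.g_L + params.g_D + float(np.max(g_E + g_I, initial=0.0))
    if dt * g_tot_max / cap >= 1.0:
        raise StabilityError(
            f"dt={dt} ms is unstable for g_tot={g_tot_max} nS (need dt*g_tot/C < 1)"
        )
    n = V_w.size
    U = np.empty(n)
    U[0] = U0
    gL, gD, EE, EI = params.g_L, params.g_D, params.E_E, params.E_I
    r = dt / cap
    u = U0
    for k in range(1, n):
        j = k - 1
        u = u + r * (
            -gL * u + gD * (V_w[j] - u) + g_E[j] * (EE - u) + g_I[j] * (EI - u)
        )
        U[k] = u
    return U


def steady_state_decomposition(V_w, g_E, g_I, params: NeuronParams):
    """Steady-state split of the somatic potential.

    Returns ``(lam, V_star, U_star, U_approx)`` with

    * nudging factor ``lam = (g_L + g_D) / g_tot`` in (0, 1],
    * attenuated dendritic potential ``V_star = g_D V_w / (g_L + g_D)``,
    * attenuated somatic input ``U_star = (g_E E_E + g_I E_I) / g_tot``,
    * ``U_approx = lam V_star + U_star``, the quasi-static somatic
      potential, valid when conductances vary slowly compared with
      ``C / g_tot``.
    """
    V_w = np.asarray(V_w, dtype=float)
    g_E = np.asarray(g_E, dtype=float)
    g_I = np.asarray(g_I, dtype=float)
    if np.any(g_E < 0) or np.any(g_I < 0):
        raise ValueError("conductances must be non-negative")
    gLD = params.g_L + params.g_D
    g_tot = gLD + g_E + g_I
    lam = gLD / g_tot
    V_star = params.g_D * V_w / gLD
    U_star = (g_E * params.E_E + g_I * params.E_I) / g_tot
    return lam, V_star, U_star, lam * V_star + U_star


def firing_rate(U, params: NeuronParams) -> np.ndarray:
    """Piecewise-linear transfer function ``phi(U)`` in kHz.

    ``phi = phi_max * U`` for ``0 <= U <= 1``, clipped to 0 below rest
    and to ``phi_max`` above saturation.
    """
    return params.phi_max * np.clip(np.asarray(U, dtype=float), 0.0, 1.0)


def sample_spikes(rate, dt: float, seed) -> np.ndarray:
    """Sample spike times from an inhomogeneous Bernoulli process.

    One independent draw per bin with success probability ``rate * dt``;
    the returned times are the bin-left edges.  ``seed`` may be an
    integer or a ``numpy.random.Generator``.
    """
    rate = np.asarray(rate, dtype=float)
    p = rate * dt
    if p.size and p.max() > 1.0:
        raise ValueError("rate * dt exceeds 1 somewhere: probability overflow")
    if np.any(p < 0):
        raise ValueError("rates must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = rng.random(p.shape) < p
    return np.flatnonzero(hits) * dt


@dataclass
class TraceBundle:
    """Aligned time series of the model variables on a shared grid."""

    dt: float
    V_w: np.ndarray
    U: np.ndarray
    V_star: np.ndarray
    U_star: np.ndarray
    lam: np.ndarray
    rate_U: np.ndarray
    rate_V_star: np.ndarray

    _FIELDS = ("V_w", "U", "V_star", "U_star", "lam", "rate_U", "rate_V_star")

    def __post_init__(self) -> None:
        n = None
        for name in self._FIELDS:
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if n is None:
                n = arr.size
            elif arr.size != n:
                raise ValueError("all traces must have equal length")
        if np.any(self.lam <= 0) or np.any(self.lam > 1):
            raise ValueError("lam must lie in (0, 1]")
        if np.any(self.rate_U < 0) or np.any(self.rate_V_star < 0):
            raise ValueError("rates must be non-negative")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.V_w.size) * self.dt

    def to_frame(self) -> pd.DataFrame:
        data = {"time_ms": self.time}
        for name in self._FIELDS:
            data[name] = getattr(self, name)
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TraceBundle":
        t = frame["time_ms"].to_numpy()
        dt = float(t[1] - t[0]) if t.size > 1 else 0.1
        return cls(dt=dt, **{name: frame[name].to_numpy() for name in cls._FIELDS})


def compute_traces(
    V_w: np.ndarray,
    sched: ConductanceSchedule,
    params: NeuronParams,
    dt: float,
    U0: float | None = None,
) -> TraceBundle:
    """Assemble a :class:`TraceBundle` from a dendritic potential trace
    and a conductance schedule (soma integrated by forward Euler)."""
    lam, V_star, U_star, U_approx = steady_state_decomposition(
        V_w, sched.g_E, sched.g_I, params
    )
    if U0 is None:
        U0 = float(U_approx[0])
    U = integrate_soma(params, V_w, sched, dt, U0=U0)
    return TraceBundle(
        dt=dt,
        V_w=V_w,
        U=U,
        V_star=V_star,
        U_star=U_star,
        lam=np.broadcast_to(lam, np.shape(V_w)).copy(),
        rate_U=firing_rate(U, params),
        rate_V_star=firing_rate(V_star, params),
    )
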