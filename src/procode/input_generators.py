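"""Seeded synthetic input generators.

Every generator is a pure function of its parameters and seed: reruns
are bit-identical.  Covered input classes:

* deterministic orthogonal spike patterns (one spike per synapse and
  period, evenly spaced),
* frozen Poisson trains (drawn once, replayed identically each period),
* inhomogeneous Poisson trains (fresh samples each trial from given
  rate profiles),
* Ornstein--Uhlenbeck short-term-memory (STM) rate traces emulating the
  readout of a recurrent reservoir after a stimulus,
* somatic conductance schedules (step pulses, a fixed multi-harmonic
  waveform, sequential group pulses) and probabilistic event trains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from procode.core_model import (
    ConductanceSchedule,
    NeuronParams,
    SpikeTrainSet,
    firing_rate,
)

__all__ = [
    "OUParams",
    "orthogonal_pattern",
    "frozen_poisson",
    "inhomogeneous_poisson",
    "random_rate_profiles",
    "piecewise_rate_profiles",
    "ou_templates",
    "stm_templates",
    "stm_trial",
    "stm_traces",
    "multiharmonic_conductance",
    "pulse_conductance",
    "sequential_stimulation",
    "probabilistic_event",
]


@dataclass(frozen=True)
class OUParams:
    """Ornstein--Uhlenbeck parameters for the STM rate traces.

    ``theta1``/``sigma1`` govern the per-label template trajectories
    (inverse correlation time 1/ms and noise scale); ``theta2`` pulls
    each trial's trace toward its template; ``sigma_in``/``sigma_out``
    are the trial noise *variances* inside/outside the stimulus window
    (stimulus onset quenches the variability).

    ``variance_mode`` controls the units of the noise scales: with
    ``"stationary"`` (default) the diffusion coefficient is
    ``sigma * sqrt(2 theta)``, so ``sigma1**2`` and ``sigma_in/out``
    are the stationary variances of the processes — which keeps the
    rate excursions inside the linear range of the transfer function;
    ``"literal"`` uses the scales directly as diffusion coefficients
    per sqrt(ms).
    """

    theta1: float = 1e-3
    sigma1: float = 1.0
    theta2: float = 1e-2
    sigma_in: float = 0.1
    sigma_out: float = 1.0
    variance_mode: str = "stationary"

    def __post_init__(self) -> None:
        for name in ("theta1", "sigma1", "theta2", "sigma_in", "sigma_out"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.variance_mode not in ("stationary", "literal"):
            raise ValueError("variance_mode must be 'stationary' or 'literal'")

    def diffusion(self, theta: float, sigma: float) -> float:
        """Diffusion coefficient for the chosen parameterisation."""
        if self.variance_mode == "stationary":
            return sigma * np.sqrt(2.0 * theta)
        return sigma


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def orthogonal_pattern(n_syn: int, period: float, dt: float) -> SpikeTrainSet:
    """One spike per synapse and period, evenly spaced: synapse ``i``
    fires at ``i * period / n_syn``.  Deterministic."""
    if n_syn > period / dt:
        raise ValueError("more synapses than time bins: spikes would collide")
    times = [np.array([i * period / n_syn]) for i in range(n_syn)]
    return SpikeTrainSet(times, duration=period, periodic=True)


def frozen_poisson(
    n: int, rate: float, period: float, dt: float, seed
) -> SpikeTrainSet:
    """Homogeneous Poisson trains drawn once and replayed each period."""
    rng = _as_rng(seed)
    p = rate * dt
    if p > 1.0:
        raise ValueError("rate * dt exceeds 1")
    n_bins = int(round(period / dt))
    trains = [np.flatnonzero(rng.random(n_bins) < p) * dt for _ in range(n)]
    return SpikeTrainSet(trains, duration=period, periodic=True)


def inhomogeneous_poisson(rate_profiles: np.ndarray, dt: float, seed) -> SpikeTrainSet:
    """Fresh Bernoulli samples from per-channel rate profiles (kHz)."""
    rng = _as_rng(seed)
    rates = np.asarray(rate_profiles, dtype=float)
    p = rates * dt
    if p.size and p.max() > 1.0:
        raise ValueError("rate * dt exceeds 1")
    trains = [np.flatnonzero(rng.random(p.shape[1]) < p[ch]) * dt
              for ch in range(p.shape[0])]
    return SpikeTrainSet(trains, duration=rates.shape[1] * dt, periodic=False)


def random_rate_profiles(
    n: int,
    period: float,
    dt: float,
    seed,
    base_rate: float = 0.02,
    n_harmonics: int = 8,
) -> np.ndarray:
    """Smooth positive periodic rate profiles with rich temporal
    structure: a random truncated Fourier series around ``base_rate``,
    rectified at zero."""
    rng = _as_rng(seed)
    n_bins = int(round(period / dt))
    t = np.arange(n_bins) * dt
    omega = 2.0 * np.pi / period
    rates = np.full((n, n_bins), 1.0)
    for k in range(1, n_harmonics + 1):
        a = rng.normal(0.0, 1.0 / np.sqrt(n_harmonics), size=(n, 1))
        b = rng.normal(0.0, 1.0 / np.sqrt(n_harmonics), size=(n, 1))
        rates += a * np.cos(k * omega * t) + b * np.sin(k * omega * t)
    return base_rate * np.clip(rates, 0.0, None)


def piecewise_rate_profiles(
    n: int,
    period: float,
    dt: float,
    seed,
    n_segments: int = 3,
    base_rate: float = 0.02,
) -> np.ndarray:
    """Rates constant over long intervals (poor temporal structure; a
    neuron trained on these learns a stepwise rather than smooth ramp)."""
    rng = _as_rng(seed)
    n_bins = int(round(period / dt))
    seg = n_bins // n_segments
    levels = rng.exponential(base_rate, size=(n, n_segments))
    rates = np.repeat(levels, seg, axis=1)
    if rates.shape[1] < n_bins:
        rates = np.concatenate(
            [rates, np.repeat(levels[:, -1:], n_bins - rates.shape[1], axis=1)], axis=1
        )
    return rates[:, :n_bins]


def ou_templates(
    n_neurons: int, params: OUParams, duration: float, dt: float, rng
) -> np.ndarray:
    """Mean-zero OU template trajectories, one per neuron, by
    Euler--Maruyama from a stationary initial draw."""
    rng = _as_rng(rng)
    n_bins = int(round(duration / dt))
    sig = params.diffusion(params.theta1, params.sigma1)
    sd_stat = sig / np.sqrt(2.0 * params.theta1)
    r = np.empty((n_neurons, n_bins))
    r[:, 0] = rng.normal(0.0, sd_stat, size=n_neurons)
    noise = rng.normal(0.0, sig * np.sqrt(dt), size=(n_neurons, n_bins - 1))
    decay = 1.0 - params.theta1 * dt
    for k in range(1, n_bins):
        r[:, k] = decay * r[:, k - 1] + noise[:, k - 1]
    return r


def stm_templates(
    n_neurons: int, params: OUParams, duration: float, dt: float, seed
) -> dict:
    """Per-label template rate trajectories (labels ``A1`` and ``A2``),
    drawn once per neuron-and-label."""
    rng = _as_rng(seed)
    return {
        "A1": ou_templates(n_neurons, params, duration, dt, rng),
        "A2": ou_templates(n_neurons, params, duration, dt, rng),
    }


def stm_trial(
    templates: dict,
    stimulus: str,
    params: OUParams,
    t_grid_start: float,
    n_bins: int,
    dt: float,
    rng,
    stim_window: tuple = (0.0, 3000.0),
    r0: np.ndarray | None = None,
):
    """One trial of the STM rate process.

    The trace relaxes toward a trial mean ``mu_s(t) = (1 - sigma(t))
    r^s(t) - sigma(t)/2`` with time-dependent noise variance
    ``sigma^2(t)`` equal to ``sigma_in`` inside the stimulus window and
    ``sigma_out`` outside, so the trajectories approach the label
    template exactly while the stimulus is present.  Times are relative
    to stimulus onset; ``t_grid_start`` may be negative.  Returns
    ``(rates, final_rates)``.
    """
    rng = _as_rng(rng)
    tmpl = templates[stimulus]
    n_neurons = tmpl.shape[0]
    t = t_grid_start + np.arange(n_bins) * dt
    in_stim = (t >= stim_window[0]) & (t <= stim_window[1])
    var = np.where(in_stim, params.sigma_in, params.sigma_out)
    sigma_t = np.sqrt(var)
    diff_in = params.diffusion(params.theta2, np.sqrt(params.sigma_in))
    diff_out = params.diffusion(params.theta2, np.sqrt(params.sigma_out))
    diff_t = np.where(in_stim, diff_in, diff_out)
    # template value at the in-window time, template index clipped to range
    idx = np.clip((np.clip(t, 0.0, None) / dt).astype(np.int64), 0, tmpl.shape[1] - 1)
    mu = (1.0 - sigma_t)[None, :] * tmpl[:, idx] - sigma_t[None, :] / 2.0
    r = np.empty((n_neurons, n_bins))
    if r0 is None:
        sd0 = params.diffusion(params.theta2, sigma_t[0]) / np.sqrt(2 * params.theta2)
        r0 = mu[:, 0] + rng.normal(0.0, sd0, size=n_neurons)
    r[:, 0] = r0
    noise = rng.normal(0.0, 1.0, size=(n_neurons, n_bins - 1))
    for k in range(1, n_bins):
        r[:, k] = (
            r[:, k - 1]
            - params.theta2 * (r[:, k - 1] - mu[:, k]) * dt
            + diff_t[k] * np.sqrt(dt) * noise[:, k - 1]
        )
    return r, r[:, -1].copy()


def stm_traces(
    n_neurons: int,
    params: OUParams,
    stimulus: str,
    trial_window: tuple,
    dt: float,
    seed,
    neuron: NeuronParams | None = None,
):
    """Rates and spikes for one STM trial (templates drawn from the seed).

    ``trial_window = (t_start, t_stop)`` in ms relative to stimulus
    onset.  Spikes are sampled at rate ``phi(r_i(t))`` — negative rate
    excursions are clipped to silence by the transfer function.
    Returns ``(rates, spikes)``.
    """
    if stimulus not in ("A1", "A2"):
        raise ValueError("stimulus label must be 'A1' or 'A2'")
    neuron = neuron or NeuronParams()
    rng = _as_rng(seed)
    t0, t1 = trial_window
    n_bins = int(round((t1 - t0) / dt))
    templates = stm_templates(n_neurons, params, max(t1, dt), dt, rng)
    rates, _ = stm_trial(templates, stimulus, params, t0, n_bins, dt, rng)
    phi_rates = firing_rate(rates, neuron)
    trains = []
    for ch in range(n_neurons):
        p = phi_rates[ch] * dt
        trains.append(np.flatnonzero(rng.random(n_bins) < p) * dt)
    spikes = SpikeTrainSet(trains, duration=n_bins * dt, periodic=False)
    return rates, spikes


def pulse_conductance(
    period: float,
    dt: float,
    start: float,
    stop: float,
    g_E: float,
    g_I_factor: float = 0.0,
) -> ConductanceSchedule:
    """Step pulse: ``g_E`` between ``start`` and ``stop``, zero
    elsewhere; ``g_I = g_I_factor * g_E`` (used to keep the somatic
    drive weak while preserving its timing)."""
    n_bins = int(round(period / dt))
    t = np.arange(n_bins) * dt
    gE = np.where((t >= start) & (t < stop), g_E, 0.0)
    return ConductanceSchedule(gE, g_I_factor * gE, dt)


def multiharmonic_conductance(
    period: float = 2000.0, dt: float = 0.1, g0: float = 6.0
) -> ConductanceSchedule:
    """Fixed time-varying excitatory drive
    ``g_E(t) = g0 (1 - sin(wt) sin(2wt) cos(4wt))`` with
    ``w = 2 pi / period`` and ``g_I = 0``; non-negative with mean
    ``g0`` over the period."""
    n_bins = int(round(period / dt))
    t = np.arange(n_bins) * dt
    w = 2.0 * np.pi / period
    gE = g0 * (1.0 - np.sin(w * t) * np.sin(2 * w * t) * np.cos(4 * w * t))
    return ConductanceSchedule(gE, np.zeros(n_bins), dt)


def sequential_stimulation(
    n_groups: int,
    group_size: int,
    pulse_ms: float,
    g_E_on: float,
    dt: float,
    mode: str = "train",
    recall_ms: float = 20.0,
    recall_window: float = 800.0,
    gap_ms: float = 1600.0,
):
    """Per-group somatic drive for the sequence protocol.

    In ``train`` mode group ``k`` receives ``g_E_on`` during its
    ``pulse_ms`` slot of each sweep (one sweep spans
    ``n_groups * pulse_ms``); groups partition the population and
    exactly one group is active at a time.  In ``recall`` mode the
    drive is silent for ``gap_ms`` (training reverberation dies out),
    then only group 0 is driven for ``recall_ms``, followed by a silent
    window.  Returns ``(group_ids, gE)`` with ``gE`` of shape
    ``(n_bins, n_groups)``.
    """
    group_ids = np.repeat(np.arange(n_groups), group_size)
    if mode == "train":
        n_bins = int(round(n_groups * pulse_ms / dt))
        gE = np.zeros((n_bins, n_groups))
        per = int(round(pulse_ms / dt))
        for k in range(n_groups):
            gE[k * per:(k + 1) * per, k] = g_E_on
    elif mode == "recall":
        gap = int(round(gap_ms / dt))
        n_bins = gap + int(round((recall_ms + recall_window) / dt))
        gE = np.zeros((n_bins, n_groups))
        gE[gap: gap + int(round(recall_ms / dt)), 0] = g_E_on
    else:
        raise ValueError("mode must be 'train' or 'recall'")
    return group_ids, gE


def probabilistic_event(
    base_schedule: ConductanceSchedule, p_event: float, n_trials: int, seed
):
    """Per-trial schedules where the somatic event is independently kept
    with probability ``p_event`` and silenced otherwise.  Kept trials
    share the base arrays (no copies)."""
    if not 0.0 <= p_event <= 1.0:
        raise ValueError("p_event must lie in [0, 1]")
    rng = _as_rng(seed)
    keep = rng.random(n_trials) < p_event
    silent = ConductanceSchedule(
        np.zeros_like(base_schedule.g_E), np.zeros_like(base_schedule.g_I),
        base_schedule.dt,
    )
    return [base_schedule if k else silent for k in keep], keep
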