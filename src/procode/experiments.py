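"""End-to-end protocol runners and their outcome metrics.

Five protocols are covered:

* **ramp** — periodic dendritic input (orthogonal / frozen Poisson /
  inhomogeneous Poisson) with a terminal somatic pulse; the neuron
  learns an anticipatory firing ramp whose time constant is the
  effective discount time constant.
* **time series** — a fixed multi-harmonic somatic drive; learning
  advances the firing rate relative to the input (measured by the peak
  of the circular cross-correlation).
* **paired associate** — stochastic short-term-memory traces as
  dendritic input; readout neurons learn sample-specific anticipatory
  ramps toward their target-specific somatic drives.
* **recurrent replay** — an all-to-all plastic network stimulated
  sequentially learns to replay the sequence, temporally compressed,
  from a brief cue.

Probe trials freeze learning (eta = 0) except in the recurrent
protocol, where the rule stays on throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit
from scipy.stats import kendalltau, pearsonr

from procode._kernels import dendritic_rate, run_recurrent, train_one_period
from procode.core_model import (
    ConductanceSchedule,
    NeuronParams,
    TraceBundle,
    _exp_filter,
    compute_traces,
    firing_rate,
    integrate_soma,
    steady_state_decomposition,
)
from procode.input_generators import (
    OUParams,
    frozen_poisson,
    inhomogeneous_poisson,
    multiharmonic_conductance,
    orthogonal_pattern,
    piecewise_rate_profiles,
    probabilistic_event,
    pulse_conductance,
    random_rate_profiles,
    sequential_stimulation,
    stm_templates,
    stm_trial,
)
from procode.plasticity import PlasticityParams, lowpass_psp
from procode.theory import ConvergenceError, periodic_fixed_point

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "run_ramp_experiment",
    "run_time_series_experiment",
    "run_paired_associate",
    "run_recurrent_replay",
    "fit_ramp_time_constant",
    "advancement_peak",
]

WEIGHT_BOUND = 1e4  # diagnostic guard on ||w||_inf during training


@dataclass
class ExperimentConfig:
    """Settings for one protocol run.

    ``input`` and ``schedule`` are small dicts with a ``kind`` key; the
    accepted kinds and their parameters are documented in the runner
    for each protocol.  ``seed`` feeds a ``numpy`` SeedSequence that
    fans out to every stochastic component.
    """

    neuron: NeuronParams = field(default_factory=NeuronParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    dt: float = 0.1
    seed: int = 0
    period: float = 2000.0
    n_training_periods: int = 500
    input: dict = field(default_factory=lambda: {"kind": "orthogonal", "n_synapses": 500})
    schedule: dict = field(
        default_factory=lambda: {"kind": "pulse", "start": 1800.0, "stop": 2000.0,
                                 "g_E": 15.0}
    )
    probe: dict = field(default_factory=dict)

    def rng_children(self, n: int):
        seqs = np.random.SeedSequence(self.seed).spawn(n)
        return [np.random.default_rng(s) for s in seqs]


@dataclass
class ExperimentResult:
    """Final weights, probe traces and the derived metrics of a run."""

    weights: np.ndarray
    traces: TraceBundle | None
    theory_rate: np.ndarray | None
    metrics: dict
    history: dict


def _check_weights(w):
    if not np.all(np.isfinite(w)) or np.max(np.abs(w)) > WEIGHT_BOUND:
        raise ConvergenceError(
            "weights diverged during training (norm grew beyond bound); "
            "check alpha against the stability bound and the learning rate"
        )


def _psp_stream(counts, dt, neuron, tau, states=None, periodic=False):
    """PSP and low-pass PSP traces from spike counts, with filter state
    carried across calls (``states`` from a previous segment)."""
    c = neuron.kappa_norm
    dm = np.exp(-dt / neuron.tau_m)
    ds = np.exp(-dt / neuron.tau_s)
    za, zb, zt = states if states is not None else (None, None, None)
    a, za = _exp_filter(counts, dm, 0.0, c * dm, periodic=periodic, zi=za,
                        return_state=True)
    b, zb = _exp_filter(counts, ds, 0.0, c * ds, periodic=periodic, zi=zb,
                        return_state=True)
    psp = a - b
    psp_tilde, zt = lowpass_psp(psp, tau, dt, periodic=periodic, zi=zt,
                                return_state=True)
    return psp, psp_tilde, (za, zb, zt)


def _build_periodic_input(config: ExperimentConfig, rng):
    """Spike trains for the deterministic periodic input kinds."""
    spec = dict(config.input)
    kind = spec.pop("kind")
    n_syn = spec.pop("n_synapses")
    if kind == "orthogonal":
        return orthogonal_pattern(n_syn, config.period, config.dt)
    if kind == "frozen_poisson":
        rate = spec.pop("rate", 0.02)
        return frozen_poisson(n_syn, rate, config.period, config.dt, rng)
    raise ValueError(f"unknown periodic input kind {kind!r}")


def _rate_profiles(config: ExperimentConfig, rng):
    spec = dict(config.input)
    n_syn = spec["n_synapses"]
    if spec.get("profile", "smooth") == "piecewise":
        return piecewise_rate_profiles(
            n_syn, config.period, config.dt, rng,
            n_segments=spec.get("n_segments", 3),
            base_rate=spec.get("rate", 0.02),
        )
    return random_rate_profiles(
        n_syn, config.period, config.dt, rng,
        base_rate=spec.get("rate", 0.02),
        n_harmonics=spec.get("n_harmonics", 8),
    )


def _base_schedule(config: ExperimentConfig) -> ConductanceSchedule:
    spec = dict(config.schedule)
    kind = spec.pop("kind")
    if kind == "pulse":
        return pulse_conductance(
            config.period, config.dt, spec["start"], spec["stop"], spec["g_E"],
            g_I_factor=spec.get("g_I_factor", 0.0),
        )
    if kind == "multiharmonic":
        sched = multiharmonic_conductance(config.period, config.dt,
                                          g0=spec.get("g0", 6.0))
        factor = spec.get("g_I_factor", 0.0)
        if factor:
            # inhibitory co-drive strengthens nudging (smaller lam)
            # while preserving the timing of the somatic input
            sched = ConductanceSchedule(sched.g_E, factor * sched.g_E, sched.dt)
        return sched
    raise ValueError(f"unknown schedule kind {kind!r}")


def _theory_curve(config, sched, p_event=1.0, lam_theory=1.0):
    """Fixed-point prediction of the dendritic rate from the somatic
    schedule (mean over event trials; the fixed point is linear in the
    mean somatic rate)."""
    neuron, plast = config.neuron, config.plasticity
    _, _, U_star, _ = steady_state_decomposition(
        np.zeros_like(sched.g_E), sched.g_E, sched.g_I, neuron
    )
    phi_Ustar = p_event * firing_rate(U_star, neuron)
    return periodic_fixed_point(
        phi_Ustar, lam_theory, plast.alpha, plast.tau, config.period, config.dt
    )


def run_ramp_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Train an anticipatory firing ramp and probe it.

    Input kinds: ``orthogonal`` (one evenly spaced spike per synapse),
    ``frozen_poisson`` (``rate`` kHz, replayed each period) and
    ``inhomogeneous_poisson`` (fresh samples each period from smooth or
    ``piecewise`` profiles).  The schedule is a terminal ``pulse``,
    optionally occurring only with probability ``p_event``.  Probing
    silences the somatic input and freezes learning; the result carries
    the probe traces, the fixed-point theory curve and per-period
    correlation/weight-norm history.
    """
    neuron, plast, dt = config.neuron, config.plasticity, config.dt
    rng_in, rng_ev = config.rng_children(2)
    sched = _base_schedule(config)
    p_event = float(config.schedule.get("p_event", 1.0))
    theory_rate = _theory_curve(config, sched, p_event)
    n_bins = sched.g_E.size
    pulse_start = config.schedule.get("start", config.period)
    pre_mask = (np.arange(n_bins) * dt) < pulse_start

    kind = config.input["kind"]
    fresh_each_period = kind == "inhomogeneous_poisson"
    if fresh_each_period:
        profiles = _rate_profiles(config, rng_in)
        n_syn = profiles.shape[0]
        psp_T = psp_tilde_T = None
        states = None
    else:
        spikes = _build_periodic_input(config, rng_in)
        n_syn = spikes.n_channels
        psp, psp_tilde, _ = _psp_stream(
            spikes.counts(dt), dt, neuron, plast.tau, periodic=True
        )
        psp_T = np.ascontiguousarray(psp.T)
        psp_tilde_T = np.ascontiguousarray(psp_tilde.T)

    n_train = config.n_training_periods
    if p_event < 1.0:
        schedules, kept = probabilistic_event(sched, p_event, n_train, rng_ev)
    else:
        schedules, kept = [sched] * n_train, np.ones(n_train, dtype=bool)

    w = np.zeros(n_syn)
    corr_hist = np.full(n_train, np.nan)
    wnorm_hist = np.zeros(n_train)
    gd_ratio = neuron.g_D / (neuron.g_L + neuron.g_D)
    U = 0.0
    for t in range(n_train):
        if fresh_each_period:
            trial_spikes = inhomogeneous_poisson(profiles, dt, rng_in)
            psp, psp_tilde, states = _psp_stream(
                trial_spikes.counts(dt), dt, neuron, plast.tau, states=states
            )
            psp_T = np.ascontiguousarray(psp.T)
            psp_tilde_T = np.ascontiguousarray(psp_tilde.T)
        s = schedules[t]
        U = train_one_period(
            w, psp_T, psp_tilde_T, s.g_E, s.g_I,
            neuron.g_L, neuron.g_D, neuron.E_E, neuron.E_I,
            neuron.cap_ms, neuron.phi_max, plast.alpha, plast.eta, dt, U,
        )
        _check_weights(w)
        wnorm_hist[t] = np.max(np.abs(w))
        rv = dendritic_rate(w, psp_T, gd_ratio, neuron.phi_max)
        if np.std(rv[pre_mask]) > 0 and np.std(theory_rate[pre_mask]) > 0:
            corr_hist[t] = pearsonr(rv[pre_mask], theory_rate[pre_mask]).statistic

    # probe: somatic input silenced, learning frozen
    if fresh_each_period:
        trial_spikes = inhomogeneous_poisson(profiles, dt, rng_in)
        psp, _, _ = _psp_stream(trial_spikes.counts(dt), dt, neuron, plast.tau,
                                states=states)
    V_w = w @ psp
    silent = ConductanceSchedule.zeros(n_bins, dt)
    traces = compute_traces(V_w, silent, neuron, dt)

    sim = traces.rate_V_star
    th, sm = theory_rate[pre_mask], sim[pre_mask]
    metrics = {
        "rms_rel_error_pre_event": float(
            np.sqrt(np.mean((sm - th) ** 2) / np.mean(th**2))
        ) if np.any(th != 0) else np.nan,
        "corr_pre_event": float(pearsonr(sm, th).statistic)
        if np.std(sm) > 0 and np.std(th) > 0 else np.nan,
        "ramp_amplitude": float(np.mean(
            sim[pre_mask & ((np.arange(n_bins) * dt) >= pulse_start - 100.0)]
        )),
        "event_fraction": float(np.mean(kept)),
    }
    history = {"corr": corr_hist, "w_inf_norm": wnorm_hist}
    return ExperimentResult(w, traces, theory_rate, metrics, history)


def run_time_series_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Train on a continuously varying somatic drive and measure the
    temporal advancement of the learned firing rate.

    The probe keeps the somatic schedule on (learning frozen); the
    advancement is the lag at the peak of the circular cross-correlation
    between phi(U) and phi(U*), positive when the learned rate leads.
    """
    neuron, plast, dt = config.neuron, config.plasticity, config.dt
    (rng_in,) = config.rng_children(1)
    sched = _base_schedule(config)
    spikes = _build_periodic_input(config, rng_in)
    psp, psp_tilde, _ = _psp_stream(spikes.counts(dt), dt, neuron, plast.tau,
                                    periodic=True)
    psp_T = np.ascontiguousarray(psp.T)
    psp_tilde_T = np.ascontiguousarray(psp_tilde.T)
    w = np.zeros(spikes.n_channels)
    U = 0.0
    wnorm_hist = np.zeros(config.n_training_periods)
    for t in range(config.n_training_periods):
        U = train_one_period(
            w, psp_T, psp_tilde_T, sched.g_E, sched.g_I,
            neuron.g_L, neuron.g_D, neuron.E_E, neuron.E_I,
            neuron.cap_ms, neuron.phi_max, plast.alpha, plast.eta, dt, U,
        )
        _check_weights(w)
        wnorm_hist[t] = np.max(np.abs(w))

    V_w = w @ psp
    traces = compute_traces(V_w, sched, neuron, dt)
    phi_Ustar = firing_rate(traces.U_star, neuron)
    lam_mean = float(np.mean(traces.lam))
    theory_rate = periodic_fixed_point(
        phi_Ustar, lam_mean, plast.alpha, plast.tau, config.period, dt
    ) if plast.tau >= 0 else None
    lag = advancement_peak(traces.rate_U, phi_Ustar, dt)
    metrics = {"advancement_ms": lag, "lam_mean": lam_mean}
    return ExperimentResult(w, traces, theory_rate, metrics,
                            {"w_inf_norm": wnorm_hist})


def fit_ramp_time_constant(
    rate: np.ndarray, event_time: float, fit_window: float, dt: float
) -> float:
    """Least-squares fit of ``a * exp((t - event_time)/tau)`` to the
    pre-event rate; returns the fitted tau (ms).

    The window is ``[event_time - fit_window, event_time)``.  A flat or
    non-positive trace raises ``ValueError``.
    """
    rate = np.asarray(rate, dtype=float)
    t = np.arange(rate.size) * dt
    mask = (t >= event_time - fit_window) & (t < event_time)
    y = rate[mask]
    tt = t[mask] - event_time
    if y.size < 4 or y.max() <= 0 or np.ptp(y) < 1e-14:
        raise ValueError("degenerate (flat) rate trace: cannot fit a ramp")
    pos = y > y.max() * 1e-3
    slope, intercept = np.polyfit(tt[pos], np.log(y[pos]), 1)
    tau0 = 1.0 / slope if slope > 0 else fit_window / 2.0
    a0 = float(np.exp(intercept))
    popt, _ = curve_fit(
        lambda x, a, tau: a * np.exp(x / tau), tt, y, p0=[a0, tau0], maxfev=10000
    )
    return float(popt[1])


def advancement_peak(rate_U: np.ndarray, rate_Ustar: np.ndarray, dt: float) -> float:
    """Lag (ms) at the maximum of the circular cross-correlation of two
    periodic rate curves; positive when the learned rate leads the
    somatic input rate."""
    a = np.asarray(rate_U, dtype=float)
    b = np.asarray(rate_Ustar, dtype=float)
    if a.size != b.size:
        raise ValueError("series must have equal length")
    a = a - a.mean()
    b = b - b.mean()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    c = np.real(np.fft.ifft(np.conj(np.fft.fft(a)) * np.fft.fft(b)))
    n = a.size
    best = int(np.argmax(c))
    lag = best if best <= n // 2 else best - n
    return lag * dt


def run_paired_associate(config: ExperimentConfig) -> ExperimentResult:
    """Delayed paired-associate task with short-term-memory input.

    Each trial presents sample A1 or A2 (equiprobable); the matching
    target drives the readout somata ``delay_ms`` after sample offset.
    Readout drives (nS) are given per neuron and label in
    ``schedule["g_E_A1"]`` / ``g_E_A2``.  Dendritic input comes from
    ``input["n_stm"]`` stochastic STM neurons whose rate trajectories
    approach label-specific templates during the trial.  Intertrial
    intervals are uniform in ``[iti_min, iti_max]``; OU rates and filter
    states persist across the whole experiment, trial noise does not.
    Probes (learning and somatic drive off) report the mean phi(U) over
    the final ``probe_ms`` of the delay per label.
    """
    neuron, plast, dt = config.neuron, config.plasticity, config.dt
    rng_tmpl, rng_trial, rng_label = config.rng_children(3)
    n_stm = config.input["n_stm"]
    ou = OUParams(**config.input.get("ou", {}))
    sc = config.schedule
    sample_ms = sc.get("sample_ms", 500.0)
    delay_ms = sc.get("delay_ms", 1000.0)
    target_ms = sc.get("target_ms", 200.0)
    iti_min, iti_max = sc.get("iti_min", 3000.0), sc.get("iti_max", 10000.0)
    g_by_label = {"A1": np.asarray(sc["g_E_A1"], float),
                  "A2": np.asarray(sc["g_E_A2"], float)}
    n_readout = g_by_label["A1"].size
    probe_ms = sc.get("probe_ms", 200.0)
    n_probe = config.probe.get("n_trials", 5)

    trial_len = sample_ms + delay_ms + target_ms
    templates = stm_templates(n_stm, ou, trial_len, dt, rng_tmpl)
    target_on = sample_ms + delay_ms
    delay_end_bin = int(round(target_on / dt))
    probe_lo = int(round((target_on - probe_ms) / dt))

    W = np.zeros((n_readout, n_stm))
    U = np.zeros(n_readout)
    states = None
    r0 = None

    def one_segment(label, gE_per_readout, learn):
        nonlocal states, r0, U
        iti = float(rng_trial.uniform(iti_min, iti_max))
        n_bins = int(round((trial_len + iti) / dt))
        rates, r0 = stm_trial(
            templates, label, ou, 0.0, n_bins, dt, rng_trial,
            stim_window=(0.0, trial_len), r0=r0,
        )
        phi_r = firing_rate(rates, neuron)
        hits = rng_trial.random(phi_r.shape) < phi_r * dt
        counts = hits.astype(np.float64)
        psp, psp_tilde, states = _psp_stream(counts, dt, neuron, plast.tau,
                                             states=states)
        psp_T = np.ascontiguousarray(psp.T)
        if learn:
            psp_tilde_T = np.ascontiguousarray(psp_tilde.T)
            t_grid = np.arange(n_bins) * dt
            on = (t_grid >= target_on) & (t_grid < trial_len)
            gI = np.zeros(n_bins)
            for rdx in range(n_readout):
                gE = np.where(on, gE_per_readout[rdx], 0.0)
                U[rdx] = train_one_period(
                    W[rdx], psp_T, psp_tilde_T, gE, gI,
                    neuron.g_L, neuron.g_D, neuron.E_E, neuron.E_I,
                    neuron.cap_ms, neuron.phi_max, plast.alpha, plast.eta, dt,
                    U[rdx],
                )
                _check_weights(W[rdx])
            return None
        # probe: no somatic drive, no learning
        silent = ConductanceSchedule.zeros(n_bins, dt)
        amps = np.empty(n_readout)
        for rdx in range(n_readout):
            V_w = psp_T @ W[rdx]
            Utr = integrate_soma(neuron, V_w, silent, dt, U0=float(U[rdx]))
            rate = firing_rate(Utr, neuron)
            amps[rdx] = float(np.mean(rate[probe_lo:delay_end_bin]))
        return amps

    labels = []
    for _ in range(config.n_training_periods):
        label = "A1" if rng_label.random() < 0.5 else "A2"
        labels.append(label)
        one_segment(label, g_by_label[label], learn=True)

    amplitudes = {lab: np.zeros(n_readout) for lab in ("A1", "A2")}
    for lab in ("A1", "A2"):
        for _ in range(n_probe):
            amplitudes[lab] += one_segment(lab, g_by_label[lab], learn=False)
        amplitudes[lab] /= n_probe

    metrics = {
        f"amp_neuron{r + 1}_{lab}": float(amplitudes[lab][r])
        for lab in ("A1", "A2") for r in range(n_readout)
    }
    history = {"labels": np.array([1 if l == "A1" else 2 for l in labels])}
    return ExperimentResult(W, None, None, metrics, history)


def run_recurrent_replay(config: ExperimentConfig) -> ExperimentResult:
    """Sequence learning in an all-to-all recurrent network.

    Groups of neurons receive sequential somatic pulses, repeated
    ``n_training_periods`` times; afterwards a brief stimulation of the
    first group triggers autonomous replay.  The learning rule stays on
    throughout (recall differs from training only in the somatic
    input); self-connections are fixed at zero.  Metrics: Kendall
    concordance of the group activation order during replay against the
    training order, and the compression factor (training sweep span /
    replay span).  If replay evokes no activity the metrics are NaN
    (undefined), not an error.
    """
    neuron, plast, dt = config.neuron, config.plasticity, config.dt
    sc = config.schedule
    n_groups = sc["n_groups"]
    group_size = sc["group_size"]
    pulse_ms = sc.get("pulse_ms", 100.0)
    g_E_on = sc.get("g_E", 20.0)
    recall_ms = sc.get("recall_ms", 20.0)
    recall_window = sc.get("recall_window", 800.0)
    gap_ms = sc.get("gap_ms", 1600.0)  # silent interval before the cue
    n_recall = sc.get("n_recall", 1)
    min_peak_rate = sc.get("min_peak_rate", 0.0002)  # kHz, replay detection
    onset_fraction = sc.get("onset_fraction", 0.3)  # of each group's own peak

    n = n_groups * group_size
    group_ids, gE_train = sequential_stimulation(
        n_groups, group_size, pulse_ms, g_E_on, dt, mode="train"
    )
    _, gE_recall = sequential_stimulation(
        n_groups, group_size, pulse_ms, g_E_on, dt, mode="recall",
        recall_ms=recall_ms, recall_window=recall_window, gap_ms=gap_ms,
    )
    W = np.zeros((n, n))
    am = np.zeros(n)
    asym = np.zeros(n)
    tilde = np.zeros(n)
    U = np.zeros(n)
    dm = float(np.exp(-dt / neuron.tau_m))
    dsn = float(np.exp(-dt / neuron.tau_s))
    seed_train, seed_recall = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(config.seed).spawn(2)
    ]
    n_sweeps = config.n_training_periods
    rates_train = np.zeros((gE_train.shape[0] * max(n_sweeps, 1), n_groups))
    if n_sweeps > 0:
        run_recurrent(
            W, gE_train, group_ids, n_sweeps, am, asym, tilde, U,
            neuron.g_L, neuron.g_D, neuron.E_E, neuron.cap_ms, neuron.phi_max,
            plast.alpha, plast.eta, plast.tau, dt, dm, dsn, neuron.kappa_norm,
            seed_train, rates_train,
        )
        _check_weights(W)
    seg_bins = gE_recall.shape[0]
    rates_recall = np.zeros((seg_bins * n_recall, n_groups))
    run_recurrent(
        W, gE_recall, group_ids, n_recall, am, asym, tilde, U,
        neuron.g_L, neuron.g_D, neuron.E_E, neuron.cap_ms, neuron.phi_max,
        plast.alpha, plast.eta, plast.tau, dt, dm, dsn, neuron.kappa_norm,
        seed_recall, rates_recall,
    )

    # PSTH over the cue(s); activation measured from cue onset.  The
    # activation time of a group is the first crossing of a fraction of
    # its own smoothed peak — robust to post-ignition reverberation,
    # which can displace the argmax peak
    cue_bin = int(round(gap_ms / dt))
    psth = rates_recall.reshape(n_recall, seg_bins, n_groups).mean(axis=0)
    smooth = gaussian_filter1d(psth[cue_bin:], sigma=5.0 / dt, axis=0)
    peak_bins = np.argmax(smooth, axis=0)
    peak_rates = smooth[peak_bins, np.arange(n_groups)]
    peak_times = peak_bins * dt
    onset_times = np.full(n_groups, np.nan)
    for g in range(n_groups):
        above = np.flatnonzero(smooth[:, g] >= onset_fraction * peak_rates[g])
        if above.size:
            onset_times[g] = above[0] * dt
    if np.any(peak_rates < min_peak_rate) or np.any(np.isnan(onset_times)):
        concordance, compression = np.nan, np.nan
    else:
        concordance = float(kendalltau(np.arange(n_groups), onset_times).statistic)
        replay_span = float(onset_times[-1] - onset_times[0])
        train_span = (n_groups - 1) * pulse_ms
        compression = train_span / replay_span if replay_span > 0 else np.nan
    metrics = {
        "order_concordance": concordance,
        "compression_factor": compression,
        "activation_times_ms": onset_times.tolist(),
        "peak_times_ms": peak_times.tolist(),
        "peak_rates_khz": peak_rates.tolist(),
    }
    history = {"rates_train": rates_train, "rates_recall": rates_recall}
    return ExperimentResult(W, None, None, metrics, history)


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Dispatch on the schedule kind."""
    kind = config.schedule.get("kind")
    if kind == "pulse":
        return run_ramp_experiment(config)
    if kind == "multiharmonic":
        return run_time_series_experiment(config)
    if kind == "paired":
        return run_paired_associate(config)
    if kind == "sequential":
        return run_recurrent_replay(config)
    raise ValueError(f"unknown schedule kind {kind!r}")
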