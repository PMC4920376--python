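# Methods

## Model

The neuron has two compartments. The dendritic potential is a weighted
sum of postsynaptic potentials,

    V_w(t) = sum_i w_i PSP_i(t),   PSP_i(t) = sum_{t_f} kappa(t - t_f),

with the normalised double-exponential spike-response kernel
`kappa(t) = c H(t) (e^{-t/tau_m} - e^{-t/tau_s})`, `tau_m = 10 ms`,
`tau_s = 10/3 ms`, `c = 1/(tau_m - tau_s)`. The somatic potential obeys

    C dU/dt = -g_L U + g_D (V_w - U) + g_E(t)(E_E - U) + g_I(t)(E_I - U),

with C = 1 nF, g_L = 100 nS, g_D = 1.8 uS, E_E = 14/3, E_I = -1/3
(potentials unitless, rest = 0; 0 maps to -70 mV and 1 to -55 mV).
Because the somatic relaxation time C/g_tot is ~0.5 ms, U is well
approximated by its quasi-static value `U = lam V* + U*` with the
nudging factor `lam = (g_L+g_D)/g_tot`, the attenuated dendritic
potential `V* = g_D V_w/(g_L+g_D)` and the attenuated somatic input
`U* = (g_E E_E + g_I E_I)/g_tot`. Spiking is an inhomogeneous Bernoulli
readout of the piecewise-linear transfer function
`phi(U) = phi_max clip(U, 0, 1)`, `phi_max = 0.06 kHz`; spikes do not
reset the potential.

## Learning rule

Dendritic weights follow

    dw_i/dt = eta [ alpha phi(U) PSPtilde_i - phi(V*) PSP_i ],

where `PSPtilde` is the PSP low-passed with time constant `tau`
(`tau = 0` recovers the Urbanczik–Senn rule when `alpha = 1`). The
extra filter widens the potentiation window; through the bootstrapping
of self-generated predictions the learned dendritic rate converges, for
periodic inputs, rich dendritic structure, constant `lam` and linear
`phi`, to the expected future discounted somatic input rate

    phi(V*(t)) = (alpha/tau) ∫_0^inf e^{-s/tau_eff} phi(U*)(t+s) ds,
    tau_eff = tau/(1 - lam alpha).

`alpha` must stay below `1/max_t lam(t)` for bounded weights. Three
depression variants are implemented (argument of the depression rate:
`V*` by default, `lam V*`, or raw `V_w`), with effective time constants
`tau/(1-lam alpha)`, `tau/(1-alpha)` and `tau/(1-lam_2 alpha)`
respectively (`lam_2 = g_D/g_tot`).

## Numerics

* Forward Euler with `dt = 0.1 ms` everywhere, with an explicit
  stability guard `dt g_tot / C < 1`; traces are bin-left aligned and a
  spike in bin `j` contributes to PSPs from bin `j+1` on (causal).
* PSPs are propagated by two exponential state variables per channel —
  the exact discrete solution of the double-exponential kernel, not a
  truncated convolution. For periodic inputs the states start at their
  closed-form periodic steady state, so late spikes wrap into the next
  period. The eligibility filter uses the exact exponential-smoothing
  recursion `y_k = q y_{k-1} + (1-q) x_k`, `q = e^{-dt/tau}`, and its
  state is carried across period/trial boundaries within a training run.
* The online training loops (weight update per 0.1 ms bin) are
  JIT-compiled with numba; probes and all analysis run in plain numpy.
* `periodic_fixed_point` evaluates the discounted-future integral by
  circularly folded trapezoid quadrature truncated where the kernel
  falls below 1e-8; `fourier_fixed_point` solves the same equation per
  Fourier mode and serves as an independent oracle (the two agree to
  ~1e-9 at dt = 0.01 ms on smooth inputs).
* Markov-chain geometric series are computed by linear solve with
  truncated-series cross-checks; the stationary distribution is
  recomputed by eigen-decomposition and validated rather than trusted.
  The mean-ODE integrator picks its Euler step as 0.2 / (spectral
  radius of the linearised update) unless overridden.

## Theory module conventions

The Markov-chain setting uses the *unnormalised* discrete eligibility
trace `PSPtilde_t = sum_s gamma^s PSP(X_{t-s})`, so the discounting
operator `A = alpha (I - gamma T)^{-1}` has row sums `alpha/(1-gamma)`
and convergence of the learned fixed point
`r_V = (I - lam A)^{-1} A r_I` requires `lam alpha < 1 - gamma`. When a
deterministic N-cycle with step `delta = dt` is compared against the
continuous periodic fixed point, the continuous potentiation factor
`alpha` maps to the per-step factor
`alpha_d = (1 - e^{-lam alpha dt/tau})/lam`, which makes
`gamma_eff = gamma/(1 - lam alpha_d)` equal `e^{-dt/tau_eff}` exactly.

For an affine transfer `phi(u) = a u + c` the fixed point derived here
is `r_V = (I - lam A)^{-1} A (r_I - lam c)`; the mean-ODE simulation
with affine transfer confirms this form (the `lam`-independent shift
`A (r_I - c)` only coincides with it at `lam = 1`).

TD(lambda) with linear value approximation converges to the same value
function when `gamma_TD = gamma_eff`, and uses the identical eligibility
trace when `lambda_TD gamma_TD = gamma`. The TD(1) comparison
initialises both rules at the exact value-function weights so that the
per-trajectory discrepancy isolates the non-cancelled telescoping
boundary term, which scales linearly with the learning rate.

## Synthetic inputs

The generators are pure functions of (parameters, seed).

* Orthogonal patterns: synapse `i` of `n` fires once per period at
  `i * T / n`. With >= 500 synapses on a 2 s period the spacing (4 ms)
  is well inside the ~30 ms PSP support, satisfying the richness
  condition for ramp learning.
* Frozen Poisson: one Bernoulli draw per bin, replayed every period.
* Inhomogeneous Poisson: fresh draws each trial from smooth random
  truncated-Fourier rate profiles (or piecewise-constant profiles,
  which are deliberately too poor in structure to support a smooth
  ramp).
* Short-term-memory traces: per-label template trajectories from a
  mean-zero OU process (`1/theta_1 = 1000 ms`), and per-trial rates
  relaxing toward `mu_s(t) = (1-sigma(t)) r^s(t) - sigma(t)/2` with
  `1/theta_2 = 100 ms` and noise variance quenched from 1 to 0.1 inside
  the stimulus window — stimulus onset quenches variability, so trials
  with the same label correlate strongly. **Units choice:** taking the
  noise scales literally as diffusion coefficients per sqrt(ms) gives
  the template process a stationary sd of ~22, far outside the linear
  range of `phi`; the default therefore interprets them as stationary
  variances (diffusion `sigma sqrt(2 theta)`), with
  `variance_mode="literal"` available. Integration is Euler–Maruyama at
  the global dt.
* Conductance schedules: terminal step pulses (g_E = 15 nS over the
  final 200 ms of a 2 s period unless configured otherwise), the fixed
  multi-harmonic waveform `g_E(t) = 6 (1 - sin wt sin 2wt cos 4wt) nS`,
  sequential group pulses, and per-trial probabilistic event masks.

These emulate the statistics the protocols need (richness, frozen
repetition, label-dependent memory traces) but none of the detailed
structure of biological spike trains (no refractoriness, bursting,
correlations between afferents); a passing suite shows the learning
mechanism behaves as the theory predicts under its stated assumptions,
not that it reproduces any recorded dataset.

## Protocols and default parameters

* Ramp protocols: period 2 s, somatic pulse in the final 200 ms,
  `tau = 9 ms`, `alpha = 0.985`. `alpha` is chosen by inverting the
  effective-time-constant relation for `tau_eff = 600 ms` at `lam = 1`.
  `eta = 50` for the sparse inputs (orthogonal one-spike patterns and
  2 Hz frozen trains, whose per-period drive is tiny), `eta = 0.5`
  otherwise. Probes silence the somatic input and freeze learning.
* The anticipatory ramp's time constant is measured by least-squares
  fit of a single exponential to the probe rate on
  `[event - 1200 ms, event)`; on the fixed-point curve itself this fit
  recovers `tau_eff` to better than 2%, so the fit window is not the
  accuracy bottleneck.
* Temporal advancement is the lag at the peak of the circular
  cross-correlation between `phi(U)` (probe with the schedule on) and
  `phi(U*)`, positive when learning leads.
* Paired associate: sample 500 ms, delay 1000 ms, target 200 ms,
  intertrial interval uniform 3–10 s; readout drives 5 nS (neurons 1, 3
  on target B1; neuron 2 on B2) and 2.5 nS (neuron 3 on B2); ramp
  amplitude = mean `phi(U)` over the final 200 ms of the delay on
  probe trials. The variance-quench window spans the whole trial.
* Recurrent replay: all-to-all network without autapses (self-weights
  pinned to 0), groups stimulated sequentially with 100 ms pulses of
  20 nS, learning active throughout; recall = 20 ms cue to group 1
  after a 1.6 s silent gap (without the gap the network still
  reverberates from training and the cue-locked cascade is
  contaminated). The discount horizon is matched to the sequence
  timescale: with a 100 ms inter-group interval the preset uses
  `tau_eff ~ 130 ms` (`alpha = 0.93`, `tau = 9 ms`), since a horizon
  much longer than the sweep makes the fixed point nearly constant in
  time and erases the order information; `eta = 5` so the weights form
  within 300 sweeps. Replay metrics: group *activation times* = first
  crossing of 30% of each group's own smoothed (5 ms Gaussian) recall
  peak — robust to post-ignition reverberation, which can displace the
  argmax peak; order concordance is the Kendall tau of these onsets
  against the training order and the compression factor is training
  span / onset span. An inactive replay (any group peak below
  0.2 Hz) reports NaN, not an error. Repeated-cue averaging is
  deliberately not used: with the rule always on and no somatic input,
  every replay event depresses the weights (the fixed point for zero
  input is zero dendritic rate), so repeated recalls erode the memory.
* "Ramp learned" is defined operationally as Pearson r >= 0.9 between
  the learned dendritic rate and the fixed-point prediction on the
  pre-event interval.

## Problem sizes

Default presets follow the protocol scales above (500–2000 afferents,
300–1000 training periods). The test suite and the reproduction script
run scaled-down instances (e.g. 500 synapses / 500 periods for the ramp
fit, 4 groups of 25 neurons for replay, a few hundred STM neurons) so
that a full run completes in minutes on one core; the scaling knobs are
ordinary config fields (`--scale` on the CLI).

## Known limitations

* The fixed-point theory assumes constant `lam`, quasi-static somatic
  potentials, linear transfer and functionally complete dendritic
  input; converged simulations track the theory curve with a few
  percent systematic residual (steeper effective decay), which is
  dt-independent and persists across input ensembles.  The dominant
  term is the somatic relaxation lag `C/g_tot ~ 0.5 ms` inside the
  bootstrap loop: the pre-event growth rate solves
  `r = (1 - alpha lam e^{-r C/g_tot})/tau`, i.e. `tau_eff ~ 565 ms`
  rather than 600 ms at the ramp defaults — near `alpha lam = 1` a
  half-millisecond lag shifts the effective time constant by several
  percent.
* Large learning rates (eta = 50 with dense input) can overshoot the
  linear range and saturate `phi`; the ramp shape (correlation) is
  robust to this, amplitudes are not.
* Nonlinear-transfer fixed points are only characterised to first
  order (affine shift); the module reports but does not certify them.
* The STM generator replaces a recurrent reservoir by a stochastic
  process; no recurrent dynamics are simulated in the paired-associate
  protocol.
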