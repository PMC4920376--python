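"""Analytic fixed points and convergence results.

These serve as independent oracles for the simulations:

* For deterministic periodic inputs the learned dendritic rate converges
  to the future somatic input rate discounted exponentially with
  ``tau_eff = tau / (1 - lam*alpha)``; :func:`periodic_fixed_point`
  evaluates that convolution in the time domain and
  :func:`fourier_fixed_point` solves the same equation per Fourier mode.
* For inputs driven by a stationary latent Markov chain the fixed point
  is a matrix geometric series; :func:`markov_fixed_point` solves it and
  :func:`mean_ode_trajectory` integrates the averaged weight dynamics,
  whose convergence is certified by a quadratic Lyapunov function.
* The fixed point coincides with the value function of TD(lambda) with
  linear function approximation when ``gamma_TD = gamma_eff``;
  :func:`td_lambda_learn` and :func:`td1_equivalence_check` make the
  correspondence executable.

Geometric series are computed by linear solve; truncated-sum
cross-checks (``*_series``) are provided for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from procode.plasticity import effective_time_constant

__all__ = [
    "ConvergenceError",
    "MarkovEnvironment",
    "TDParams",
    "stationary_distribution",
    "periodic_fixed_point",
    "fourier_fixed_point",
    "discount_operator",
    "discount_operator_series",
    "effective_discount",
    "markov_fixed_point",
    "markov_fixed_point_series",
    "mean_ode_trajectory",
    "value_function",
    "td_lambda_learn",
    "td1_equivalence_check",
]


class ConvergenceError(RuntimeError):
    """A discounted series or a learning trajectory diverges."""


def stationary_distribution(T: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix, by
    eigen-decomposition of ``T'`` (validated, not trusted from input)."""
    T = np.asarray(T, dtype=float)
    vals, vecs = np.linalg.eig(T.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = pi / pi.sum()
    if np.any(pi <= 0):
        raise ValueError("chain is not irreducible: stationary weights must be > 0")
    if np.max(np.abs(pi @ T - pi)) > tol:
        raise ValueError("failed to compute a valid stationary distribution")
    return pi


@dataclass
class MarkovEnvironment:
    """Latent Markov chain driving dendritic and somatic inputs.

    T : row-stochastic transition matrix (n_states x n_states).
    B : per-state PSP values, shape (n_states, n_synapses); row x holds
        the dendritic input pattern PSP_i(x).
    r_I : per-state somatic input rate phi(U*) (kHz).
    lam : constant nudging factor in (0, 1].
    gamma : per-step discount in [0, 1).
    delta : duration of one chain step (ms); links the discrete discount
        to continuous time via gamma = exp(-delta/tau).
    """

    T: np.ndarray
    B: np.ndarray
    r_I: np.ndarray
    lam: float = 1.0
    gamma: float = 0.5
    delta: float = 1.0
    pi: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.r_I = np.asarray(self.r_I, dtype=float)
        n = self.T.shape[0]
        if self.T.shape != (n, n):
            raise ValueError("T must be square")
        if np.max(np.abs(self.T.sum(axis=1) - 1.0)) > 1e-10 or np.any(self.T < 0):
            raise ValueError("T must be row-stochastic")
        if self.B.shape[0] != n or self.r_I.shape != (n,):
            raise ValueError("B and r_I must have one row/entry per state")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        self.pi = stationary_distribution(self.T)

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    @property
    def n_synapses(self) -> int:
        return self.B.shape[1]


@dataclass(frozen=True)
class TDParams:
    """TD(lambda) hyper-parameters."""

    gamma_TD: float
    lambda_TD: float = 1.0
    eta: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma_TD < 1.0:
            raise ValueError("gamma_TD must lie in (0, 1)")
        if not 0.0 <= self.lambda_TD <= 1.0:
            raise ValueError("lambda_TD must lie in [0, 1]")
        if not self.eta > 0:
            raise ValueError("eta must be positive")


# ---------------------------------------------------------------------------
# periodic environments


def periodic_fixed_point(
    phi_Ustar: np.ndarray,
    lam: float,
    alpha: float,
    tau: float,
    period: float,
    dt: float | None = None,
    truncation: float = 1e-8,
) -> np.ndarray:
    """Learned dendritic rate for a periodic somatic input rate.

    Evaluates ``f(t) = (alpha/tau) * int_0^inf exp(-s/tau_eff)
    phi_Ustar(t+s) ds`` (the expected future discounted somatic input
    rate, with ``tau_eff = tau/(1-lam*alpha)``) by wrapped discrete
    convolution, truncating the kernel where ``exp(-s/tau_eff) <
    truncation``.  Quadrature is trapezoidal on the sampling grid.
    """
    g = np.asarray(phi_Ustar, dtype=float)
    n = g.size
    if dt is None:
        dt = period / n
    if abs(n * dt - period) > 1e-9 * period:
        raise ValueError("period must equal len(phi_Ustar) * dt")
    if tau == 0.0:
        if lam * alpha >= 1.0:
            raise ValueError("lam*alpha >= 1: divergent fixed point")
        return (alpha / (1.0 - lam * alpha)) * g
    tau_eff = effective_time_constant(tau, lam, alpha)
    n_ker = int(np.ceil(-tau_eff * np.log(truncation) / dt)) + 1
    s = np.arange(n_ker) * dt
    w = np.exp(-s / tau_eff) * dt
    w[0] *= 0.5
    w[-1] *= 0.5
    w *= alpha / tau
    # fold the kernel onto one period and correlate circularly
    n_pad = int(np.ceil(n_ker / n)) * n
    w_fold = np.zeros(n_pad)
    w_fold[:n_ker] = w
    w_fold = w_fold.reshape(-1, n).sum(axis=0)
    f = np.fft.ifft(np.conj(np.fft.fft(w_fold)) * np.fft.fft(g))
    return np.real(f)


def fourier_fixed_point(
    phi_Ustar: np.ndarray,
    lam: float,
    alpha: float,
    tau: float,
    period: float,
) -> np.ndarray:
    """Same fixed point, solved mode by mode in Fourier space.

    Each mode of the somatic rate is scaled by ``(alpha/tau) / ((1 -
    alpha*lam)/tau - i 2 pi k / T)``; higher modes are attenuated, which
    is why the learned ramp is a smoothed, advanced copy of the input.
    """
    g = np.asarray(phi_Ustar, dtype=float)
    n = g.size
    if lam * alpha >= 1.0:
        raise ValueError("lam*alpha >= 1: divergent fixed point")
    if tau == 0.0:
        return (alpha / (1.0 - lam * alpha)) * g
    k = np.fft.fftfreq(n, d=1.0 / n)  # signed mode numbers
    denom = (1.0 - alpha * lam) / tau - 1j * 2.0 * np.pi * k / period
    f_hat = (alpha / tau) * np.fft.fft(g) / denom
    f = np.fft.ifft(f_hat)
    if np.max(np.abs(f.imag)) > 1e-10 * max(1.0, np.max(np.abs(f.real))):
        raise RuntimeError("inverse transform is not real within tolerance")
    return np.real(f)


# ---------------------------------------------------------------------------
# Markov-chain environments


def discount_operator(env: MarkovEnvironment, alpha: float) -> np.ndarray:
    """Discounting operator ``A = alpha * sum_t gamma^t T^t =
    alpha (I - gamma T)^{-1}``.  Every row of ``A`` sums to
    ``alpha / (1 - gamma)``."""
    n = env.n_states
    return alpha * np.linalg.solve(np.eye(n) - env.gamma * env.T, np.eye(n))


def discount_operator_series(
    env: MarkovEnvironment, alpha: float, tol: float = 1e-12
) -> np.ndarray:
    """Truncated-series evaluation of the discounting operator
    (cross-check oracle; truncation at ``gamma^t < tol``)."""
    n = env.n_states
    A = np.eye(n).copy()
    term = np.eye(n)
    g = 1.0
    while g >= tol:
        term = env.T @ term
        g *= env.gamma
        A += g * term
        if env.gamma == 0.0:
            break
    return alpha * A


def effective_discount(gamma: float, lam: float, alpha: float) -> float:
    """Effective discount factor ``gamma_eff = gamma / (1 - lam*alpha)``.

    Finite (< 1) exactly when ``lam * alpha < 1 - gamma``; approaches 1
    as ``alpha -> (1 - gamma)/lam``.
    """
    if lam * alpha >= 1.0 - gamma:
        raise ConvergenceError(
            f"lam*alpha = {lam * alpha} >= 1 - gamma = {1 - gamma}: series diverges"
        )
    return gamma / (1.0 - lam * alpha)


def markov_fixed_point(env: MarkovEnvironment, alpha: float) -> np.ndarray:
    """Per-state dendritic rate at the fixed point of learning,
    ``r_V = (I - lam A)^{-1} A r_I``.

    Requires ``lam * alpha < 1 - gamma`` (convergence of the implied
    geometric series with ratio ``gamma_eff``).
    """
    effective_discount(env.gamma, env.lam, alpha)  # validates convergence
    A = discount_operator(env, alpha)
    n = env.n_states
    return np.linalg.solve(np.eye(n) - env.lam * A, A @ env.r_I)


def markov_fixed_point_series(
    env: MarkovEnvironment, alpha: float, tol: float = 1e-12
) -> np.ndarray:
    """Equivalent series form ``(alpha/(1-lam*alpha)) * sum_t gamma_eff^t
    T^t r_I`` summed to truncation (independent cross-check)."""
    g_eff = effective_discount(env.gamma, env.lam, alpha)
    out = env.r_I.astype(float).copy()
    term = env.r_I.astype(float).copy()
    g = 1.0
    while g >= tol:
        term = env.T @ term
        g *= g_eff
        out += g * term
    return alpha / (1.0 - env.lam * alpha) * out


def _ode_system(env, alpha, eta, phi_slope, phi_intercept):
    """Matrices of the averaged weight dynamics ``dw/dt = X w + c``."""
    A = discount_operator(env, alpha)
    Pi = np.diag(env.pi)
    B = env.B
    I = np.eye(env.n_states)
    X = eta * phi_slope * B.T @ Pi @ (env.lam * A - I) @ B
    c = eta * B.T @ Pi @ (A @ env.r_I - phi_intercept * np.ones(env.n_states))
    return X, c


def mean_ode_trajectory(
    env: MarkovEnvironment,
    alpha: float,
    eta: float,
    w0: np.ndarray,
    n_steps: int,
    step: float | None = None,
    phi_slope: float = 1.0,
    phi_intercept: float = 0.0,
):
    """Euler integration of the averaged (mean-field) weight ODE.

    The rule averaged over the stationary chain reads ``dw/dt =
    eta B' Pi [A r_U - r_V]`` with ``r_V = phi_slope * B w +
    phi_intercept`` and ``r_U = lam r_V + r_I - lam * phi_intercept``
    (affine transfer, no clipping).  Returns ``(trajectory, L, w_star)``
    where ``L(w) = 0.5 ||w - w*||^2`` is a Lyapunov function of the flow
    and ``w*`` the orthogonal projection of ``w0`` onto the fixed-point
    set.  The default step keeps the spectral radius of the update map
    well below 1; a diverging iteration raises
    :class:`ConvergenceError`.
    """
    w = np.asarray(w0, dtype=float).copy()
    X, c = _ode_system(env, alpha, eta, phi_slope, phi_intercept)
    rho = float(np.max(np.abs(np.linalg.eigvals(X))))
    if step is None:
        step = 0.2 / rho if rho > 0 else 1.0
    X_pinv = np.linalg.pinv(X)
    w_star = -X_pinv @ c + (np.eye(w.size) - X_pinv @ X) @ w
    bound = 1e6 * (1.0 + np.linalg.norm(w) + np.linalg.norm(w_star))
    traj = np.empty((n_steps + 1, w.size))
    L = np.empty(n_steps + 1)
    traj[0] = w
    L[0] = 0.5 * float((w - w_star) @ (w - w_star))
    for k in range(1, n_steps + 1):
        w = w + step * (X @ w + c)
        if not np.all(np.isfinite(w)) or np.linalg.norm(w) > bound:
            raise ConvergenceError("mean-ODE iteration diverged: reduce the step size")
        traj[k] = w
        L[k] = 0.5 * float((w - w_star) @ (w - w_star))
    return traj, L, w_star


# ---------------------------------------------------------------------------
# TD(lambda) correspondence


def value_function(env: MarkovEnvironment, alpha: float, td: TDParams) -> np.ndarray:
    """Discounted value function ``V(x) = (alpha/(1-alpha*lam)) *
    sum_t gamma_TD^t E[phi(U*)(X_t) | X_0 = x]`` by matrix solve."""
    n = env.n_states
    scale = alpha / (1.0 - alpha * env.lam)
    return scale * np.linalg.solve(np.eye(n) - td.gamma_TD * env.T, env.r_I)


def _sample_chain(env: MarkovEnvironment, n_steps: int, rng: np.random.Generator):
    """Sample a state sequence of length ``n_steps + 1`` starting from pi."""
    cum = np.cumsum(env.T, axis=1)
    states = np.empty(n_steps + 1, dtype=np.int64)
    states[0] = rng.choice(env.n_states, p=env.pi)
    u = rng.random(n_steps)
    for t in range(n_steps):
        states[t + 1] = np.searchsorted(cum[states[t]], u[t], side="right")
    return states


def td_lambda_learn(
    env: MarkovEnvironment,
    alpha: float,
    td: TDParams,
    seed: int,
    n_steps: int,
    w0: np.ndarray | None = None,
    record_every: int = 1,
):
    """Online TD(lambda) with linear value approximation ``V_hat(x) =
    (B w)(x)``.

    Maintains the eligibility trace ``e_t = lambda_TD gamma_TD e_{t-1} +
    PSP(X_t)`` and applies ``dw = eta delta_t e_t`` with delta error
    ``delta_t = (alpha/(1-alpha*lam)) r_I(X_t) + gamma_TD V_hat(X_{t+1})
    - V_hat(X_t)``.  Returns ``(weights trajectory, deltas)``.
    """
    rng = np.random.default_rng(seed)
    states = _sample_chain(env, n_steps, rng)
    w = np.zeros(env.n_synapses) if w0 is None else np.asarray(w0, dtype=float).copy()
    e = np.zeros(env.n_synapses)
    scale = alpha / (1.0 - alpha * env.lam)
    n_rec = n_steps // record_every + 1
    traj = np.empty((n_rec, w.size))
    traj[0] = w
    deltas = np.empty(n_steps)
    j = 1
    for t in range(n_steps):
        x, x1 = states[t], states[t + 1]
        e = td.lambda_TD * td.gamma_TD * e + env.B[x]
        v = env.B @ w
        delta = scale * env.r_I[x] + td.gamma_TD * v[x1] - v[x]
        deltas[t] = delta
        w = w + td.eta * delta * e
        if (t + 1) % record_every == 0:
            traj[j] = w
            j += 1
    return traj[:j], deltas


def td1_equivalence_check(
    env: MarkovEnvironment,
    alpha: float,
    seed: int,
    n_steps: int,
    eta: float = 0.01,
    w0: np.ndarray | None = None,
) -> float:
    """Maximal weight discrepancy between the discrete prospective rule
    and TD(1) with the full-somatic-potential delta error.

    Both rules run side by side on the *same* chain realisation, from
    the same initial weights (default: the exact value-function weights,
    so the residual is dominated by the non-cancelled telescoping
    boundary term at the trajectory end, which scales linearly with
    ``eta``; the boundary pair at the start cancels exactly because the
    eligibility trace starts at zero).  Returns
    ``max_t || w_td(t) - w_pro(t) ||_inf``; exactly 0 for ``eta = 0``.
    """
    rng = np.random.default_rng(seed)
    states = _sample_chain(env, n_steps, rng)
    gamma = env.gamma
    if w0 is None:
        g_eff = effective_discount(gamma, env.lam, alpha)
        v_exact = value_function(env, alpha, TDParams(gamma_TD=g_eff, eta=1.0))
        w0 = np.linalg.lstsq(env.B, v_exact, rcond=None)[0]
    w_pro = np.asarray(w0, dtype=float).copy()
    w_td = w_pro.copy()
    psp_tilde = np.zeros(env.n_synapses)
    max_disc = 0.0
    for t in range(n_steps):
        x, x1 = states[t], states[t + 1]
        psp_tilde = gamma * psp_tilde + env.B[x]
        # each rule evaluates the postsynaptic terms with its own weights
        v_p = env.B @ w_pro
        r_u_p = env.lam * v_p[x] + env.r_I[x]
        w_pro = w_pro + eta * (alpha * r_u_p * psp_tilde - v_p[x] * env.B[x])
        v_t = env.B @ w_td
        r_u_t = env.lam * v_t[x] + env.r_I[x]
        delta = alpha * r_u_t + gamma * v_t[x1] - v_t[x]
        w_td = w_td + eta * delta * psp_tilde
        disc = float(np.max(np.abs(w_td - w_pro)))
        max_disc = max(max_disc, disc)
    return max_disc
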