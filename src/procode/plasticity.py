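"""The prospective-coding plasticity rule.

Dendritic weights evolve as

    dw_i/dt = eta * [ alpha * phi(U) * PSPtilde_i  -  phi(V*_w) * PSP_i ]

where ``PSPtilde`` is a low-pass filtered copy of the postsynaptic
potential (time constant ``tau``).  The extra filtering widens the
potentiation window beyond the PSP itself; together with the
bootstrapping of self-generated predictions this extends the effective
discount time constant from ``tau`` to ``tau / (1 - lam * alpha)``,
where ``lam`` is the somatic nudging factor.  In the limit ``tau -> 0``,
``alpha = 1`` the rule reduces to the Urbanczik--Senn rule (dendritic
prediction of *current* somatic firing), for which matched potentials
give exactly zero weight change.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from procode.core_model import NeuronParams, _exp_filter, firing_rate

__all__ = [
    "PlasticityParams",
    "SynapseState",
    "lowpass_psp",
    "weight_step",
    "effective_time_constant",
    "variant_time_constant",
    "stability_bound",
    "DEPRESSION_VARIANTS",
]

DEPRESSION_VARIANTS = ("attenuated_dendritic", "nudged_dendritic", "raw_dendritic")
POSTSYNAPTIC_MODES = ("rate", "spike")


@dataclass(frozen=True)
class PlasticityParams:
    """Learning-rule constants.

    alpha : potentiation factor; must stay below the inverse of the
        largest nudging factor to keep weights bounded.
    eta : learning rate.
    tau : eligibility low-pass time constant (ms); ``tau = 0`` makes
        ``PSPtilde = PSP``.
    depression_variant : which potential enters the depression term —
        ``attenuated_dendritic`` uses ``phi(V*_w)`` (default),
        ``nudged_dendritic`` uses ``phi(lam V*_w)``,
        ``raw_dendritic`` uses ``phi(V_w)``.
    postsynaptic_mode : ``rate`` uses ``phi(U)`` in the potentiation
        term; ``spike`` replaces it by a sampled spike indicator / dt.
    """

    alpha: float = 0.985
    eta: float = 0.5
    tau: float = 9.0
    depression_variant: str = "attenuated_dendritic"
    postsynaptic_mode: str = "rate"

    def __post_init__(self) -> None:
        if not self.eta > 0:
            raise ValueError("eta must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if self.depression_variant not in DEPRESSION_VARIANTS:
            raise ValueError(f"unknown depression variant {self.depression_variant!r}")
        if self.postsynaptic_mode not in POSTSYNAPTIC_MODES:
            raise ValueError(f"unknown postsynaptic mode {self.postsynaptic_mode!r}")


@dataclass
class SynapseState:
    """Weights plus the running PSP and low-pass PSP values per synapse."""

    weights: np.ndarray
    psp: np.ndarray
    psp_tilde: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.psp = np.asarray(self.psp, dtype=float)
        self.psp_tilde = np.asarray(self.psp_tilde, dtype=float)
        if not (self.weights.shape == self.psp.shape == self.psp_tilde.shape):
            raise ValueError("weights, psp and psp_tilde must have equal shapes")
        if np.any(self.psp < 0) or np.any(self.psp_tilde < 0):
            raise ValueError("PSP values must be non-negative")


def lowpass_psp(
    psp: np.ndarray,
    tau: float,
    dt: float,
    periodic: bool = False,
    zi: np.ndarray | None = None,
    return_state: bool = False,
):
    """Low-pass filter PSP(t) with kernel ``(1/tau) exp(-s/tau)``.

    Discretised as the exact exponential-smoothing recursion
    ``y[k] = q y[k-1] + (1-q) x[k]`` with ``q = exp(-dt/tau)`` (exact for
    input that is piecewise constant on bins).  ``tau = 0`` returns the
    input unchanged.  Filters along the last axis; with
    ``periodic=True`` the state starts at the periodic steady state,
    with ``zi`` it continues from a previous call (``return_state=True``
    hands the final filter state back).
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    x = np.asarray(psp, dtype=float)
    if tau == 0.0:
        return (x.copy(), np.zeros(x.shape[:-1] + (1,))) if return_state else x.copy()
    q = float(np.exp(-dt / tau))
    return _exp_filter(x, q, 1.0 - q, 0.0, periodic=periodic, zi=zi,
                       return_state=return_state)


def weight_step(
    state: SynapseState,
    U: float,
    V_star: float,
    p: PlasticityParams,
    neuron: NeuronParams,
    dt: float,
    post_spike: int | None = None,
    lam: float | None = None,
    V_w: float | None = None,
) -> SynapseState:
    """One explicit Euler step of the weight dynamics.

    In ``rate`` mode the potentiation term uses ``phi(U)``; in ``spike``
    mode it uses the sampled postsynaptic spike indicator divided by
    ``dt`` (same expectation).  The depression term is evaluated from
    the same time bin (synchronous update); its argument depends on
    ``depression_variant`` (see :class:`PlasticityParams`), for which
    the ``nudged``/``raw`` variants additionally need ``lam`` / ``V_w``.
    """
    if p.postsynaptic_mode == "spike":
        if post_spike is None:
            raise ValueError("spike mode requires the post_spike indicator")
        post = float(post_spike) / dt
    else:
        post = float(firing_rate(U, neuron))
    if p.depression_variant == "attenuated_dendritic":
        dep = float(firing_rate(V_star, neuron))
    elif p.depression_variant == "nudged_dendritic":
        if lam is None:
            raise ValueError("nudged_dendritic variant requires lam")
        dep = float(firing_rate(lam * V_star, neuron))
    else:  # raw_dendritic
        if V_w is None:
            raise ValueError("raw_dendritic variant requires V_w")
        dep = float(firing_rate(V_w, neuron))
    dw = dt * p.eta * (p.alpha * post * state.psp_tilde - dep * state.psp)
    return replace(state, weights=state.weights + dw)


def effective_time_constant(tau: float, lam: float, alpha: float) -> float:
    """Effective discount time constant ``tau_eff = tau / (1 - lam*alpha)``.

    Raises when ``lam * alpha >= 1`` (the discounted future diverges).
    """
    if lam * alpha >= 1.0:
        raise ValueError(f"lam*alpha = {lam * alpha} >= 1: divergent time constant")
    return tau / (1.0 - lam * alpha)


def variant_time_constant(
    tau: float, lam: float, lam2: float, alpha: float, variant: str
) -> float:
    """Effective time constant under the three depression variants.

    ``attenuated_dendritic`` -> tau/(1 - lam*alpha);
    ``nudged_dendritic``     -> tau/(1 - alpha), independent of lam;
    ``raw_dendritic``        -> tau/(1 - lam2*alpha) with lam2 = g_D/g_tot.
    """
    if variant == "attenuated_dendritic":
        factor = lam * alpha
    elif variant == "nudged_dendritic":
        factor = alpha
    elif variant == "raw_dendritic":
        factor = lam2 * alpha
    else:
        raise ValueError(f"unknown depression variant {variant!r}")
    if factor >= 1.0:
        raise ValueError("non-positive denominator: divergent time constant")
    return tau / (1.0 - factor)


def stability_bound(max_lambda: float) -> float:
    """Largest admissible potentiation factor, ``1 / max_t lam(t)``."""
    if not 0.0 < max_lambda <= 1.0:
        raise ValueError("max_lambda must lie in (0, 1]")
    return 1.0 / max_lambda
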