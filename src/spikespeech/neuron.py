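"""Discrete-time adaptive leaky integrate-and-fire (AdLIF) neuron dynamics.

The neuron is described by two dimensionless state variables: the membrane
potential ``u`` (threshold at 1, rest at 0) and an adaptation current ``w``.
Four constants characterize a neuron: the membrane time constant ``tau_u``,
the adaptation time constant ``tau_w``, the subthreshold coupling strength
``a`` and the spike-triggered adaptation increment ``b``.  With decay factors
``alpha = exp(-dt/tau_u)`` and ``beta = exp(-dt/tau_w)`` the exponential-Euler
update reads::

    u[t] = alpha * (u[t-1] - s[t-1]) + (1 - alpha) * (I[t] - w[t-1])
    w[t] = beta * (w[t-1] + b * s[t-1]) + (1 - beta) * a * u[t-1]
    s[t] = 1  if u[t] >= 1 else 0

Setting ``a = b = 0`` recovers the plain leaky integrate-and-fire (LIF)
neuron: the adaptation current then stays identically zero.

During gradient training the non-differentiable threshold is replaced by a
boxcar surrogate derivative (:func:`boxcar_surrogate`) on the backward pass.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TAU_U_RANGE",
    "TAU_W_RANGE",
    "A_RANGE",
    "B_RANGE",
    "NeuronParameters",
    "NeuronState",
    "DecayCoefficients",
    "adlif_step",
    "simulate_neuron",
    "boxcar_surrogate",
    "srm_kernels",
    "clamp_parameters",
    "subthreshold_matrix",
    "spectral_radius",
]

# Biologically plausible parameter boxes (ms for the time constants).
TAU_U_RANGE = (3.0, 25.0)
TAU_W_RANGE = (30.0, 350.0)
A_RANGE = (-0.5, 5.0)
B_RANGE = (0.0, 2.0)


def _as_float_array(x) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    return arr


@dataclass
class NeuronParameters:
    """Per-neuron AdLIF constants.

    All fields broadcast against each other, so scalar values describe a
    single neuron while 1-d arrays describe a population.  ``sfa_enabled``
    marks neurons with spike-frequency adaptation; where it is False the
    adaptation parameters ``a`` and ``b`` are forced to zero (LIF dynamics).
    """

    tau_u: np.ndarray  # membrane time constant, ms
    tau_w: np.ndarray  # adaptation time constant, ms
    a: np.ndarray  # subthreshold coupling, dimensionless
    b: np.ndarray  # spike-triggered increment, dimensionless
    sfa_enabled: np.ndarray = True

    def __post_init__(self) -> None:
        self.tau_u = _as_float_array(self.tau_u)
        self.tau_w = _as_float_array(self.tau_w)
        self.a = _as_float_array(self.a)
        self.b = _as_float_array(self.b)
        self.sfa_enabled = np.asarray(self.sfa_enabled, dtype=bool)

    def copy(self) -> "NeuronParameters":
        return NeuronParameters(
            self.tau_u.copy(), self.tau_w.copy(), self.a.copy(), self.b.copy(),
            self.sfa_enabled.copy(),
        )


@dataclass
class NeuronState:
    """Instantaneous neuron state (membrane potential, adaptation, spike)."""

    u: np.ndarray
    w: np.ndarray
    s: np.ndarray

    @classmethod
    def zeros(cls, shape=()) -> "NeuronState":
        return cls(np.zeros(shape), np.zeros(shape), np.zeros(shape))


@dataclass
class DecayCoefficients:
    """Exponential decay factors for a given simulation step ``dt`` (ms)."""

    alpha: np.ndarray
    beta: np.ndarray
    dt: float

    @classmethod
    def from_params(cls, params: NeuronParameters, dt: float) -> "DecayCoefficients":
        if dt <= 0:
            raise ValueError(f"simulation step must be positive, got dt={dt}")
        return cls(np.exp(-dt / params.tau_u), np.exp(-dt / params.tau_w), float(dt))


def _effective_ab(params: NeuronParameters):
    """Adaptation parameters with the SFA mask applied."""
    mask = np.asarray(params.sfa_enabled, dtype=float)
    return params.a * mask, params.b * mask


def adlif_step(
    state: NeuronState,
    stimulus,
    params: NeuronParameters,
    coeffs: DecayCoefficients,
) -> NeuronState:
    """One discrete AdLIF update; reads only previous-step state values."""
    stimulus = _as_float_array(stimulus)
    if not np.all(np.isfinite(stimulus)):
        raise ValueError("non-finite stimulus")
    a, b = _effective_ab(params)
    alpha, beta = coeffs.alpha, coeffs.beta
    u = alpha * (state.u - state.s) + (1.0 - alpha) * (stimulus - state.w)
    w = beta * (state.w + b * state.s) + (1.0 - beta) * a * state.u
    s = (u >= 1.0).astype(np.float64)
    return NeuronState(u, w, s)


def simulate_neuron(stimulus_series, params: NeuronParameters, dt: float):
    """Run the AdLIF recurrence from rest over a stimulus series.

    Returns ``(u_trace, w_trace, spike_train)`` of the same length as the
    stimulus, starting from ``u_0 = w_0 = s_0 = 0``.
    """
    stim = _as_float_array(stimulus_series)
    if stim.ndim != 1 or stim.size == 0:
        raise ValueError("stimulus series must be a nonempty 1-d sequence")
    if not np.all(np.isfinite(stim)):
        raise ValueError("non-finite stimulus")
    coeffs = DecayCoefficients.from_params(params, dt)
    state = NeuronState.zeros(np.broadcast(params.tau_u, params.a).shape)
    u_tr, w_tr, s_tr = [], [], []
    for it in stim:
        state = adlif_step(state, it, params, coeffs)
        u_tr.append(state.u)
        w_tr.append(state.w)
        s_tr.append(state.s)
    return np.array(u_tr), np.array(w_tr), np.array(s_tr)


def boxcar_surrogate(u_t):
    """Surrogate derivative of the spike threshold: 0.5 inside |u-1| <= 0.5."""
    u = _as_float_array(u_t)
    return np.where(np.abs(u - 1.0) <= 0.5, 0.5, 0.0)


def subthreshold_matrix(alpha: float, beta: float, a: float) -> np.ndarray:
    """Transition matrix of the spike-free linear (u, w) map."""
    return np.array([[alpha, -(1.0 - alpha)], [(1.0 - beta) * a, beta]])


def spectral_radius(alpha, beta, a):
    """Spectral radius of the 2x2 subthreshold map, vectorized over neurons."""
    alpha, beta, a = np.broadcast_arrays(
        _as_float_array(alpha), _as_float_array(beta), _as_float_array(a)
    )
    tr = alpha + beta
    det = alpha * beta + (1.0 - alpha) * (1.0 - beta) * a
    disc = tr * tr - 4.0 * det
    rho = np.where(
        disc >= 0,
        (np.abs(tr) + np.sqrt(np.maximum(disc, 0.0))) / 2.0,
        np.sqrt(np.maximum(det, 0.0)),
    )
    return rho


def clamp_parameters(
    params: NeuronParameters, dt: float = 2.0, stability_margin: float = 1e-3
) -> NeuronParameters:
    """Project parameters into their biological ranges (idempotent).

    Each constant is clipped to its box, the SFA mask is re-applied and, if
    the subthreshold two-variable map would be unstable (spectral radius
    >= 1), the coupling ``a`` is shrunk toward zero until stability holds.
    For simulation steps up to 5 ms the box is intrinsically stable and the
    shrinkage never triggers.
    """
    tau_u = np.clip(params.tau_u, *TAU_U_RANGE)
    tau_w = np.clip(params.tau_w, *TAU_W_RANGE)
    a = np.clip(params.a, *A_RANGE)
    b = np.clip(params.b, *B_RANGE)
    sfa = np.asarray(params.sfa_enabled, dtype=bool)
    a = np.where(sfa, a, 0.0)
    b = np.where(sfa, b, 0.0)

    alpha = np.exp(-dt / tau_u)
    beta = np.exp(-dt / tau_w)
    rho = spectral_radius(alpha, beta, a)
    unstable = rho >= 1.0 - stability_margin
    if np.any(unstable):
        # a = 0 is always stable (radius max(alpha, beta) < 1): bisect on the
        # shrink factor applied to a for the violating neurons.
        lo = np.zeros_like(a)
        hi = np.ones_like(a)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            ok = spectral_radius(alpha, beta, a * mid) < 1.0 - stability_margin
            lo = np.where(ok, mid, lo)
            hi = np.where(ok, hi, mid)
        a = np.where(unstable, a * lo, a)
    out = NeuronParameters(tau_u, tau_w, a, b, sfa)
    return out


def srm_kernels(params: NeuronParameters, dt: float, horizon: float):
    """Input-response and spike-response kernels of the equivalent SRM.

    The AdLIF neuron is equivalent to a spike response model whose two
    kernels are obtained by direct simulation from rest: the membrane
    response to (i) a unit input pulse at t = 0 and (ii) an emitted spike at
    t = 0 (exercising the reset and the spike-triggered adaptation).  Both
    are reported up to input scaling.

    Returns ``(times_ms, input_kernel, spike_kernel)``.
    """
    horizon = float(horizon)
    if horizon < float(np.max(params.tau_u)):
        raise ValueError("horizon must cover at least one membrane time constant")
    n = int(round(horizon / dt))
    stim = np.zeros(n)
    stim[0] = 1.0
    u_in, _, _ = simulate_neuron(stim, params, dt)

    # Response to an emitted spike: start from rest with s_0 = 1, no input.
    coeffs = DecayCoefficients.from_params(params, dt)
    state = NeuronState(np.zeros(()), np.zeros(()), np.ones(()))
    u_sp = []
    for _ in range(n):
        # suppress further threshold crossings so the kernel is the pure
        # linear response to the initial spike
        state = adlif_step(state, 0.0, params, coeffs)
        state = NeuronState(state.u, state.w, np.zeros(()))
        u_sp.append(float(state.u))
    times = np.arange(1, n + 1) * dt
    return times, np.asarray(u_in, dtype=float), np.asarray(u_sp, dtype=float)
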