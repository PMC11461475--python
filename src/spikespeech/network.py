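"""Layers of AdLIF/LIF neurons with masked feedforward and recurrent weights.

A layer receives binary spikes from the previous layer through a feedforward
matrix ``W`` and its own previous-step spikes through a recurrent matrix
``V`` (zero diagonal, no autapses):

    I[t] = W @ s_prev[t] + V @ s_own[t-1]

Fixed random binary masks limit the fraction of nonzero connections, a
second mask selects which neurons carry spike-frequency adaptation, and an
optional Dale's-law constraint forces every presynaptic neuron's outgoing
weights to share one sign (excitatory or inhibitory).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .neuron import (
    A_RANGE,
    B_RANGE,
    TAU_U_RANGE,
    TAU_W_RANGE,
    DecayCoefficients,
    NeuronParameters,
    NeuronState,
    adlif_step,
    clamp_parameters,
)

__all__ = [
    "LayerSpec",
    "SpikeRaster",
    "RegularizationConfig",
    "SpikingLayer",
    "layer_stimulus",
    "layer_forward",
    "apply_dale",
    "dale_signs",
    "firing_rates",
    "regularization_loss",
]


@dataclass
class LayerSpec:
    """Structural description of one spiking layer."""

    n_neurons: int
    ff_connectivity: float = 1.0
    rec_connectivity: float = 1.0
    sfa_fraction: float = 0.5
    dale: bool = False
    ei_ratio: float = 1.0  # excitatory:inhibitory odds; 1 -> half/half
    mask_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ff_connectivity", "rec_connectivity", "sfa_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class SpikeRaster:
    """Binary spike tensor over (utterance, time step, neuron).

    ``durations`` records each utterance's true duration in seconds, used for
    firing-rate computations on padded batches.
    """

    values: np.ndarray  # (B, T, N) in {0, 1}
    dt: float  # ms
    layer_id: str = ""
    durations: Optional[np.ndarray] = None  # (B,) seconds

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim == 2:
            self.values = self.values[None]
        if self.values.ndim != 3:
            raise ValueError("raster must have shape (utterance, time, neuron)")
        vals = np.unique(self.values)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("raster entries must be binary")
        if self.durations is None:
            b, t, _ = self.values.shape
            self.durations = np.full(b, t * self.dt / 1000.0)
        else:
            self.durations = np.asarray(self.durations, dtype=float)

    @property
    def n_utterances(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[2]


@dataclass
class RegularizationConfig:
    """Firing-rate regularization band; defaults keep rates between
    0.5 Hz and the simulation Nyquist frequency 1000/(2*dt_ms) Hz."""

    f_min: float = 0.5
    f_max: Optional[float] = None
    weight: float = 1.0

    def resolve_f_max(self, dt: float) -> float:
        return self.f_max if self.f_max is not None else 1000.0 / (2.0 * dt)


def dale_signs(n_neurons: int, ei_ratio: float, rng: np.random.Generator) -> np.ndarray:
    """Fixed +1/-1 outgoing-sign assignment under Dale's law.

    ``ei_ratio`` is the excitatory:inhibitory odds, so the excitatory count is
    ``ceil(N * r / (1 + r))`` (1 -> half/half, 0.33 -> one quarter excitatory),
    assigned to a seeded random subset of neurons.
    """
    n_exc = int(np.ceil(n_neurons * ei_ratio / (1.0 + ei_ratio)))
    signs = -np.ones(n_neurons)
    order = rng.permutation(n_neurons)
    signs[order[:n_exc]] = 1.0
    return signs


def apply_dale(W_raw: np.ndarray, presynaptic_signs: np.ndarray) -> np.ndarray:
    """Constrain column j (presynaptic neuron j) to the sign of signs[j]."""
    return np.abs(W_raw) * np.asarray(presynaptic_signs)[None, :]


class SpikingLayer:
    """One AdLIF/LIF layer with fixed masks and trainable weights/params.

    Masks, Dale signs and the SFA assignment are drawn once from
    ``spec.mask_seed`` and never change afterwards.  The effective weight
    matrices exposed by :attr:`W` and :attr:`V` always honor the masks, the
    zero recurrent diagonal and (if enabled) Dale's law, regardless of what
    the raw trainable arrays contain.
    """

    def __init__(self, n_inputs: int, spec: LayerSpec, dt: float,
                 input_signs: Optional[np.ndarray] = None,
                 weight_gain: float = 1.0):
        self.n_inputs = int(n_inputs)
        self.spec = spec
        self.dt = float(dt)
        rng = np.random.default_rng(spec.mask_seed)
        n = spec.n_neurons

        self.ff_mask = (rng.random((n, n_inputs)) < spec.ff_connectivity).astype(float)
        self.rec_mask = (rng.random((n, n)) < spec.rec_connectivity).astype(float)
        np.fill_diagonal(self.rec_mask, 0.0)

        n_sfa = int(round(spec.sfa_fraction * n))
        sfa = np.zeros(n, dtype=bool)
        sfa[rng.permutation(n)[:n_sfa]] = True
        self.sfa_mask = sfa

        self.signs = dale_signs(n, spec.ei_ratio, rng) if spec.dale else None
        self.input_signs = input_signs  # Dale signs of the presynaptic layer

        # Symmetric zero-mean init scaled by (masked) fan-in.
        ff_fan = max(1.0, spec.ff_connectivity * n_inputs)
        rec_fan = max(1.0, spec.rec_connectivity * n)
        self.W_raw = rng.normal(0.0, weight_gain / np.sqrt(ff_fan), (n, n_inputs))
        self.V_raw = rng.normal(0.0, weight_gain / np.sqrt(rec_fan), (n, n))

        self.params = NeuronParameters(
            tau_u=rng.uniform(*TAU_U_RANGE, n),
            tau_w=rng.uniform(*TAU_W_RANGE, n),
            a=rng.uniform(*A_RANGE, n),
            b=rng.uniform(*B_RANGE, n),
            sfa_enabled=sfa,
        )
        self.params = clamp_parameters(self.params, dt)

    @property
    def W(self) -> np.ndarray:
        w = self.W_raw
        if self.input_signs is not None:
            w = apply_dale(w, self.input_signs)
        return w * self.ff_mask

    @property
    def V(self) -> np.ndarray:
        v = self.V_raw
        if self.signs is not None:
            v = apply_dale(v, self.signs)
        return v * self.rec_mask

    def coefficients(self) -> DecayCoefficients:
        return DecayCoefficients.from_params(self.params, self.dt)


def layer_stimulus(prev_layer_spikes_t, own_spikes_tminus1, W, V):
    """Neuron stimulus I[t] = W @ s_prev[t] + V @ s_own[t-1]."""
    s_prev = np.asarray(prev_layer_spikes_t, dtype=float)
    s_own = np.asarray(own_spikes_tminus1, dtype=float)
    W = np.asarray(W)
    V = np.asarray(V)
    if W.shape[1] != s_prev.shape[-1] or V.shape[1] != s_own.shape[-1]:
        raise ValueError("weight/spike shape mismatch")
    return s_prev @ W.T + s_own @ V.T


def layer_forward(input_spikes: SpikeRaster, layer: SpikingLayer,
                  return_traces: bool = False):
    """Reference forward pass of one spiking layer over a raster.

    Evolves every neuron by the AdLIF recurrence with the stimulus from
    :func:`layer_stimulus`.  This is the plain float64 implementation used as
    the analysis surface and as the ground truth for the trainable pipeline.
    """
    if abs(input_spikes.dt - layer.dt) > 1e-9:
        raise ValueError(
            f"raster dt {input_spikes.dt} != layer dt {layer.dt}"
        )
    B, T, n_in = input_spikes.values.shape
    if n_in != layer.n_inputs:
        raise ValueError("input raster width does not match layer fan-in")
    W, V = layer.W, layer.V
    coeffs = layer.coefficients()
    params = layer.params
    n = layer.spec.n_neurons
    state = NeuronState.zeros((B, n))
    s_out = np.zeros((B, T, n))
    u_tr = np.zeros((B, T, n)) if return_traces else None
    w_tr = np.zeros((B, T, n)) if return_traces else None
    x = input_spikes.values.astype(float)
    for t in range(T):
        stim = layer_stimulus(x[:, t], state.s, W, V)
        state = adlif_step(state, stim, params, coeffs)
        s_out[:, t] = state.s
        if return_traces:
            u_tr[:, t] = state.u
            w_tr[:, t] = state.w
    raster = SpikeRaster(s_out.astype(np.uint8), dt=layer.dt,
                         layer_id="", durations=input_spikes.durations)
    if return_traces:
        return raster, u_tr, w_tr
    return raster


def firing_rates(raster: SpikeRaster) -> np.ndarray:
    """Per-utterance, per-neuron firing rates in Hz: spike count / duration."""
    if np.any(raster.durations <= 0):
        raise ValueError("utterance durations must be positive")
    counts = raster.values.sum(axis=1).astype(float)  # (B, N)
    return counts / raster.durations[:, None]


def regularization_loss(rates: Sequence[np.ndarray], cfg: RegularizationConfig,
                        dt: Optional[float] = None) -> float:
    """Hinge penalty keeping rates inside [f_min, f_max].

    ``rates`` is one (B, N_l) array per layer.  The loss averages over
    utterances and layers, with a per-layer average over neurons::

        (1 / (B L)) sum_b sum_l (1 / N_l) sum_n
            ReLU(f_min - f) + ReLU(f - f_max)
    """
    if len(rates) == 0:
        return 0.0
    f_max = cfg.resolve_f_max(dt) if cfg.f_max is None else cfg.f_max
    if cfg.f_max is None and dt is None:
        raise ValueError("dt required to resolve the Nyquist default f_max")
    B = rates[0].shape[0]
    L = len(rates)
    total = 0.0
    for r in rates:
        r = np.asarray(r, dtype=float)
        if np.any(r < 0):
            raise ValueError("rates must be non-negative")
        hinge = np.maximum(cfg.f_min - r, 0.0) + np.maximum(r - f_max, 0.0)
        total += hinge.mean(axis=1).sum()  # (1/N_l) sum_n, summed over b
    return float(total / (B * L))
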