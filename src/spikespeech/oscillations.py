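"""EEG-like population signals and phase-amplitude coupling (PAC) analysis.

A layer's binary spike trains are summed per time step into a population
signal (the model's analog of an EEG trace), z-scored over time, decomposed
into canonical frequency bands with zero-phase FIR filters, and tested for
phase-amplitude coupling: does the phase of a slow band (delta, theta,
alpha, beta) modulate the envelope of a fast band (low/high gamma)?

Two coupling metrics are computed — the Tort modulation index (normalized
KL divergence of the phase-binned amplitude profile) and the Canolty mean
vector length — and each is compared against a null distribution of
cut-and-swap surrogates of the amplitude series.  A coupling counts as
significant only when both metrics yield Gaussian-fit p-values below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps
from scipy import stats

from .network import SpikeRaster, firing_rates

__all__ = [
    "PopulationSignal",
    "FrequencyBand",
    "CouplingScenario",
    "PACResult",
    "DEFAULT_LOW_BANDS",
    "DEFAULT_HIGH_BANDS",
    "aggregate_population",
    "bandpass",
    "phase_and_envelope",
    "modulation_index",
    "mean_vector_length",
    "surrogate_distribution",
    "gaussian_p_value",
    "pac_metrics",
    "pac_test",
    "enumerate_scenarios",
    "coupling_report",
    "rate_distribution",
]


@dataclass
class FrequencyBand:
    name: str
    lo: float  # Hz
    hi: float  # Hz
    role: str  # "modulating" (phase) or "modulated" (amplitude)


DEFAULT_LOW_BANDS = [
    FrequencyBand("delta", 0.5, 4.0, "modulating"),
    FrequencyBand("theta", 4.0, 8.0, "modulating"),
    FrequencyBand("alpha", 8.0, 13.0, "modulating"),
    FrequencyBand("beta", 13.0, 30.0, "modulating"),
]
DEFAULT_HIGH_BANDS = [
    FrequencyBand("low-gamma", 30.0, 80.0, "modulated"),
    FrequencyBand("high-gamma", 80.0, 150.0, "modulated"),
]


@dataclass
class PopulationSignal:
    """Per-layer, per-utterance aggregated spiking activity."""

    raw: np.ndarray  # spike counts per time step
    normalized: np.ndarray  # z-scored over time
    dt: float  # ms
    layer_id: str = ""
    utterance_id: int = 0

    @property
    def fs(self) -> float:
        return 1000.0 / self.dt


@dataclass
class CouplingScenario:
    phase_layer: str
    amplitude_layer: str
    phase_band: FrequencyBand
    amplitude_band: FrequencyBand
    utterance_id: int = 0

    @property
    def intra(self) -> bool:
        return self.phase_layer == self.amplitude_layer


@dataclass
class PACResult:
    mi: float
    mvl: float
    p_mi: float
    p_mvl: float
    n_surrogates: int
    significant: bool
    rng_seed: Optional[int] = None


def aggregate_population(raster: SpikeRaster, utterance: int = 0) -> PopulationSignal:
    """Sum a single utterance's binary spike trains per step and z-score."""
    vals = raster.values
    if vals.shape[0] <= utterance:
        raise ValueError("utterance index out of range")
    raw = vals[utterance].sum(axis=1).astype(float)
    sd = raw.std()
    if sd == 0:
        raise ValueError("degenerate signal: population activity is constant")
    normalized = (raw - raw.mean()) / sd
    return PopulationSignal(raw, normalized, raster.dt, raster.layer_id, utterance)


def _design_fir(band: FrequencyBand, fs: float, n_samples: int,
                cycles: float = 3.0) -> np.ndarray:
    """Windowed-sinc band-pass; zero-phase application via filtfilt.

    The order covers at least `cycles` cycles of the band's low edge and is
    additionally long enough that the Hamming transition width stays below
    half the band's width (a short filter would leak neighboring-band
    rhythms into the passband and confound the coupling attribution).  The
    order is shortened if the signal cannot accommodate it (filtfilt needs
    3*numtaps < n).
    """
    if band.hi >= fs / 2.0:
        raise ValueError(
            f"band {band.name} upper edge {band.hi} Hz >= Nyquist {fs / 2} Hz"
        )
    by_cycles = int(round(cycles * fs / band.lo))
    # Hamming window transition width ~ 3.3 * fs / numtaps
    by_transition = int(round(3.3 * fs / (0.5 * (band.hi - band.lo))))
    desired = max(by_cycles, by_transition) | 1
    max_taps = (n_samples - 2) // 3
    if max_taps % 2 == 0:
        max_taps -= 1
    numtaps = min(desired, max_taps)
    min_taps = (int(round(fs / band.hi)) * 2 + 3) | 1
    if numtaps < min_taps:
        raise ValueError(
            f"signal of {n_samples} samples shorter than the filter span "
            f"needed for band {band.name}"
        )
    return sps.firwin(numtaps, [band.lo, band.hi], fs=fs, pass_zero=False)


def bandpass(signal_in, band: FrequencyBand, fs: Optional[float] = None,
             cycles: float = 3.0) -> np.ndarray:
    """Zero-phase FIR band-pass (forward-backward application)."""
    if isinstance(signal_in, PopulationSignal):
        x = signal_in.normalized
        fs = signal_in.fs
    else:
        x = np.asarray(signal_in, dtype=float)
        if fs is None:
            raise ValueError("fs required for plain array input")
    taps = _design_fir(band, fs, x.size, cycles)
    return sps.filtfilt(taps, [1.0], x)


def filter_halfspan(band: FrequencyBand, fs: float, n_samples: int,
                    cycles: float = 3.0) -> int:
    return _design_fir(band, fs, n_samples, cycles).size // 2


def phase_and_envelope(filtered_low: np.ndarray, filtered_high: np.ndarray):
    """Analytic-signal phase of the slow series, envelope of the fast one."""
    if len(filtered_low) != len(filtered_high):
        raise ValueError("phase and amplitude series must have equal length")
    phi = np.angle(sps.hilbert(filtered_low))
    amp = np.abs(sps.hilbert(filtered_high))
    return phi, amp


def _bin_indices(phi: np.ndarray, n_bins: int) -> np.ndarray:
    # bins over (-pi, pi]
    idx = np.ceil((phi + np.pi) / (2 * np.pi) * n_bins).astype(int) - 1
    return np.clip(idx, 0, n_bins - 1)


def modulation_index(phi: np.ndarray, amp: np.ndarray, n_bins: int = 18) -> float:
    """Tort modulation index: KL(P || uniform) / log(n_bins), P the
    normalized phase-binned mean amplitude profile."""
    if n_bins < 2:
        raise ValueError("need at least 2 phase bins")
    phi = np.asarray(phi, dtype=float)
    amp = np.asarray(amp, dtype=float)
    if phi.size == 0:
        raise ValueError("empty series")
    idx = _bin_indices(phi, n_bins)
    sums = np.bincount(idx, weights=amp, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    means = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    total = means.sum()
    if total <= 0:
        raise ValueError("all phase bins have zero mean amplitude")
    p = means / total
    nz = p > 0
    kl = np.log(n_bins) + float((p[nz] * np.log(p[nz])).sum())
    return kl / np.log(n_bins)


def mean_vector_length(phi: np.ndarray, amp: np.ndarray) -> float:
    """Canolty mean vector length |mean(A * exp(i*phi))|."""
    phi = np.asarray(phi, dtype=float)
    amp = np.asarray(amp, dtype=float)
    if phi.size == 0:
        raise ValueError("empty series")
    return float(np.abs(np.mean(amp * np.exp(1j * phi))))


def surrogate_distribution(phi: np.ndarray, amp: np.ndarray, n: int = 10000,
                           rng_seed: Optional[int] = None, n_bins: int = 18):
    """Cut-and-swap null: cut the amplitude series at a random interior
    point, swap the two segments, recompute both metrics against the
    unchanged phase series.  Returns (mi_samples, mvl_samples)."""
    phi = np.asarray(phi, dtype=float)
    amp = np.asarray(amp, dtype=float)
    T = phi.size
    if T < 4:
        raise ValueError("series too short for surrogates")
    rng = np.random.default_rng(rng_seed)
    cuts = rng.integers(1, T, size=n)
    rolled = amp[(np.arange(T)[None, :] + cuts[:, None]) % T]  # (n, T)

    idx = _bin_indices(phi, n_bins)
    ind = np.zeros((n_bins, T))
    ind[idx, np.arange(T)] = 1.0
    counts = ind.sum(axis=1)
    sums = rolled @ ind.T  # (n, n_bins)
    means = np.divide(sums, counts[None, :],
                      out=np.zeros_like(sums), where=counts[None, :] > 0)
    totals = means.sum(axis=1, keepdims=True)
    p = means / totals
    plogp = np.where(p > 0, p * np.log(np.maximum(p, 1e-300)), 0.0)
    mi = (np.log(n_bins) + plogp.sum(axis=1)) / np.log(n_bins)

    phasor = np.exp(1j * phi)
    mvl = np.abs(rolled @ phasor) / T
    return mi, mvl


def gaussian_p_value(observed: float, surrogate_samples: np.ndarray) -> float:
    """Upper-tail probability of the observed value under a Gaussian fitted
    (by moments) to the surrogate distribution."""
    s = np.asarray(surrogate_samples, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 surrogate samples")
    mu, sd = s.mean(), s.std(ddof=1)
    if sd == 0:
        raise ValueError("surrogate distribution has zero spread")
    return float(stats.norm.sf((observed - mu) / sd))


def pac_metrics(phase_signal: PopulationSignal, amp_signal: PopulationSignal,
                phase_band: FrequencyBand, amp_band: FrequencyBand,
                n_surrogates: int = 10000, rng_seed: Optional[int] = None,
                n_bins: int = 18, alpha: float = 0.05) -> PACResult:
    """Full PAC test between two population signals for one band pair."""
    fs = phase_signal.fs
    low = bandpass(phase_signal, phase_band)
    high = bandpass(amp_signal, amp_band)
    phi, amp = phase_and_envelope(low, high)
    trim = max(
        filter_halfspan(phase_band, fs, phase_signal.normalized.size),
        filter_halfspan(amp_band, fs, amp_signal.normalized.size),
    )
    if phi.size - 2 * trim < 4:
        raise ValueError("signal too short after trimming filter transients")
    sl = slice(trim, phi.size - trim)
    phi, amp = phi[sl], amp[sl]
    mi = modulation_index(phi, amp, n_bins)
    mvl = mean_vector_length(phi, amp)
    mi_s, mvl_s = surrogate_distribution(phi, amp, n_surrogates, rng_seed, n_bins)
    p_mi = gaussian_p_value(mi, mi_s)
    p_mvl = gaussian_p_value(mvl, mvl_s)
    return PACResult(mi, mvl, p_mi, p_mvl, n_surrogates,
                     bool(p_mi < alpha and p_mvl < alpha), rng_seed)


def pac_test(scenario: CouplingScenario,
             signals: Dict[Tuple[str, int], PopulationSignal],
             n_surrogates: int = 10000,
             rng_seed: Optional[int] = None) -> PACResult:
    """Run the PAC test for one coupling scenario against a signal set keyed
    by (layer_id, utterance_id)."""
    key_p = (scenario.phase_layer, scenario.utterance_id)
    key_a = (scenario.amplitude_layer, scenario.utterance_id)
    if key_p not in signals or key_a not in signals:
        raise KeyError(f"missing population signals for scenario {scenario}")
    return pac_metrics(signals[key_p], signals[key_a],
                       scenario.phase_band, scenario.amplitude_band,
                       n_surrogates, rng_seed)


def enumerate_scenarios(populations: Sequence[str],
                        low_bands: Sequence[FrequencyBand] = tuple(DEFAULT_LOW_BANDS),
                        high_bands: Sequence[FrequencyBand] = tuple(DEFAULT_HIGH_BANDS),
                        utterance_ids: Sequence[int] = (0,)) -> List[CouplingScenario]:
    """All intra-layer couplings plus inter-layer ones where the amplitude
    layer lies strictly downstream of the phase layer, crossed with every
    (low band, high band) pair and utterance.

    ``populations`` must be ordered from the nerve upwards.
    """
    if isinstance(populations, int):
        populations = [f"pop{i}" for i in range(populations)]
    relations = [(p, p) for p in populations]
    relations += [(a, b) for a, b in combinations(populations, 2)]
    out = []
    for utt in utterance_ids:
        for ph, am in relations:
            for lb in low_bands:
                for hb in high_bands:
                    out.append(CouplingScenario(ph, am, lb, hb, utt))
    return out


def coupling_report(results: Sequence[Tuple[CouplingScenario, PACResult]]) -> dict:
    """Tabulate significant couplings by relation type, layer pair and bands."""
    n_intra = 0
    n_inter = 0
    by_pair: Dict[str, int] = {}
    by_bands: Dict[str, int] = {}
    for scen, res in results:
        if not res.significant:
            continue
        if scen.intra:
            n_intra += 1
        else:
            n_inter += 1
        pair = f"{scen.phase_layer}->{scen.amplitude_layer}"
        bands = f"{scen.phase_band.name}/{scen.amplitude_band.name}"
        by_pair[pair] = by_pair.get(pair, 0) + 1
        by_bands[bands] = by_bands.get(bands, 0) + 1
    return {
        "n_scenarios": len(results),
        "n_significant": n_intra + n_inter,
        "n_intra": n_intra,
        "n_inter": n_inter,
        "by_layer_pair": by_pair,
        "by_band_pair": by_bands,
    }


def rate_distribution(raster: SpikeRaster, bin_edges) -> np.ndarray:
    """Histogram of single-neuron firing rates over the given Hz bin edges."""
    rates = firing_rates(raster).ravel()
    hist, _ = np.histogram(rates, bins=np.asarray(bin_edges, dtype=float))
    return hist
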