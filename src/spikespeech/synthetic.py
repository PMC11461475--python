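"""Synthetic data generators.

Everything the rest of the package consumes can be generated here at desk
scale: coupled-oscillation signals with known phase-amplitude coupling for
validating the PAC statistics, Bernoulli spike rasters with controlled
rates, a tone-sequence corpus that stands in for phoneme-labeled speech
(each "utterance" concatenates pure tones whose symbol sequence plays the
role of the phonetic transcript), and noise inputs (uniform white noise and
babble-like amplitude-modulated narrowband noise).  Every generator is
deterministic given its seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .network import SpikeRaster

__all__ = [
    "PACGenSpec",
    "ToneTaskSpec",
    "gen_pac_signal",
    "gen_poisson_raster",
    "gen_tone_corpus",
    "gen_noise_inputs",
    "write_corpus",
]


@dataclass
class PACGenSpec:
    """Coupled-oscillation signal with known theta->gamma-style PAC.

    The slow modulator is a narrowband stochastic oscillation (band-limited
    Gaussian noise of width ``bandwidth`` around ``f_phase``) rather than a
    strict sinusoid, for two reasons grounded in how the surrogate test
    works: a perfectly periodic modulator (i) makes cut-and-swap surrogates
    blind to the planted coupling — a circular shift of a periodic envelope
    only moves the preferred phase, which neither PAC metric distinguishes —
    and (ii) has a zero-width spectral line whose filtered phase stays
    coherent over the whole record, inflating the surrogate null.  The
    band-limited modulator decorrelates over ~1/bandwidth seconds and puts
    no power outside its own band, so the planted coupling is attributed to
    the right frequency pair.  The background noise is pink (1/f), as in
    EEG-like recordings.
    """

    f_phase: float = 6.0  # Hz, slow modulator center (e.g. theta)
    f_amp: float = 55.0  # Hz, fast carrier (e.g. low gamma)
    depth: float = 1.0  # modulation depth in [0, 1]
    snr_db: float = 10.0  # additive-noise level
    fs: float = 500.0  # Hz
    duration: float = 5.0  # s
    bandwidth: float = 2.0  # Hz, modulator band width
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.f_phase < self.f_amp < self.fs / 2:
            raise ValueError("need f_phase < f_amp < fs/2")
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError("modulation depth must lie in [0, 1]")
        if not 0.0 < self.bandwidth < 2 * self.f_phase:
            raise ValueError("modulator bandwidth must be positive and < 2*f_phase")


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance 1/f Gaussian noise (EEG-like background)."""
    f = np.fft.rfftfreq(n, 1.0 / fs)
    f[0] = f[1] if f.size > 1 else 1.0
    spec = (rng.normal(size=f.size) + 1j * rng.normal(size=f.size)) / np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def gen_pac_signal(spec: PACGenSpec):
    """Generate x(t) = (1 + depth*cos(phi)) * cos(2*pi*f_amp*t) + cos(phi)
    + pink noise at the requested SNR, where phi is the analytic phase of a
    band-limited slow oscillation centered at f_phase.

    Returns ``(x, phi, envelope)``: the wrapped modulator phase and the
    planted gamma envelope are ground truth for oracle checks.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.fs * spec.duration))
    t = np.arange(n) / spec.fs
    lo = spec.f_phase - spec.bandwidth / 2.0
    hi = spec.f_phase + spec.bandwidth / 2.0
    numtaps = min(2001, ((n - 2) // 3) | 1)
    taps = sps.firwin(numtaps, [lo, hi], fs=spec.fs, pass_zero=False)
    slow = sps.filtfilt(taps, [1.0], rng.normal(size=n))
    phi = np.angle(sps.hilbert(slow))
    envelope = 1.0 + spec.depth * np.cos(phi)
    clean = envelope * np.cos(2 * np.pi * spec.f_amp * t) + np.cos(phi)
    p_sig = np.mean(clean ** 2)
    sigma = np.sqrt(p_sig / (10.0 ** (spec.snr_db / 10.0)))
    x = clean + sigma * _pink_noise(rng, n, spec.fs)
    return x, phi, envelope


def gen_poisson_raster(rate: float, n_neurons: int, duration: float,
                       dt: float, seed: int = 0,
                       layer_id: str = "poisson") -> SpikeRaster:
    """Independent Bernoulli(rate*dt) spikes per step and neuron."""
    p = rate * dt / 1000.0
    if p > 1.0:
        raise ValueError(
            f"rate {rate} Hz exceeds one spike per {dt} ms step"
        )
    rng = np.random.default_rng(seed)
    T = int(round(duration * 1000.0 / dt))
    values = (rng.random((1, T, n_neurons)) < p).astype(np.uint8)
    return SpikeRaster(values, dt=dt, layer_id=layer_id)


@dataclass
class ToneTaskSpec:
    """Desk-scale CTC corpus: tone sequences with symbol transcripts."""

    n_symbols: int = 4
    tone_freqs: Optional[Sequence[float]] = None  # Hz, one per symbol
    seq_len_range: Tuple[int, int] = (2, 5)  # tokens per utterance
    tone_dur_range: Tuple[float, float] = (60.0, 100.0)  # ms
    noise_floor_db: float = -30.0  # additive noise relative to tone power
    fs: float = 16000.0
    n_utterances: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tone_freqs is None:
            # log-spaced, well separated on the Mel axis, below Nyquist
            self.tone_freqs = [400.0 * 2 ** i for i in range(self.n_symbols)]
        if len(set(self.tone_freqs)) != self.n_symbols:
            raise ValueError("tone frequencies must be distinct")
        if max(self.tone_freqs) >= self.fs / 2:
            raise ValueError("tone frequencies must lie below Nyquist")

    @property
    def tokens(self) -> List[str]:
        return [f"t{i}" for i in range(self.n_symbols)]


def _tone(freq: float, n: int, fs: float, amplitude: float = 0.8) -> np.ndarray:
    # headroom below full scale so tone + noise floor survives 16-bit WAV
    t = np.arange(n) / fs
    x = amplitude * np.sin(2 * np.pi * freq * t)
    ramp = min(n // 4, int(0.005 * fs))
    if ramp > 0:
        env = np.ones(n)
        env[:ramp] = np.linspace(0, 1, ramp)
        env[-ramp:] = np.linspace(1, 0, ramp)
        x = x * env
    return x


def gen_tone_corpus(spec: ToneTaskSpec):
    """Generate the corpus in memory.

    Returns ``(utterances, token_inventory)`` with utterances a list of
    ``(waveform, symbol_indices)``; symbol index i corresponds to token
    ``t{i-1}`` (index 0 is reserved for the CTC blank).
    """
    rng = np.random.default_rng(spec.seed)
    utts = []
    pad = int(0.05 * spec.fs)  # 50 ms of near-silence at each end
    for _ in range(spec.n_utterances):
        n_tok = int(rng.integers(spec.seq_len_range[0], spec.seq_len_range[1] + 1))
        symbols = rng.integers(0, spec.n_symbols, size=n_tok)
        pieces = [np.zeros(pad)]
        for s in symbols:
            dur = rng.uniform(*spec.tone_dur_range)
            n = int(round(dur * spec.fs / 1000.0))
            pieces.append(_tone(spec.tone_freqs[s], n, spec.fs))
            gap = int(rng.uniform(5.0, 20.0) * spec.fs / 1000.0)
            pieces.append(np.zeros(gap))
        pieces.append(np.zeros(pad))
        wave = np.concatenate(pieces)
        noise_amp = np.sqrt(0.5) * 10.0 ** (spec.noise_floor_db / 20.0)
        wave = wave + rng.normal(0.0, noise_amp, wave.size)
        labels = [int(s) + 1 for s in symbols]  # 0 is the blank
        utts.append((wave, labels))
    return utts, spec.tokens


def gen_noise_inputs(kind: str, duration: float, fs: float = 16000.0,
                     seed: int = 0) -> np.ndarray:
    """Noise waveforms for out-of-distribution probing.

    ``uniform``: white noise uniform in [-1, 1].  ``babble``: a sum of
    amplitude-modulated narrowband processes in the voiced band, emulating
    the slow temporal envelope structure of overlapping talkers without any
    symbolic content.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    if kind == "uniform":
        return rng.uniform(-1.0, 1.0, n)
    if kind == "babble":
        out = np.zeros(n)
        t = np.arange(n) / fs
        centers = [300.0, 600.0, 1200.0, 2400.0, 3600.0]
        for c in centers:
            band = rng.normal(0.0, 1.0, n)
            sos = sps.butter(4, [c * 0.7, c * 1.3], btype="band", fs=fs, output="sos")
            band = sps.sosfilt(sos, band)
            fm = rng.uniform(2.0, 6.0)
            phase = rng.uniform(0, 2 * np.pi)
            out += band * (1.0 + np.cos(2 * np.pi * fm * t + phase))
        out /= np.max(np.abs(out))
        return out
    raise ValueError(f"unknown noise kind: {kind!r}")


def write_corpus(utts, tokens: List[str], out_dir: str, fs: float = 16000.0) -> None:
    """Write WAVs, a transcript file and the token inventory to a directory."""
    from .dataio import save_wav, write_token_inventory, write_transcripts

    os.makedirs(out_dir, exist_ok=True)
    lines = []
    inv = {tok: i + 1 for i, tok in enumerate(tokens)}
    rev = {i + 1: tok for i, tok in enumerate(tokens)}
    for i, (wave, labels) in enumerate(utts):
        name = f"utt_{i:04d}"
        save_wav(os.path.join(out_dir, name + ".wav"), wave, fs)
        lines.append((name, [rev[l] for l in labels]))
    write_transcripts(os.path.join(out_dir, "transcripts.txt"), lines)
    write_token_inventory(os.path.join(out_dir, "tokens.txt"), tokens)
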