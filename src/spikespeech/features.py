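"""Log-Mel filterbank frontend.

Frames a 16 kHz mono waveform with a 25 ms window and a small hop (1, 2 or
5 ms), takes the power spectrum and applies a bank of 80 triangular Mel
filters spanning 0-8 kHz, followed by log compression.  A 2 ms hop turns the
16 kHz waveform into a 500 Hz, 80-bin spectrogram, which also fixes the
simulation time step of the downstream spiking layers.
"""

from __future__ import annotations

import numpy as np

__all__ = ["mel_filterbank", "extract_features", "frame_rate_hz"]


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, fs: float,
                   f_lo: float = 0.0, f_hi: float | None = None) -> np.ndarray:
    """Triangular Mel filters as an (n_mels, n_fft//2 + 1) matrix."""
    if f_hi is None:
        f_hi = fs / 2.0
    pts = _mel_to_hz(np.linspace(_hz_to_mel(f_lo), _hz_to_mel(f_hi), n_mels + 2))
    bins = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    fb = np.zeros((n_mels, bins.size))
    for m in range(n_mels):
        lo, ctr, hi = pts[m], pts[m + 1], pts[m + 2]
        up = (bins - lo) / max(ctr - lo, 1e-12)
        down = (hi - bins) / max(hi - ctr, 1e-12)
        fb[m] = np.maximum(0.0, np.minimum(up, down))
    return fb


def mel_centers(n_mels: int, fs: float, f_lo: float = 0.0,
                f_hi: float | None = None) -> np.ndarray:
    """Center frequency (Hz) of each Mel filter."""
    if f_hi is None:
        f_hi = fs / 2.0
    pts = _mel_to_hz(np.linspace(_hz_to_mel(f_lo), _hz_to_mel(f_hi), n_mels + 2))
    return pts[1:-1]


def frame_rate_hz(hop_ms: float) -> float:
    return 1000.0 / hop_ms


def extract_features(waveform, fs: float = 16000.0, n_mels: int = 80,
                     win_ms: float = 25.0, hop_ms: float = 2.0,
                     eps: float = 1e-10) -> np.ndarray:
    """Log-Mel spectrogram of a mono waveform, shape (frames, n_mels)."""
    x = np.asarray(waveform, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("waveform must be mono (1-d)")
    win = int(round(win_ms * fs / 1000.0))
    hop = int(round(hop_ms * fs / 1000.0))
    if x.size < win:
        raise ValueError(
            f"waveform too short: {x.size / fs * 1000:.1f} ms < one "
            f"{win_ms:.0f} ms analysis window"
        )
    n_frames = 1 + (x.size - win) // hop
    n_fft = int(2 ** np.ceil(np.log2(win)))
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * np.hanning(win)[None, :]
    power = np.abs(np.fft.rfft(frames, n_fft, axis=1)) ** 2
    fb = mel_filterbank(n_mels, n_fft, fs)
    return np.log(power @ fb.T + eps)
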