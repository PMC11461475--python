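"""File formats: WAV audio, transcripts, token inventories, spike rasters.

Audio is 16 kHz mono PCM WAV.  Transcripts are plain text, one utterance per
line: the utterance id followed by whitespace-separated tokens.  The token
inventory maps tokens to integer indices with index 0 reserved for the CTC
blank.  Spike rasters serialize to a sparse event-list text format: a JSON
header line followed by one "t n" pair per spike; the round trip is
lossless.
"""

from __future__ import annotations

import json
import os
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.io import wavfile

from .network import SpikeRaster

__all__ = [
    "save_wav",
    "load_wav",
    "write_transcripts",
    "read_transcripts",
    "write_token_inventory",
    "read_token_inventory",
    "load_corpus",
    "save_raster",
    "load_raster",
]


def save_wav(path: str, waveform: np.ndarray, fs: float = 16000.0) -> None:
    x = np.clip(np.asarray(waveform, dtype=np.float64), -1.0, 1.0)
    wavfile.write(path, int(fs), (x * 32767.0).astype(np.int16))


def load_wav(path: str) -> Tuple[np.ndarray, float]:
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio")
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32767.0
    else:
        data = data.astype(np.float64)
    return data, float(fs)


def write_transcripts(path: str, lines: Sequence[Tuple[str, Sequence[str]]]) -> None:
    with open(path, "w") as fh:
        for utt_id, tokens in lines:
            fh.write(utt_id + " " + " ".join(tokens) + "\n")


def read_transcripts(path: str) -> List[Tuple[str, List[str]]]:
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if parts:
                out.append((parts[0], parts[1:]))
    return out


def write_token_inventory(path: str, tokens: Sequence[str]) -> None:
    """Token -> index map; index 0 is the CTC blank (bit-exact contract)."""
    with open(path, "w") as fh:
        fh.write("<blank> 0\n")
        for i, tok in enumerate(tokens):
            fh.write(f"{tok} {i + 1}\n")


def read_token_inventory(path: str) -> Dict[str, int]:
    inv: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            tok, idx = line.split()
            inv[tok] = int(idx)
    if inv.get("<blank>", 0) != 0:
        raise ValueError("token inventory must reserve index 0 for the blank")
    return inv


def load_corpus(data_dir: str) -> Tuple[List[Tuple[np.ndarray, List[int]]], Dict[str, int]]:
    """Read a corpus directory (WAVs + transcripts.txt + tokens.txt)."""
    inv = read_token_inventory(os.path.join(data_dir, "tokens.txt"))
    utts = []
    for utt_id, tokens in read_transcripts(os.path.join(data_dir, "transcripts.txt")):
        wave, _ = load_wav(os.path.join(data_dir, utt_id + ".wav"))
        utts.append((wave, [inv[t] for t in tokens]))
    return utts, inv


def save_raster(path: str, raster: SpikeRaster, utterance: int = 0) -> None:
    """Write one utterance of a raster as a sparse (t, n) event list."""
    vals = raster.values[utterance]
    header = {
        "dt_ms": raster.dt,
        "n_steps": int(vals.shape[0]),
        "n_neurons": int(vals.shape[1]),
        "duration_s": float(raster.durations[utterance]),
        "layer_id": raster.layer_id,
    }
    ts, ns = np.nonzero(vals)
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        for t, n in zip(ts, ns):
            fh.write(f"{t} {n}\n")


def load_raster(path: str) -> SpikeRaster:
    with open(path) as fh:
        header = json.loads(fh.readline())
        vals = np.zeros((1, header["n_steps"], header["n_neurons"]), dtype=np.uint8)
        for line in fh:
            t, n = line.split()
            vals[0, int(t), int(n)] = 1
    return SpikeRaster(vals, dt=header["dt_ms"], layer_id=header["layer_id"],
                       durations=np.array([header["duration_s"]]))
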