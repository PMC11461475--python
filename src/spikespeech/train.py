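"""Training loop for the waveform-to-symbol pipeline.

Plain Adam with global-norm gradient clipping; neuron parameters are
projected back into their biological ranges after every step, while
connectivity masks and Dale signs are structural and never touched by the
optimizer.  Runs are deterministic given the seed and emit a JSON-lines log
(epoch, losses, error rate, mean firing rate per layer).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .ctc import edit_distance, greedy_ctc_decode
from .model import SpeechSNN
from .nn import Adam, global_norm_clip

__all__ = ["TrainSettings", "prepare_dataset", "train", "evaluate", "symbol_error_rate"]


@dataclass
class TrainSettings:
    epochs: int = 15
    batch_size: int = 8
    lr: float = 3e-3
    clip_norm: float = 5.0
    seed: int = 0
    target_error: Optional[float] = None  # early stop when eval error falls below, %
    log_path: Optional[str] = None


def prepare_dataset(model: SpeechSNN, corpus: Sequence[Tuple[np.ndarray, Sequence[int]]]):
    """Pre-extract log-Mel features for a list of (waveform, label-ids)."""
    feats = [model.features(w) for w, _ in corpus]
    labels = [list(l) for _, l in corpus]
    return feats, labels


def _pad_batch(feats: List[np.ndarray]):
    lengths = np.array([f.shape[0] for f in feats])
    T = int(lengths.max())
    out = np.zeros((len(feats), T, feats[0].shape[1]))
    for i, f in enumerate(feats):
        out[i, : f.shape[0]] = f
    return out, lengths


def symbol_error_rate(model: SpeechSNN, feats: List[np.ndarray],
                      labels: List[List[int]], batch_size: int = 16) -> float:
    """Corpus-level error rate: total edit distance / total reference length."""
    k = model.cfg.pool_kernel
    errs = 0
    total = 0
    for i in range(0, len(feats), batch_size):
        batch, lengths = _pad_batch(feats[i:i + batch_size])
        log_probs, _ = model.forward(batch, train=False)
        for b in range(batch.shape[0]):
            hyp = greedy_ctc_decode(log_probs[b, : int(lengths[b]) // k])
            ref = labels[i + b]
            errs += edit_distance(ref, hyp)
            total += len(ref)
    return 100.0 * errs / max(1, total)


def evaluate(model: SpeechSNN, corpus) -> float:
    feats, labels = prepare_dataset(model, corpus)
    return symbol_error_rate(model, feats, labels)


def train(model: SpeechSNN, corpus, settings: TrainSettings,
          eval_corpus=None) -> List[dict]:
    """Train in place; returns the per-epoch log records."""
    rng = np.random.default_rng(settings.seed)
    feats, labels = prepare_dataset(model, corpus)
    eval_feats, eval_labels = (prepare_dataset(model, eval_corpus)
                               if eval_corpus is not None else (feats, labels))
    items = model.param_items()
    opt = Adam(items, lr=settings.lr)
    log: List[dict] = []
    n = len(feats)
    for epoch in range(settings.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_ctc = 0.0
        epoch_reg = 0.0
        n_batches = 0
        t0 = time.time()
        for start in range(0, n, settings.batch_size):
            idx = order[start:start + settings.batch_size]
            batch, lengths = _pad_batch([feats[i] for i in idx])
            opt.zero_grad()
            total, ctc, reg = model.loss_and_grads(
                batch, lengths, [labels[i] for i in idx], train=True, rng=rng)
            if not np.isfinite(total):
                raise RuntimeError(
                    f"divergent loss at epoch {epoch}: total={total} "
                    f"(ctc={ctc}, reg={reg})"
                )
            global_norm_clip(items, settings.clip_norm)
            opt.step()
            model.clamp()
            epoch_loss += total
            epoch_ctc += ctc
            epoch_reg += reg
            n_batches += 1
        err = symbol_error_rate(model, eval_feats, eval_labels)
        _, spikes = model.forward(_pad_batch(feats[:4])[0], train=False)
        dur = spikes[0].shape[1] * model.cfg.dt / 1000.0
        mean_rates = [float(s.sum(axis=1).mean() / dur) for s in spikes]
        rec = {
            "epoch": epoch,
            "loss": epoch_loss / n_batches,
            "ctc": epoch_ctc / n_batches,
            "reg": epoch_reg / n_batches,
            "per": err,
            "mean_rate_per_layer": mean_rates,
            "seconds": time.time() - t0,
        }
        log.append(rec)
        if settings.log_path:
            with open(settings.log_path, "a") as fh:
                fh.write(json.dumps(rec) + "\n")
        if settings.target_error is not None and err < settings.target_error:
            break
    return log
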