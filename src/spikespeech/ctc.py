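"""Connectionist temporal classification: loss, gradient, decoding, PER.

The CTC loss sums the probability of every frame-level alignment that
collapses (repeat-merge, then blank-removal) to the reference label
sequence, computed with the standard forward-backward recursion in log
space.  The blank token always has index 0.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

__all__ = [
    "BLANK",
    "ctc_loss_grad",
    "ctc_feasible",
    "greedy_ctc_decode",
    "collapse_alignment",
    "edit_distance",
    "phoneme_error_rate",
]

BLANK = 0


def _extended(labels: Sequence[int]) -> np.ndarray:
    ext = np.full(2 * len(labels) + 1, BLANK, dtype=int)
    ext[1::2] = labels
    return ext


def ctc_feasible(n_frames: int, labels: Sequence[int]) -> bool:
    """A label sequence fits in T frames iff T >= U + number of repeats."""
    labels = list(labels)
    repeats = sum(1 for i in range(1, len(labels)) if labels[i] == labels[i - 1])
    return n_frames >= len(labels) + repeats


def ctc_loss_grad(log_probs: np.ndarray, labels: Sequence[int]) -> Tuple[float, np.ndarray]:
    """Negative log-likelihood and its gradient w.r.t. the log-probabilities.

    ``log_probs`` has shape (T, K) with valid log-distributions per frame;
    ``labels`` are class indices (1..K-1) without blanks.
    """
    labels = [int(x) for x in labels]
    if any(l == BLANK for l in labels):
        raise ValueError("labels must not contain the blank index")
    T, K = log_probs.shape
    if not ctc_feasible(T, labels):
        raise ValueError(
            f"label sequence of length {len(labels)} does not fit in {T} frames"
        )
    ext = _extended(labels)
    S = ext.size
    NEG = -np.inf

    lp = log_probs[:, ext]  # (T, S)
    alpha = np.full((T, S), NEG)
    alpha[0, 0] = lp[0, 0]
    if S > 1:
        alpha[0, 1] = lp[0, 1]
    # transitions: stay, advance by 1, skip a blank between distinct labels
    skip_ok = np.zeros(S, dtype=bool)
    skip_ok[2:] = (ext[2:] != BLANK) & (ext[2:] != ext[:-2])
    for t in range(1, T):
        prev = alpha[t - 1]
        stay = prev
        adv = np.concatenate(([NEG], prev[:-1]))
        skp = np.concatenate(([NEG, NEG], prev[:-2]))
        skp = np.where(skip_ok, skp, NEG)
        alpha[t] = np.logaddexp(np.logaddexp(stay, adv), skp) + lp[t]

    ll = np.logaddexp(alpha[T - 1, S - 1], alpha[T - 1, S - 2]) if S > 1 else alpha[T - 1, S - 1]
    loss = -ll

    beta = np.full((T, S), NEG)
    beta[T - 1, S - 1] = lp[T - 1, S - 1]
    if S > 1:
        beta[T - 1, S - 2] = lp[T - 1, S - 2]
    for t in range(T - 2, -1, -1):
        nxt = beta[t + 1]
        stay = nxt
        adv = np.concatenate((nxt[1:], [NEG]))
        skp = np.concatenate((nxt[2:], [NEG, NEG]))
        skip_fwd = np.zeros(S, dtype=bool)
        skip_fwd[:-2] = skip_ok[2:]
        skp = np.where(skip_fwd, skp, NEG)
        beta[t] = np.logaddexp(np.logaddexp(stay, adv), skp) + lp[t]

    # posterior occupancy of (t, s): alpha*beta double-counts lp[t]
    with np.errstate(invalid="ignore"):
        gamma = alpha + beta - lp - ll  # log posterior
    grad = np.zeros_like(log_probs)
    for s in range(S):
        grad[:, ext[s]] -= np.exp(gamma[:, s])
    return float(loss), grad


def collapse_alignment(path: Sequence[int]) -> List[int]:
    """CTC collapse: merge repeats, then drop blanks."""
    out: List[int] = []
    prev = None
    for p in path:
        if p != prev and p != BLANK:
            out.append(int(p))
        prev = p
    return out


def greedy_ctc_decode(log_probs: np.ndarray) -> List[int]:
    """Best-path decoding: per-frame argmax, then CTC collapse."""
    return collapse_alignment(np.argmax(log_probs, axis=-1))


def edit_distance(reference: Sequence, hypothesis: Sequence) -> int:
    """Levenshtein distance (substitutions + insertions + deletions)."""
    m, n = len(reference), len(hypothesis)
    prev = np.arange(n + 1)
    for i in range(1, m + 1):
        cur = np.empty(n + 1, dtype=int)
        cur[0] = i
        for j in range(1, n + 1):
            cost = 0 if reference[i - 1] == hypothesis[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return int(prev[n])


def phoneme_error_rate(reference: Sequence, hypothesis: Sequence) -> float:
    """Edit distance divided by reference length, as a percentage."""
    if len(reference) == 0:
        raise ValueError("reference sequence must be nonempty")
    return 100.0 * edit_distance(reference, hypothesis) / len(reference)
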