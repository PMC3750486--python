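"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by the most naive route
(double loops, exhaustive sweeps) so the library's vectorised paths are
checked against something that cannot share their bugs.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def oracle_canonical(w: str) -> str:
    rc = oracle_revcomp(w)
    return w if w <= rc else rc


def oracle_present(seq: str, w: str) -> bool:
    """Naive both-strand substring presence of w in seq, skipping N windows."""
    for word in (w, oracle_revcomp(w)):
        k = len(word)
        for i in range(len(seq) - k + 1):
            win = seq[i : i + k]
            if "N" not in win and win == word:
                return True
    return False


def all_kmers(k: int) -> list[str]:
    out = [""]
    for _ in range(k):
        out = [w + b for w in out for b in BASES]
    return out


def all_canonical_kmers(k: int) -> list[str]:
    return sorted({oracle_canonical(w) for w in all_kmers(k)})


def random_dna(rng: np.random.Generator, length: int, n_prob: float = 0.0) -> str:
    alphabet = "ACGTN" if n_prob > 0 else BASES
    p = None
    if n_prob > 0:
        p = [(1 - n_prob) / 4] * 4 + [n_prob]
    return "".join(rng.choice(list(alphabet), size=length, p=p))


def oracle_best_accuracy(scores, labels) -> float:
    """Max accuracy of `score >= t => positive` over an exhaustive sweep of
    every observed score plus one above the maximum."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    best = 0.0
    for t in list(np.unique(scores)) + [scores.max() + 1.0]:
        pred = (scores >= t).astype(int)
        best = max(best, float(np.mean(pred == labels)))
    return best


def oracle_auc(pos, neg) -> float:
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def oracle_scan_max(probs: np.ndarray, background: np.ndarray, s: str) -> float:
    """Max log-odds over all windows and both strands, skipping N windows."""
    L = len(probs)
    best = -math.inf
    for strand_seq in (s, oracle_revcomp(s)):
        for i in range(len(strand_seq) - L + 1):
            win = strand_seq[i : i + L]
            if "N" in win:
                continue
            score = sum(
                math.log(probs[j][BASES.index(b)]) - math.log(background[BASES.index(b)])
                for j, b in enumerate(win)
            )
            best = max(best, score)
    return best


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130812)
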