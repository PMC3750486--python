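"""Position weight matrices: ingestion, log-odds scanning, classification.

PWMs are the benchmark the k-mer model is compared against.  A PWM stores
per-position base probabilities under positional independence; a sequence
is scored by the maximum over all windows (both strands) of the summed
log-odds against a background distribution (uniform by default).

Consumed formats: MEME minimal, JASPAR-style count matrices, and a plain
whitespace-separated L x 4 matrix (columns A, C, G, T).  PWM *construction*
here is limited to the naive count matrix over aligned motif instances,
used to benchmark simulated data where the planted alignment is known.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evaluate import EvalResult, accuracy_result, optimal_threshold
from .sequences import clean_sequence, reverse_complement

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class ShortSequenceError(ValueError):
    """Sequence shorter than the motif; no window can be scored."""


class PWMParseError(ValueError):
    """Malformed motif file."""


@dataclass
class PWM:
    """Per-position base probabilities (rows: positions, columns A,C,G,T)."""

    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or len(self.probs) < 1:
            raise ValueError("probs must be an L x 4 matrix with L >= 1")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM row must sum to 1")
        if np.any(self.probs <= 0):
            raise ValueError("PWM entries must be positive (apply a pseudocount)")

    @property
    def length(self) -> int:
        return len(self.probs)

    @property
    def log_odds(self) -> np.ndarray:
        """log(probs / background), natural log."""
        return np.log(self.probs) - np.log(self.background)[None, :]

    @property
    def consensus(self) -> str:
        return "".join(BASES[j] for j in self.probs.argmax(axis=1))

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudocount: float = 1.0) -> "PWM":
        counts = np.asarray(counts, dtype=np.float64) + pseudocount
        return cls(counts / counts.sum(axis=1, keepdims=True), pseudocount=pseudocount)

    @classmethod
    def from_frequencies(cls, freqs: np.ndarray, pseudocount: float = 0.01) -> "PWM":
        freqs = np.asarray(freqs, dtype=np.float64) + pseudocount
        return cls(freqs / freqs.sum(axis=1, keepdims=True), pseudocount=pseudocount)


def build_count_pwm(instances: list[str], pseudocount: float = 1.0) -> PWM:
    """Naive count PWM from equal-length aligned motif instances."""
    if not instances:
        raise ValueError("need at least one instance")
    L = len(instances[0])
    if any(len(s) != L for s in instances):
        raise ValueError("instances must have equal length")
    counts = np.zeros((L, 4))
    for s in instances:
        for i, b in enumerate(clean_sequence(s)):
            counts[i, _BASE_INDEX[b]] += 1
    return PWM.from_counts(counts, pseudocount)


# --- file formats ---------------------------------------------------------

def _sniff_pwm_format(text: str) -> str:
    stripped = text.lstrip()
    if stripped.startswith("MEME version") or "letter-probability matrix" in text:
        return "meme"
    if stripped.startswith(">"):
        return "jaspar"
    return "plain"


def _parse_plain(text: str) -> PWM:
    rows = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise PWMParseError(f"line {ln}: expected 4 columns, got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise PWMParseError(f"line {ln}: {exc}") from exc
    if not rows:
        raise PWMParseError("no matrix rows found")
    mat = np.array(rows)
    if np.allclose(mat.sum(axis=1), 1.0, atol=1e-6):
        return PWM.from_frequencies(mat, pseudocount=0.0) if np.all(mat > 0) \
            else PWM.from_frequencies(mat)
    return PWM.from_counts(mat)


def read_pwm(path: str | Path, fmt: str | None = None) -> PWM:
    """Read a PWM from MEME minimal, JASPAR, or plain-matrix files.

    Counts get pseudocount 1, frequencies pseudocount 0.01 (0 when all
    entries are already positive), then rows are renormalised.
    """
    from Bio import motifs

    text = Path(path).read_text()
    fmt = fmt or _sniff_pwm_format(text)
    if fmt == "plain":
        return _parse_plain(text)
    try:
        if fmt == "jaspar":
            motif = motifs.read(io.StringIO(text), "jaspar")
            counts = np.array([list(motif.counts[b]) for b in BASES]).T
            return PWM.from_counts(counts)
        if fmt == "meme":
            motif = motifs.read(io.StringIO(text), "minimal")
            freqs = np.array([list(motif.pwm[b]) for b in BASES]).T
            if np.all(freqs > 0):
                return PWM.from_frequencies(freqs, pseudocount=0.0)
            return PWM.from_frequencies(freqs)
    except PWMParseError:
        raise
    except Exception as exc:
        raise PWMParseError(f"failed to parse {path} as {fmt}: {exc}") from exc
    raise ValueError(f"unknown PWM format: {fmt}")


def write_pwm(pwm: PWM, path: str | Path) -> None:
    """Write probabilities as a plain L x 4 matrix at full float precision."""
    with open(path, "wt") as fh:
        fh.write("# columns: A C G T (probabilities)\n")
        for row in pwm.probs:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# --- scanning -------------------------------------------------------------

def _encode(s: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, -1) for b in s], dtype=np.int64)


def _window_scores(pwm: PWM, s: str) -> np.ndarray:
    """Log-odds score of every clean forward window of s; N windows -> -inf."""
    codes = _encode(s)
    L = pwm.length
    lo = pwm.log_odds
    n_win = len(codes) - L + 1
    scores = np.full(n_win, -np.inf)
    for i in range(n_win):
        win = codes[i : i + L]
        if np.any(win < 0):
            continue
        scores[i] = lo[np.arange(L), win].sum()
    return scores


def scan_max_score(pwm: PWM, s: str, both_strands: bool = True) -> float:
    """Maximum log-odds window score of s under the PWM.

    Both strands are scanned by default; windows containing N are excluded.
    """
    s = clean_sequence(s)
    if len(s) < pwm.length:
        raise ShortSequenceError(
            f"sequence length {len(s)} < motif length {pwm.length}"
        )
    best = _window_scores(pwm, s).max()
    if both_strands:
        best = max(best, _window_scores(pwm, reverse_complement(s)).max())
    if not np.isfinite(best):
        raise ShortSequenceError("no N-free window to score")
    return float(best)


def scan_reads(pwm: PWM, reads: list[str], both_strands: bool = True) -> np.ndarray:
    """Max-score every read; reads shorter than the motif are skipped with a
    warning and excluded from the returned array."""
    scores = []
    skipped = 0
    for r in reads:
        try:
            scores.append(scan_max_score(pwm, r, both_strands))
        except ShortSequenceError:
            skipped += 1
    if skipped:
        logger.warning("skipped %d reads shorter than the motif", skipped)
    return np.array(scores)


def classify_with_pwm(
    pwm: PWM,
    train_pos: list[str],
    train_neg: list[str],
    test_pos: list[str],
    test_neg: list[str],
    both_strands: bool = True,
) -> EvalResult:
    """Max-score classification with the threshold optimised on training
    scores; returns test accuracy with a normal-approximation interval."""
    tr_pos = scan_reads(pwm, train_pos, both_strands)
    tr_neg = scan_reads(pwm, train_neg, both_strands)
    scores = np.concatenate([tr_pos, tr_neg])
    labels = np.concatenate([np.ones(len(tr_pos)), np.zeros(len(tr_neg))])
    thr, _ = optimal_threshold(scores, labels)
    te_pos = scan_reads(pwm, test_pos, both_strands)
    te_neg = scan_reads(pwm, test_neg, both_strands)
    return accuracy_result(te_pos, te_neg, thr)


def align_kmers_to_pwm(
    pwm: PWM, kmers: list[str]
) -> list[tuple[str, str, int, float]]:
    """Best (strand, offset) placement of each k-mer against the motif.

    Every offset with at least one overlapping position is tried, on both
    the k-mer and its reverse complement; overhanging positions score at
    the background probability.  The score is the summed log probability of
    the k-mer's bases.  Ties prefer the forward strand, then the smaller
    offset.  Returns (kmer, strand '+'/'-', offset, score) per k-mer.
    """
    log_p = np.log(pwm.probs)
    log_bg = np.log(pwm.background)
    L = pwm.length
    results = []
    for w in kmers:
        w = clean_sequence(w)
        k = len(w)
        best = None
        for strand, word in (("+", w), ("-", reverse_complement(w))):
            codes = _encode(word)
            for off in range(-(k - 1), L):
                score = 0.0
                for j, c in enumerate(codes):
                    pos = off + j
                    score += log_p[pos, c] if 0 <= pos < L else log_bg[c]
                if best is None or score > best[3] + 1e-12:
                    best = (w, strand, off, score)
        results.append((best[0], best[1], best[2], float(best[3])))
    return results
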