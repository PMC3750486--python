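"""SELEX enrichment simulator and peak-sequence generator.

Ground truth for testing the model end to end.  A SELEX run starts from a
uniform random pool of fixed-length oligos; each cycle selects reads with
probability proportional to exp(beta * affinity) under a planted affinity
model (a k-mer->affinity map or a PWM) and resamples with replacement back
to constant pool size, mimicking binding, precipitation and PCR
amplification.  Later cycles are therefore increasingly dominated by
high-affinity sequences, which is exactly the trend the classifier should
pick up.

``simulate_dependent_motif_reads`` plants one of several motif *variants*
per read, producing position dependencies that no single PWM can represent
— the regime where a k-mer model should win.  ``simulate_peaks`` builds
ChIP-seq-style positive/negative sequence sets with the motif planted near
the peak midpoint.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evaluate import generate_random_reads
from .pwm import PWM, scan_max_score
from .sequences import KmerSpec, kmers_present

logger = logging.getLogger(__name__)

AffinityModel = "dict[str, float] | PWM"


@dataclass
class SelexSimConfig:
    """Parameters of one simulated SELEX experiment.

    ``affinity`` is either a canonical-k-mer -> affinity map (a read's
    affinity is the sum over k-mers present, matching the linear model) or
    a PWM (affinity is the max log-odds scan score).  ``beta`` is the
    selection stringency of the Boltzmann selection rule
    P(select read) ∝ exp(beta * affinity).
    """

    pool_size: int = 5000
    n_cycles: int = 3
    affinity: dict[str, float] | PWM = field(
        default_factory=lambda: {"ACGTCA": 1.0}
    )
    read_length: int = 14
    beta: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < 1 or self.n_cycles < 1 or self.beta <= 0:
            raise ValueError("pool_size >= 1, n_cycles >= 1, beta > 0 required")


@dataclass
class SimResult:
    """Per-cycle read pools; ``pools[0]`` is the uniform initial pool."""

    pools: list[list[str]]
    config: SelexSimConfig

    def reads(self, cycle: int) -> list[str]:
        return self.pools[cycle]

    @property
    def n_cycles(self) -> int:
        return len(self.pools) - 1

    def truth_dict(self) -> dict:
        aff = self.config.affinity
        return {
            "affinity": aff if isinstance(aff, dict) else {"pwm_consensus": aff.consensus},
            "beta": self.config.beta,
            "read_length": self.config.read_length,
            "pool_size": self.config.pool_size,
            "n_cycles": self.config.n_cycles,
            "seed": self.config.seed,
        }


def _read_affinity(read: str, affinity, spec: KmerSpec | None, cache: dict) -> float:
    if read in cache:
        return cache[read]
    if isinstance(affinity, PWM):
        a = scan_max_score(affinity, read)
    else:
        present = kmers_present(read, spec)
        a = sum(affinity[w] for w in present if w in affinity)
    cache[read] = a
    return a


def simulate_selex(config: SelexSimConfig) -> SimResult:
    """Run the cycle-wise enrichment simulation.

    Cycle 0 is i.i.d. uniform; each later pool is drawn with replacement
    from the previous one with Boltzmann weights exp(beta * affinity).
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    pool = generate_random_reads(config.pool_size, config.read_length, rng)
    pools = [pool]
    spec = None
    if isinstance(config.affinity, dict):
        spec = KmerSpec(tuple(sorted({len(w) for w in config.affinity})))
    cache: dict[str, float] = {}
    for _ in range(config.n_cycles):
        aff = np.array(
            [_read_affinity(r, config.affinity, spec, cache) for r in pool]
        )
        w = np.exp(config.beta * (aff - aff.max()))
        p = w / w.sum()
        idx = rng.choice(len(pool), size=config.pool_size, replace=True, p=p)
        pool = [pool[i] for i in idx]
        pools.append(pool)
    return SimResult(pools=pools, config=config)


def simulate_dependent_motif_reads(
    n: int,
    read_length: int,
    variants: list[tuple[str, float]],
    seed: int = 0,
    both_strands: bool = True,
) -> list[str]:
    """Reads that each carry exactly one motif variant.

    The variant is sampled by weight, planted at a uniform random offset
    (and uniformly chosen strand when ``both_strands``); all other bases
    are uniform.  Using several dissimilar variants creates the positional
    dependencies that break the PWM independence assumption.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    motifs = [m.upper() for m, _ in variants]
    weights = np.array([w for _, w in variants], dtype=np.float64)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("variant weights must be non-negative and sum > 0")
    for m in motifs:
        if len(m) > read_length:
            raise ValueError(f"variant {m!r} longer than read_length {read_length}")
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    from .sequences import reverse_complement

    reads = []
    for _ in range(n):
        v = motifs[rng.choice(len(motifs), p=weights)]
        if both_strands and rng.integers(2):
            v = reverse_complement(v)
        offset = int(rng.integers(0, read_length - len(v) + 1))
        bg = generate_random_reads(1, read_length, rng)[0]
        reads.append(bg[:offset] + v + bg[offset + len(v):])
    return reads


def simulate_peaks(
    n_pos: int,
    n_neg: int,
    peak_length: int,
    motif: str,
    planting_prob_at_center: float = 1.0,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """ChIP-seq-style positive and negative peak sequences.

    Positives receive the motif with the stated probability, planted
    uniformly within the central 50 nt so a 50 nt center window always
    covers it; negatives are uniform random.  The motif must fit in the
    central 50 nt.
    """
    motif = motif.upper()
    win = min(50, peak_length)
    if len(motif) > win:
        raise ValueError("motif must fit within the central 50 nt")
    rng = np.random.default_rng(seed)
    center = peak_length // 2
    lo = max(0, center - win // 2)
    hi = min(peak_length, lo + win) - len(motif)
    positives = []
    for _ in range(n_pos):
        s = generate_random_reads(1, peak_length, rng)[0]
        if rng.random() < planting_prob_at_center:
            start = int(rng.integers(lo, hi + 1))
            s = s[:start] + motif + s[start + len(motif):]
        positives.append(s)
    negatives = generate_random_reads(n_neg, peak_length, rng)
    return positives, negatives


def write_truth(path: str | Path, truth: dict) -> None:
    with open(path, "wt") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
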