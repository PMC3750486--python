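"""Sequence alphabet handling and k-mer counting.

DNA sequences are plain Python strings over ``{A, C, G, T, N}``, normalised
to upper case on ingestion.  Binding is detected on both strands, so a k-mer
and its reverse complement are merged into one *canonical* feature (the
lexicographically smaller of the pair) by default; without this merge the
two orientations would be perfectly collinear columns in the design matrix.

The central data structure is the :class:`KmerTable`, which lists per-k-mer
counts in a set of bound reads and a set of unbound (random) reads together
with the derived enrichment statistics (difference and fold change).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Iterator, Literal

import pandas as pd

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CountingMode = Literal["presence", "occurrence"]


class AlphabetError(ValueError):
    """A sequence contains characters outside {A, C, G, T, N}."""


class EmptyInputError(ValueError):
    """An operation received an empty read set where reads are required."""


def clean_sequence(s: str) -> str:
    """Upper-case ``s`` and verify it is over the DNA alphabet (N allowed)."""
    s = s.upper()
    if not ALPHABET.issuperset(s):
        bad = sorted(set(s) - ALPHABET)
        raise AlphabetError(f"non-DNA characters in sequence: {bad}")
    return s


def reverse_complement(s: str) -> str:
    """Watson-Crick complement of ``s``, reversed; N maps to N."""
    if not ALPHABET.issuperset(s):
        bad = sorted(set(s) - ALPHABET)
        raise AlphabetError(f"non-DNA characters in sequence: {bad}")
    return s.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=1 << 20)
def canonical(w: str) -> str:
    """The lexicographically smaller of ``w`` and its reverse complement.

    Defined only for unambiguous k-mers: an N makes the strand merge
    ill-defined and raises :class:`AlphabetError`.
    """
    if "N" in w:
        raise AlphabetError(f"k-mer contains N: {w!r}")
    rc = reverse_complement(w)
    return w if w <= rc else rc


def kmer_sort_key(w: str) -> tuple[int, str]:
    """Deterministic feature order: by length, then lexicographic."""
    return (len(w), w)


@dataclass(frozen=True)
class KmerSpec:
    """Which word lengths are counted and how strands are handled.

    Parameters
    ----------
    k_values
        Word lengths to enumerate, each >= 1.  Stored sorted and unique.
    canonicalize
        Merge each k-mer with its reverse complement into one feature.
    both_strands
        Presence of a k-mer means the word or its reverse complement occurs
        as a substring.  Implied by ``canonicalize``.
    """

    k_values: tuple[int, ...] = (4, 5, 6, 7, 8)
    canonicalize: bool = True
    both_strands: bool = True

    def __post_init__(self) -> None:
        ks = tuple(sorted(set(int(k) for k in self.k_values)))
        if not ks or any(k < 1 for k in ks):
            raise ValueError("k_values must be non-empty positive integers")
        object.__setattr__(self, "k_values", ks)
        if self.canonicalize and not self.both_strands:
            raise ValueError("canonicalize requires both_strands")

    def restrict(self, ks: Iterable[int]) -> "KmerSpec":
        """A copy limited to the lengths in ``ks`` (used when scoring against
        a fixed feature list that does not span every configured length)."""
        return KmerSpec(tuple(ks), self.canonicalize, self.both_strands)


def kmers_present(s: str, spec: KmerSpec) -> set[str]:
    """Set of (canonical) k-mers present in ``s`` for every k in the spec.

    Windows containing N contribute nothing.  With canonicalization off but
    ``both_strands`` on, each clean window contributes the word and its
    reverse complement, so membership still answers "does w occur on either
    strand".
    """
    out: set[str] = set()
    n = len(s)
    has_n = "N" in s
    for k in spec.k_values:
        for i in range(n - k + 1):
            w = s[i : i + k]
            if has_n and "N" in w:
                continue
            if spec.canonicalize:
                out.add(canonical(w))
            else:
                out.add(w)
                if spec.both_strands:
                    out.add(reverse_complement(w))
    return out


def kmer_occurrences(s: str, spec: KmerSpec) -> dict[str, int]:
    """Number of windows of ``s`` whose (canonical) word equals each k-mer."""
    out: dict[str, int] = {}
    n = len(s)
    has_n = "N" in s
    for k in spec.k_values:
        for i in range(n - k + 1):
            w = s[i : i + k]
            if has_n and "N" in w:
                continue
            key = canonical(w) if spec.canonicalize else w
            out[key] = out.get(key, 0) + 1
    return out


@dataclass
class KmerTable:
    """Per-k-mer counts in bound vs unbound read sets.

    ``entries`` maps each (canonical) k-mer to ``(count_bound,
    count_unbound)``.  Under presence mode every count is a number of reads,
    so it is bounded by the corresponding read-set size.
    """

    entries: dict[str, tuple[int, int]]
    n_bound_reads: int
    n_unbound_reads: int
    counting_mode: CountingMode = "presence"
    spec: KmerSpec = field(default_factory=KmerSpec)

    def __len__(self) -> int:
        return len(self.entries)

    def difference(self, kmer: str) -> int:
        cb, cu = self.entries[kmer]
        return cb - cu

    def fold_change(self, kmer: str, pseudocount: float = 1.0) -> float:
        cb, cu = self.entries[kmer]
        return (cb + pseudocount) / (cu + pseudocount)

    def frequency(self, kmer: str) -> int:
        cb, cu = self.entries[kmer]
        return cb + cu

    def to_frame(self, pseudocount: float = 1.0) -> pd.DataFrame:
        rows = [
            {
                "kmer": w,
                "k": len(w),
                "count_bound": cb,
                "count_unbound": cu,
                "difference": cb - cu,
                "fold_change": (cb + pseudocount) / (cu + pseudocount),
            }
            for w, (cb, cu) in sorted(
                self.entries.items(), key=lambda it: kmer_sort_key(it[0])
            )
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "kmer", "k", "count_bound", "count_unbound",
                "difference", "fold_change",
            ],
        )

    def to_tsv(self, path: str | Path, pseudocount: float = 1.0) -> None:
        self.to_frame(pseudocount).to_csv(path, sep="\t", index=False)


def build_kmer_table(
    bound: list[str],
    unbound: list[str],
    spec: KmerSpec | None = None,
    mode: CountingMode = "presence",
) -> KmerTable:
    """Count every k-mer of the spec in the bound and unbound read sets.

    Presence mode counts each k-mer at most once per read (matching the
    binary design matrix); occurrence mode counts windows.
    """
    if not bound or not unbound:
        raise EmptyInputError("bound and unbound read sets must be non-empty")
    spec = spec or KmerSpec()
    entries: dict[str, list[int]] = {}
    for col, reads in ((0, bound), (1, unbound)):
        for read in reads:
            read = clean_sequence(read)
            if mode == "presence":
                for w in kmers_present(read, spec):
                    entries.setdefault(w, [0, 0])[col] += 1
            else:
                for w, c in kmer_occurrences(read, spec).items():
                    entries.setdefault(w, [0, 0])[col] += c
    return KmerTable(
        entries={w: (cb, cu) for w, (cb, cu) in entries.items()},
        n_bound_reads=len(bound),
        n_unbound_reads=len(unbound),
        counting_mode=mode,
        spec=spec,
    )


# --- read ingestion -------------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(path: Path, first: str) -> str:
    name = path.name.removesuffix(".gz")
    if name.endswith((".fa", ".fasta", ".fna")) or first.startswith(">"):
        return "fasta"
    if name.endswith((".fq", ".fastq")) or first.startswith("@"):
        return "fastq"
    return "plain"


def read_sequences(path: str | Path, fmt: str | None = None) -> list[str]:
    """Read fixed-length reads or peak sequences from a file.

    Supported formats: plain text (one read per line), FASTA and FASTQ
    (qualities ignored), each optionally gzip-compressed.  The format is
    sniffed from the extension and first character when ``fmt`` is None.
    """
    from Bio import SeqIO

    path = Path(path)
    with _open_text(path) as fh:
        first = fh.readline()
        fh.seek(0)
        fmt = fmt or _sniff_format(path, first)
        if fmt == "plain":
            return [clean_sequence(line.strip()) for line in fh if line.strip()]
        return [clean_sequence(str(rec.seq)) for rec in SeqIO.parse(fh, fmt)]


def write_sequences(
    reads: Iterable[str], path: str | Path, fmt: str = "plain",
    names: Iterator[str] | None = None,
) -> None:
    """Write reads as plain text (one per line) or FASTA."""
    path = Path(path)
    with open(path, "wt") as fh:
        if fmt == "plain":
            for r in reads:
                fh.write(r + "\n")
        elif fmt == "fasta":
            for i, r in enumerate(reads):
                name = next(names) if names is not None else f"seq_{i}"
                fh.write(f">{name}\n{r}\n")
        else:
            raise ValueError(f"unsupported output format: {fmt}")
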