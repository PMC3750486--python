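"""The linear k-mer affinity model.

A read set is encoded as a binary design matrix A (reads x k-mers, entry 1
iff the k-mer occurs in the read on either strand) and per-k-mer affinities
x are obtained by least squares on A x = b, where b is 1 for enriched
(bound) reads and 0 for random (unbound) reads.  A sequence's predicted
binding affinity is then the sum of the affinities of the model k-mers it
contains.

The solver is ridge-regularised least squares; the tiny default
``ridge_lambda`` exists purely for conditioning, because perfectly
co-occurring k-mers make A rank deficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .sequences import (
    KmerSpec,
    canonical,
    clean_sequence,
    kmer_occurrences,
    kmer_sort_key,
    kmers_present,
)

logger = logging.getLogger(__name__)

DEFAULT_RIDGE = 1e-6


class DuplicateFeatureError(ValueError):
    """The k-mer column list contains duplicates."""


class RankDeficiencyError(ValueError):
    """Unregularised fit attempted on a visibly rank-deficient system."""


@dataclass
class DesignMatrix:
    """Binary reads x k-mers presence matrix (CSR sparse).

    Column order is exactly ``kmers``; row order is read input order.
    """

    matrix: sp.csr_matrix
    kmers: tuple[str, ...]

    @property
    def n_reads(self) -> int:
        return self.matrix.shape[0]

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


def _spec_for_kmers(kmers: tuple[str, ...], spec: KmerSpec) -> KmerSpec:
    lengths = sorted({len(w) for w in kmers})
    return spec.restrict(lengths) if lengths else spec


def build_design_matrix(
    reads: list[str], kmers: list[str] | tuple[str, ...], spec: KmerSpec | None = None
) -> DesignMatrix:
    """Binary presence matrix: entry (i, j) is 1 iff k-mer j occurs in read i.

    The k-mer list must be unique (and canonical when the spec
    canonicalizes); its order defines the column order.
    """
    spec = spec or KmerSpec()
    kmers = tuple(kmers)
    if len(set(kmers)) != len(kmers):
        raise DuplicateFeatureError("duplicate k-mer columns")
    if spec.canonicalize:
        bad = [w for w in kmers if canonical(w) != w]
        if bad:
            raise ValueError(f"non-canonical k-mers under canonical spec: {bad[:5]}")
    col = {w: j for j, w in enumerate(kmers)}
    scan_spec = _spec_for_kmers(kmers, spec)
    indptr = [0]
    indices: list[int] = []
    for read in reads:
        read = clean_sequence(read)
        hits = sorted(col[w] for w in kmers_present(read, scan_spec) if w in col)
        indices.extend(hits)
        indptr.append(len(indices))
    mat = sp.csr_matrix(
        (np.ones(len(indices), dtype=np.float64), indices, indptr),
        shape=(len(reads), len(kmers)),
    )
    return DesignMatrix(matrix=mat, kmers=kmers)


@dataclass
class KmerModel:
    """Trained k-mer affinities plus the spec needed to score sequences."""

    kmers: tuple[str, ...]
    affinities: np.ndarray
    ridge_lambda: float = DEFAULT_RIDGE
    spec: KmerSpec = field(default_factory=KmerSpec)
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.affinities = np.asarray(self.affinities, dtype=np.float64)
        if len(self.kmers) != len(self.affinities):
            raise ValueError("kmers and affinities must be aligned")

    def score_sequence(self, s: str, occurrence_weighted: bool = False) -> float:
        """Predicted affinity: sum of affinities of model k-mers present in s.

        Binary presence by default (identical to the training design rule);
        ``occurrence_weighted`` multiplies each affinity by the number of
        windows instead, for exploration only.
        """
        if not self.kmers:
            return 0.0
        s = clean_sequence(s)
        scan_spec = _spec_for_kmers(self.kmers, self.spec)
        idx = {w: a for w, a in zip(self.kmers, self.affinities)}
        if occurrence_weighted:
            occ = kmer_occurrences(s, scan_spec)
            return float(sum(idx[w] * c for w, c in occ.items() if w in idx))
        present = kmers_present(s, scan_spec)
        return float(sum(idx[w] for w in present if w in idx))

    def score_sequences(self, seqs: list[str]) -> np.ndarray:
        A = build_design_matrix(seqs, self.kmers, self.spec)
        return np.asarray(A.matrix @ self.affinities)

    def top_kmers(self, n: int = 10) -> list[tuple[str, float]]:
        """The n highest-affinity k-mers, descending."""
        order = np.argsort(-self.affinities, kind="stable")[:n]
        return [(self.kmers[j], float(self.affinities[j])) for j in order]

    # -- persistence: TSV with a small header, lossless round trip ---------

    def save(self, path: str | Path) -> None:
        with open(path, "wt") as fh:
            fh.write(f"# k_values\t{','.join(map(str, self.spec.k_values))}\n")
            fh.write(f"# ridge_lambda\t{self.ridge_lambda!r}\n")
            fh.write(f"# canonicalize\t{int(self.spec.canonicalize)}\n")
            fh.write("kmer\taffinity\n")
            for w, a in zip(self.kmers, self.affinities):
                fh.write(f"{w}\t{float(a)!r}\n")

    @classmethod
    def load(cls, path: str | Path) -> "KmerModel":
        header: dict[str, str] = {}
        kmers: list[str] = []
        aff: list[float] = []
        with open(path, "rt") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("\t")
                    header[key.strip()] = val
                elif line and not line.startswith("kmer\t"):
                    w, a = line.split("\t")
                    kmers.append(w)
                    aff.append(float(a))
        spec = KmerSpec(
            tuple(int(k) for k in header["k_values"].split(",")),
            canonicalize=bool(int(header.get("canonicalize", "1"))),
        )
        return cls(
            kmers=tuple(kmers),
            affinities=np.array(aff),
            ridge_lambda=float(header.get("ridge_lambda", DEFAULT_RIDGE)),
            spec=spec,
        )


def fit_affinities(
    A: DesignMatrix,
    b: np.ndarray,
    ridge_lambda: float = DEFAULT_RIDGE,
    spec: KmerSpec | None = None,
) -> KmerModel:
    """Solve min_x ||Ax - b||^2 + ridge_lambda ||x||^2 for the affinities.

    With ``ridge_lambda = 0`` the minimum-norm least-squares solution is
    returned, but an all-zero column (a k-mer absent from every read) is
    rejected as rank deficient since its affinity is unidentifiable.
    Underdetermined systems (more k-mers than reads) are permitted with a
    logged warning.
    """
    b = np.asarray(b, dtype=np.float64).ravel()
    if A.n_reads != len(b):
        raise ValueError("design rows and label vector length differ")
    if len(np.unique(b)) < 2:
        raise ValueError("labels must contain both classes for training")
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be non-negative")
    m = len(A.kmers)
    spec = spec or KmerSpec(tuple(sorted({len(w) for w in A.kmers})) or (4,))
    if m == 0:
        return KmerModel((), np.zeros(0), ridge_lambda, spec,
                         {"n_reads": A.n_reads, "residual_norm": float(np.linalg.norm(b))})
    col_sums = np.asarray(A.matrix.sum(axis=0)).ravel()
    if ridge_lambda == 0.0:
        if np.any(col_sums == 0):
            empty = [A.kmers[j] for j in np.flatnonzero(col_sums == 0)[:5]]
            raise RankDeficiencyError(
                f"all-zero design columns with ridge_lambda=0: {empty}"
            )
        x, *_ = np.linalg.lstsq(A.toarray(), b, rcond=None)
    else:
        if m > A.n_reads:
            logger.warning(
                "underdetermined system (%d k-mers > %d reads); "
                "minimum-norm ridge solution", m, A.n_reads,
            )
        G = (A.matrix.T @ A.matrix).toarray()
        G[np.diag_indices_from(G)] += ridge_lambda
        c = A.matrix.T @ b
        x = scipy.linalg.solve(G, c, assume_a="pos")
    residual = float(np.linalg.norm(A.matrix @ x - b))
    return KmerModel(
        kmers=A.kmers,
        affinities=x,
        ridge_lambda=ridge_lambda,
        spec=spec,
        training_meta={"n_reads": A.n_reads, "residual_norm": residual},
    )


def sort_kmers(kmers: list[str]) -> list[str]:
    """Deterministic model column order: by (k, lexicographic)."""
    return sorted(kmers, key=kmer_sort_key)
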