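"""Oligonucleotide-frequency (ONF) signatures and PCA ordination.

Full-length 16S genes are summarized as relative k-mer frequency vectors
(tetranucleotides by default) and ordinated by plain covariance PCA.  No
strand canonicalization is applied by default: 16S genes are oriented, so
a k-mer and its reverse complement are distinct signals; a flag enables
canonicalization for raw-contig input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Optional

import numpy as np

from .errors import InvalidArgument
from .records import SequenceRecord, reverse_complement

__all__ = ["ONFMatrix", "onf_matrix", "pca", "PCAResult"]

_BASES = "ACGT"


def kmer_alphabet(k: int) -> list[str]:
    return ["".join(p) for p in product(_BASES, repeat=k)]


def _kmer_counts(seq: str, k: int) -> np.ndarray:
    """Overlapping k-mer counts; windows containing non-ACGT are skipped."""
    code = {b: i for i, b in enumerate(_BASES)}
    counts = np.zeros(4 ** k)
    enc = np.array([code.get(c, -1) for c in seq], dtype=np.int64)
    n = len(seq) - k + 1
    if n <= 0:
        return counts
    windows = np.lib.stride_tricks.sliding_window_view(enc, k)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return counts
    powers = 4 ** np.arange(k - 1, -1, -1)
    idx = (windows[valid] * powers).sum(axis=1)
    np.add.at(counts, idx, 1)
    return counts


@dataclass
class ONFMatrix:
    """Rows = sequences, columns = all 4^k k-mers, entries = relative
    frequencies (each row sums to 1)."""

    labels: list[str]
    kmers: list[str]
    freqs: np.ndarray
    k: int
    genus: list[str] = field(default_factory=list)
    rejected: list[str] = field(default_factory=list)


def onf_matrix(seqs: list[SequenceRecord], k: int = 4,
               genus_labels: Optional[dict[str, str]] = None,
               canonical: bool = False) -> ONFMatrix:
    """Relative k-mer frequency matrix over oriented sequences.

    Rows with zero countable k-mers (too short, or all-ambiguous) are
    rejected and listed in ``rejected``.
    """
    if not (1 <= k <= 6):
        raise InvalidArgument("k must be in 1..6")
    labels, rows, genus, rejected = [], [], [], []
    for rec in seqs:
        seq = rec.seq.upper()
        counts = _kmer_counts(seq, k)
        if canonical:
            counts = counts + _kmer_counts(reverse_complement(seq), k)
        total = counts.sum()
        if total == 0:
            rejected.append(rec.id)
            continue
        labels.append(rec.id)
        rows.append(counts / total)
        if genus_labels:
            genus.append(genus_labels.get(rec.genome_id, ""))
    freqs = np.array(rows) if rows else np.zeros((0, 4 ** k))
    return ONFMatrix(labels, kmer_alphabet(k), freqs, k, genus, rejected)


@dataclass
class PCAResult:
    scores: np.ndarray              # (n_rows, n_components)
    loadings: np.ndarray            # (n_components, n_features)
    explained_variance_ratio: np.ndarray
    means: np.ndarray


def pca(X: ONFMatrix | np.ndarray, n_components: int = 2) -> PCAResult:
    """Covariance PCA with mean centering, no scaling.

    Sign convention: each loading vector's largest-magnitude entry is made
    positive, so scores are reproducible across runs and BLAS builds.
    """
    mat = X.freqs if isinstance(X, ONFMatrix) else np.asarray(X, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise InvalidArgument("pca needs at least two rows")
    means = mat.mean(axis=0)
    centered = mat - means
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    if n_components > rank:
        raise InvalidArgument(
            f"n_components={n_components} exceeds matrix rank {rank}")
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    # fix signs
    flips = np.ones(n_components)
    for i in range(n_components):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            flips[i] = -1.0
    Vt = Vt * flips[:, None]
    scores = (U * s) * flips[None, :]
    var = (s ** 2) / (mat.shape[0] - 1)
    total_var = centered.var(axis=0, ddof=1).sum()
    ratio = var / total_var if total_var > 0 else np.zeros_like(var)
    return PCAResult(scores, Vt, ratio, means)
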