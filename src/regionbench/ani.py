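"""Average nucleotide identity by fragment mapping, and 95% ANI grouping.

The estimator follows the classic fragment-based recipe: the query genome is
cut into non-overlapping 1020-bp windows, each window is located on the
subject via shared 16-mers (both strands), the best candidate locus is
aligned, and ANI is the mean identity over fragments that align at >= 70%
identity.  The final value is symmetrized as the mean of the two directed
estimates.  Base-level alignment of a fragment against its candidate window
uses edlib's bit-parallel edit-distance alignment in semi-global mode, with
the edit distance capped at 30% of the fragment length (any alignment worse
than that would fail the 70% identity acceptance rule anyway).

Grouping at the 95% identity threshold is single-linkage: connected
components of the graph with an edge wherever ANI >= threshold — the natural
reading of "grouped into ANI groups using a 95% identity threshold".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np
from skbio import DistanceMatrix

from .errors import InvalidArgument
from .records import SequenceRecord, reverse_complement

log = logging.getLogger("regionbench")

__all__ = ["ANIResult", "ANIGroups", "pairwise_ani", "ani_distance_matrix",
           "ani_groups", "ani_fragment_table"]

FRAG_LEN = 1020
KMER = 16
MIN_IDENTITY = 70.0      # percent; fragments below are not "aligned"
BAND_FRACTION = 0.1      # candidate-window padding (~DP band width)


@dataclass
class ANIResult:
    genome_a: str
    genome_b: str
    ani: Optional[float]           # percent, None when undefined
    n_fragments_aligned: int
    n_fragments_total: int
    fragment_identities: list[float] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return self.ani is not None


@dataclass
class ANIGroups:
    """Dense partition of genomes into ANI groups."""

    assignment: dict[str, int]
    n_groups: int

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for g, grp in self.assignment.items():
            out.setdefault(grp, []).append(g)
        return {k: sorted(v) for k, v in out.items()}


class _KmerIndex:
    """16-mer position index over a subject genome and its reverse
    complement, concatenated conceptually as two strands."""

    def __init__(self, seq: str, k: int = KMER):
        self.k = k
        self.seq = seq
        self.rc = reverse_complement(seq)
        self.index: dict[str, list[tuple[int, int]]] = {}
        for strand, s in ((0, seq), (1, self.rc)):
            for i in range(0, len(s) - k + 1):
                self.index.setdefault(s[i:i + k], []).append((strand, i))

    def _vote(self, frag: str, stride: int) -> Optional[tuple[int, int]]:
        votes: dict[tuple[int, int], int] = {}
        hits: list[tuple[int, int]] = []
        k = self.k
        get = self.index.get
        for p in range(0, len(frag) - k + 1, stride):
            for strand, loc in get(frag[p:p + k], ()):
                offset = loc - p
                key = (strand, offset // 64)
                votes[key] = votes.get(key, 0) + 1
                hits.append((strand * (1 << 40) + (offset // 64), offset))
        if not votes:
            return None
        (strand, bucket), _ = max(votes.items(),
                                  key=lambda kv: (kv[1], -kv[0][0],
                                                  -kv[0][1]))
        code = strand * (1 << 40) + bucket
        offsets = sorted(off for c, off in hits if c == code)
        return strand, int(offsets[len(offsets) // 2])

    def locate(self, frag: str) -> Optional[tuple[int, int]]:
        """Best (strand, offset) by seed voting; offsets are bucketed to
        absorb small indel drift.  A sparse seed pass handles similar
        genomes cheaply; divergent pairs fall back to dense seeding."""
        hit = self._vote(frag, 48)
        if hit is None:
            hit = self._vote(frag, 4)
        return hit


def _directed_identities(query: str, index: _KmerIndex,
                         frag_len: int) -> list[Optional[float]]:
    """Percent identity per query fragment (None = unaligned)."""
    pad = int(BAND_FRACTION * frag_len)
    max_dist = int(0.3 * frag_len)
    out: list[Optional[float]] = []
    n_frags = len(query) // frag_len
    for f in range(n_frags):
        frag = query[f * frag_len:(f + 1) * frag_len]
        hit = index.locate(frag)
        if hit is None:
            out.append(None)
            continue
        strand, offset = hit
        subject = index.seq if strand == 0 else index.rc
        lo = max(0, offset - pad)
        hi = min(len(subject), offset + frag_len + pad)
        window = subject[lo:hi]
        if len(window) < frag_len - pad:
            out.append(None)
            continue
        res = edlib.align(frag, window, mode="HW", task="distance",
                          k=max_dist)
        dist = res["editDistance"]
        if dist < 0:
            out.append(None)
            continue
        identity = 100.0 * (frag_len - dist) / frag_len
        out.append(identity if identity >= MIN_IDENTITY else None)
    return out


def pairwise_ani(a: SequenceRecord | str, b: SequenceRecord | str,
                 frag_len: int = FRAG_LEN, k: int = KMER,
                 _index_a: Optional[_KmerIndex] = None,
                 _index_b: Optional[_KmerIndex] = None) -> ANIResult:
    """Symmetrized fragment-mapping ANI between two genomes.

    The reported value is the mean of the a->b and b->a directed means;
    fragment identities from both directions are kept for bootstrapping.
    Returns ``ani=None`` (undefined) when no fragment aligns.
    """
    id_a, seq_a = _unpack(a)
    id_b, seq_b = _unpack(b)
    if len(seq_a) < frag_len or len(seq_b) < frag_len:
        raise InvalidArgument(
            f"genomes must be >= frag_len={frag_len} bases "
            f"({id_a}: {len(seq_a)}, {id_b}: {len(seq_b)})")
    fwd = _directed_identities(seq_a, _index_b or _KmerIndex(seq_b, k),
                               frag_len)
    rev = _directed_identities(seq_b, _index_a or _KmerIndex(seq_a, k),
                               frag_len)
    total = len(fwd) + len(rev)
    directed_means = []
    kept: list[float] = []
    for idents in (fwd, rev):
        vals = [x for x in idents if x is not None]
        kept.extend(vals)
        if vals:
            directed_means.append(sum(vals) / len(vals))
    ani = (sum(directed_means) / len(directed_means)) if directed_means \
        else None
    return ANIResult(id_a, id_b, ani, len(kept), total, kept)


def _unpack(g: SequenceRecord | str) -> tuple[str, str]:
    if isinstance(g, SequenceRecord):
        return g.genome_id, g.seq.upper()
    return "<anonymous>", g.upper()


def ani_distance_matrix(genomes: Sequence[SequenceRecord],
                        frag_len: int = FRAG_LEN, k: int = KMER
                        ) -> tuple[DistanceMatrix, list[ANIResult]]:
    """All-pairs ANI as a distance matrix d = 1 - ANI/100.

    Undefined pairs (no aligned fragments) get distance 1.0 with a warning,
    keeping the matrix complete for tree building.
    """
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise InvalidArgument("duplicate genome ids")
    n = len(genomes)
    mat = np.zeros((n, n))
    results: list[ANIResult] = []
    # one k-mer index per genome, shared across all its pairings
    indexes = [_KmerIndex(g.seq.upper(), k) for g in genomes]
    for i in range(n):
        for j in range(i + 1, n):
            res = pairwise_ani(genomes[i], genomes[j], frag_len, k,
                               _index_a=indexes[i], _index_b=indexes[j])
            results.append(res)
            if res.ani is None:
                log.warning("ANI undefined for pair (%s, %s); "
                            "using distance 1.0", ids[i], ids[j])
                d = 1.0
            else:
                d = 1.0 - res.ani / 100.0
            mat[i, j] = mat[j, i] = max(0.0, d)
    return DistanceMatrix(mat, ids), results


def ani_fragment_table(results: Sequence[ANIResult]
                       ) -> dict[tuple[str, str], list[float]]:
    """Pair -> per-fragment identities, for the dendrogram bootstrap."""
    return {(r.genome_a, r.genome_b): list(r.fragment_identities)
            for r in results}


def ani_groups(D: DistanceMatrix, threshold: float = 95.0) -> ANIGroups:
    """Single-linkage components of the >= threshold-ANI graph.

    ``D`` holds distances 1 - ANI/100, so the edge rule is
    d <= 1 - threshold/100.  Group indices are dense from 0, ordered by
    each group's smallest genome id.
    """
    ids = list(D.ids)
    mat = np.asarray(D.data, dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise InvalidArgument("distance matrix must be square")
    cutoff = 1.0 - threshold / 100.0
    n = len(ids)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if mat[i, j] <= cutoff + 1e-12:
                parent[find(i)] = find(j)
    roots: dict[int, list[str]] = {}
    for i in range(n):
        roots.setdefault(find(i), []).append(ids[i])
    groups = sorted(roots.values(), key=lambda members: min(members))
    assignment = {g: idx for idx, members in enumerate(groups)
                  for g in members}
    return ANIGroups(assignment, len(groups))
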