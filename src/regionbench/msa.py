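"""Multiple sequence alignment and per-column Shannon entropy.

The aligner is a classic progressive scheme: a UPGMA guide tree on 6-mer
cosine distances, then profile-profile Needleman-Wunsch merges with
column-average scoring and "once a gap, always a gap" semantics.  It is not
meant to compete with mafft on hard data — the synthetic sequences this
package studies are born nearly aligned — but it is fully specified and
deterministic, which the downstream benchmark needs.

Entropy is reported in bits (log base 2).  Under the default
``gap_mode="exclude"`` gaps and N are removed from a column before
frequencies are formed, so entropy lies in [0, 2]; under ``fifth-state`` the
gap is a fifth symbol and the ceiling is log2(5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgument
from .records import SequenceRecord

__all__ = ["Alignment", "EntropyProfile", "needleman_wunsch",
           "progressive_msa", "column_entropy", "region_entropy_summary"]

_ALPHA = "ACGT-"          # profile alphabet; N is treated as missing
_AIDX = {c: i for i, c in enumerate(_ALPHA)}


@dataclass
class Alignment:
    """Equal-length gapped rows over {A,C,G,T,N,-} with unique labels."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise InvalidArgument("labels and rows differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise InvalidArgument("duplicate labels in alignment")
        if self.rows and len({len(r) for r in self.rows}) > 1:
            raise InvalidArgument("alignment rows have unequal lengths")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_array(self) -> np.ndarray:
        """Rows as a (n_rows, n_cols) array of single-byte characters."""
        if not self.rows:
            return np.empty((0, 0), dtype="S1")
        return np.frombuffer("".join(self.rows).encode("ascii"),
                             dtype="S1").reshape(self.n_rows, self.n_cols)

    def select(self, labels: Sequence[str]) -> "Alignment":
        index = {l: i for i, l in enumerate(self.labels)}
        missing = [l for l in labels if l not in index]
        if missing:
            raise InvalidArgument(f"labels not in alignment: {missing}")
        return Alignment(list(labels), [self.rows[index[l]] for l in labels])

    def columns(self, start: int, end: int) -> "Alignment":
        if not (0 <= start <= end <= self.n_cols):
            raise InvalidArgument(
                f"column range [{start}, {end}) outside alignment "
                f"of width {self.n_cols}")
        return Alignment(list(self.labels),
                         [r[start:end] for r in self.rows])


@dataclass
class EntropyProfile:
    """Per-column entropies with optional smoothing and region annotations."""

    entropy: np.ndarray
    gap_mode: str
    smoothed: Optional[np.ndarray] = None
    regions: list[tuple[str, int, int]] = field(default_factory=list)
    all_gap_columns: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=bool))


# ---------------------------------------------------------------------------
# pairwise global alignment

_GAP = -1  # traceback codes: 0 diagonal, 1 up (gap in b), 2 left (gap in a)


def _nw_dp(score: np.ndarray, gap: float) -> np.ndarray:
    """Fill the global-alignment DP table for a precomputed match-score
    matrix under a linear gap penalty.  Vectorized row-wise: within a row,
    H[i, j] = max_{k<=j} M[i, k] - gap_cost*(j-k) with
    M[i, j] = max(H[i-1, j-1] + s[i, j], H[i-1, j] - gap_cost), which a
    running maximum computes without an inner Python loop."""
    n, m = score.shape
    H = np.empty((n + 1, m + 1))
    H[0, :] = np.arange(m + 1) * gap
    H[:, 0] = np.arange(n + 1) * gap
    idx = np.arange(m + 1)
    for i in range(1, n + 1):
        M = np.empty(m + 1)
        M[0] = H[i, 0]
        M[1:] = np.maximum(H[i - 1, :-1] + score[i - 1],
                           H[i - 1, 1:] + gap)
        H[i] = np.maximum.accumulate(M - gap * idx) + gap * idx
    return H


def _nw_traceback(H: np.ndarray, score: np.ndarray, gap: float
                  ) -> list[tuple[int, int]]:
    """Recover one optimal path, preferring diagonal > up > left on ties."""
    i, j = score.shape
    path: list[tuple[int, int]] = []
    eps = 1e-9
    while i > 0 or j > 0:
        h = H[i, j]
        if i > 0 and j > 0 and abs(H[i - 1, j - 1] + score[i - 1, j - 1]
                                   - h) < eps:
            i, j = i - 1, j - 1
            path.append((0, 0))
        elif i > 0 and abs(H[i - 1, j] + gap - h) < eps:
            i -= 1
            path.append((0, 1))
        else:
            j -= 1
            path.append((1, 0))
    path.reverse()
    return path


def needleman_wunsch(a: str, b: str, match: float = 1.0,
                     mismatch: float = -1.0, gap: float = -1.0
                     ) -> tuple[str, str, float]:
    """Optimal global alignment of two sequences under linear gap penalty.

    Ties during traceback prefer diagonal over up over left, making the
    reported alignment deterministic.
    """
    if not a or not b:
        raise InvalidArgument("needleman_wunsch: empty sequence")
    ea = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    eb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    score = np.where(ea[:, None] == eb[None, :], match, mismatch)
    H = _nw_dp(score, gap)
    path = _nw_traceback(H, score, gap)
    out_a, out_b = [], []
    i = j = 0
    for skip_a, skip_b in path:
        if skip_a == 0 and skip_b == 0:
            out_a.append(a[i]); out_b.append(b[j]); i += 1; j += 1
        elif skip_b == 1:
            out_a.append(a[i]); out_b.append("-"); i += 1
        else:
            out_a.append("-"); out_b.append(b[j]); j += 1
    return "".join(out_a), "".join(out_b), float(H[-1, -1])


# ---------------------------------------------------------------------------
# progressive MSA


def _profile(aln_rows: list[str]) -> np.ndarray:
    """Column frequency profile over A,C,G,T,- (N contributes nothing)."""
    arr = np.frombuffer("".join(aln_rows).encode("ascii"),
                        dtype=np.uint8).reshape(len(aln_rows), -1)
    prof = np.zeros((arr.shape[1], len(_ALPHA)))
    for sym, k in _AIDX.items():
        prof[:, k] = (arr == ord(sym)).sum(axis=0)
    return prof / len(aln_rows)


def _substitution_matrix(match: float, mismatch: float, gap: float
                         ) -> np.ndarray:
    S = np.full((5, 5), mismatch)
    np.fill_diagonal(S, match)
    S[4, :] = gap
    S[:, 4] = gap
    S[4, 4] = 0.0
    return S


def _merge(rows_a: list[str], rows_b: list[str], match: float,
           mismatch: float, gap: float) -> tuple[list[str], list[str]]:
    pa, pb = _profile(rows_a), _profile(rows_b)
    S = _substitution_matrix(match, mismatch, gap)
    score = pa @ S @ pb.T
    H = _nw_dp(score, gap)
    path = _nw_traceback(H, score, gap)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for skip_a, skip_b in path:
        take_a = skip_a == 0 and (skip_b == 0 or skip_b == 1)
        take_b = skip_a == 0 and skip_b == 0 or skip_a == 1
        if take_a:
            for r, row in enumerate(rows_a):
                out_a[r].append(row[i])
            i += 1
        else:
            for r in range(len(rows_a)):
                out_a[r].append("-")
        if take_b:
            for r, row in enumerate(rows_b):
                out_b[r].append(row[j])
            j += 1
        else:
            for r in range(len(rows_b)):
                out_b[r].append("-")
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def _kmer_cosine_distances(seqs: list[str], k: int = 6) -> np.ndarray:
    from .onf import _kmer_counts

    vecs = np.array([_kmer_counts(s, k) for s in seqs], dtype=float)
    norms = np.linalg.norm(vecs, axis=1)
    norms[norms == 0] = 1.0
    unit = vecs / norms[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    d = 1.0 - cos
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def progressive_msa(seqs: list[SequenceRecord], match: float = 1.0,
                    mismatch: float = -1.0, gap: float = -4.0) -> Alignment:
    """Progressive alignment along a UPGMA guide tree (6-mer cosine
    distances); single-sequence input is returned as a 1-row alignment."""
    if not seqs:
        raise InvalidArgument("progressive_msa: no sequences")
    if len(seqs) == 1:
        return Alignment([seqs[0].id], [seqs[0].seq.upper()])

    from .phylo import upgma
    from skbio import DistanceMatrix

    labels = [r.id for r in seqs]
    dm = DistanceMatrix(_kmer_cosine_distances([r.seq.upper() for r in seqs]),
                        labels)
    guide = upgma(dm)
    by_label = {r.id: r for r in seqs}

    def build(node) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [node.name], [by_label[node.name].seq.upper()]
        parts = [build(c) for c in node.children]
        cur_labels, cur_rows = parts[0]
        for nxt_labels, nxt_rows in parts[1:]:
            cur_rows, nxt_rows = _merge(cur_rows, nxt_rows,
                                        match, mismatch, gap)
            cur_labels = cur_labels + nxt_labels
            cur_rows = cur_rows + nxt_rows
        return cur_labels, cur_rows

    out_labels, out_rows = build(guide.root)
    order = {l: i for i, l in enumerate(out_labels)}
    # report rows in input order
    aln = Alignment(labels, [out_rows[order[l]] for l in labels])
    return aln


# ---------------------------------------------------------------------------
# entropy


def column_entropy(aln: Alignment, gap_mode: str = "exclude",
                   smooth_window: int = 10,
                   regions: Optional[list[tuple[str, int, int]]] = None
                   ) -> EntropyProfile:
    """Shannon entropy (bits) per alignment column.

    ``gap_mode="exclude"`` drops gaps and N before forming frequencies;
    ``"fifth-state"`` keeps the gap as its own symbol (N is still excluded —
    it is missing data, not a state).  Columns with no countable state get
    entropy 0 and are flagged in ``all_gap_columns``.
    """
    if gap_mode not in ("exclude", "fifth-state"):
        raise InvalidArgument(f"unknown gap_mode {gap_mode!r}")
    if aln.n_rows == 0:
        raise InvalidArgument("column_entropy: empty alignment")
    arr = aln.to_array()
    symbols = [b"A", b"C", b"G", b"T"]
    if gap_mode == "fifth-state":
        symbols.append(b"-")
    counts = np.stack([(arr == s).sum(axis=0) for s in symbols]).T
    totals = counts.sum(axis=1)
    flagged = totals == 0
    safe_tot = np.where(flagged, 1, totals)
    p = counts / safe_tot[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(p), 0.0)
    ent = terms.sum(axis=1)
    ent[flagged] = 0.0

    smoothed = None
    if smooth_window and smooth_window > 1 and len(ent) >= smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        smoothed = np.convolve(ent, kernel, mode="same")

    regions = list(regions) if regions else []
    for label, start, end in regions:
        if not (0 <= start < end <= aln.n_cols):
            raise InvalidArgument(
                f"region {label!r} interval [{start}, {end}) outside "
                f"alignment of width {aln.n_cols}")
    return EntropyProfile(ent, gap_mode, smoothed, regions, flagged)


def region_entropy_summary(profile: EntropyProfile) -> pd.DataFrame:
    """Mean and max entropy per annotated region, plus a background row
    covering all unannotated columns."""
    rows = []
    covered = np.zeros(len(profile.entropy), dtype=bool)
    for label, start, end in profile.regions:
        window = profile.entropy[start:end]
        covered[start:end] = True
        rows.append({"region_label": label,
                     "mean_entropy": float(window.mean()),
                     "max_entropy": float(window.max()),
                     "n_columns": int(end - start)})
    if profile.regions and (~covered).any():
        window = profile.entropy[~covered]
        rows.append({"region_label": "background",
                     "mean_entropy": float(window.mean()),
                     "max_entropy": float(window.max()),
                     "n_columns": int((~covered).sum())})
    return pd.DataFrame(rows,
                        columns=["region_label", "mean_entropy",
                                 "max_entropy", "n_columns"])
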