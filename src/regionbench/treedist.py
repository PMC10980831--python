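"""Tree comparison: Robinson-Foulds, generalized Jaccard-RF, and mutual
clustering information.

The classic RF distance counts bipartitions present in one tree but not the
other — an all-or-nothing criterion that saturates quickly on large or noisy
trees.  The generalized Jaccard-Robinson-Foulds (JRF) distance softens it:
each pair of bipartitions gets a Jaccard-style agreement score, an optimal
one-to-one matching between the two split sets maximizes total agreement,
and the normalized distance is

    jrf = (|S1| + |S2| - 2 * sum of matched scores) / (|S1| + |S2|)  in [0, 1].

The per-pair score used here is the orientation-maximized minimum of the two
side-wise Jaccard indices, raised to a concavity exponent k (k=1 by default;
k -> infinity recovers RF).  Mutual clustering information (MCI) scores a
matched pair by the mutual information between the bipartitions viewed as
binary leaf labelings and is reported both as total bits and as a
normalized distance.

Splits are encoded as bitmasks over a shared sorted taxon index; the
canonical side of a split is the side *not* containing taxon 0.  Rooted
dendrograms are unrooted before split extraction so every comparison lives
in one split universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import InvalidArgument
from .tree import Tree, TreeNode

__all__ = ["SplitSet", "TreeComparison", "splits", "rf_distance",
           "jrf_distance", "mci", "brute_force_match"]


@dataclass(frozen=True)
class SplitSet:
    """Non-trivial bipartitions of one tree over an indexed taxon set."""

    taxa: tuple[str, ...]                  # sorted leaf labels
    masks: tuple[int, ...]                 # canonical-side bitmasks, sorted

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def __len__(self) -> int:
        return len(self.masks)

    def side_sets(self, mask: int) -> tuple[frozenset[str], frozenset[str]]:
        inside = frozenset(t for i, t in enumerate(self.taxa)
                           if mask >> i & 1)
        return inside, frozenset(self.taxa) - inside


def splits(tree: Tree) -> SplitSet:
    """One split per internal edge; trivial splits (a side with < 2 taxa)
    are dropped and rooted trees are unrooted first."""
    if tree.rooted:
        tree = tree.unrooted()
    taxa = tuple(sorted(tree.leaf_names()))
    index = {t: i for i, t in enumerate(taxa)}
    full = (1 << len(taxa)) - 1
    found: set[int] = set()

    def walk(node: TreeNode) -> int:
        if node.is_leaf:
            return 1 << index[node.name]
        below = 0
        for c in node.children:
            below |= walk(c)
        size = below.bit_count()
        if 1 < size < len(taxa) - 1:
            mask = (full ^ below) if (below & 1) else below
            found.add(mask)
        return below

    walk(tree.root)
    return SplitSet(taxa, tuple(sorted(found)))


def _check_same_taxa(s1: SplitSet, s2: SplitSet) -> None:
    if s1.taxa != s2.taxa:
        only1 = sorted(set(s1.taxa) - set(s2.taxa))
        only2 = sorted(set(s2.taxa) - set(s1.taxa))
        raise InvalidArgument(
            f"leaf sets differ: only in first {only1}, only in second {only2}")


def _as_splitset(t: Tree | SplitSet) -> SplitSet:
    return t if isinstance(t, SplitSet) else splits(t)


def rf_distance(t1: Tree | SplitSet, t2: Tree | SplitSet) -> int:
    """|S1 symmetric-difference S2|."""
    s1, s2 = _as_splitset(t1), _as_splitset(t2)
    _check_same_taxa(s1, s2)
    return len(set(s1.masks) ^ set(s2.masks))


# ---------------------------------------------------------------------------
# pair scores


def _jaccard_pair_score(mask1: int, mask2: int, n: int, k: float) -> float:
    """Orientation-maximized min-side Jaccard agreement, raised to k."""
    full = (1 << n) - 1
    a, b = mask1, full ^ mask1
    c, d = mask2, full ^ mask2

    def jac(x: int, y: int) -> float:
        union = (x | y).bit_count()
        return (x & y).bit_count() / union if union else 1.0

    same = min(jac(a, c), jac(b, d))
    flip = min(jac(a, d), jac(b, c))
    return max(same, flip) ** k


def _mi_pair_score(mask1: int, mask2: int, n: int) -> float:
    """Mutual information (bits) between two bipartitions as binary
    labelings of the n leaves."""
    full = (1 << n) - 1
    total = 0.0
    for x in (mask1, full ^ mask1):
        for y in (mask2, full ^ mask2):
            nxy = (x & y).bit_count()
            if nxy == 0:
                continue
            nx, ny = x.bit_count(), y.bit_count()
            total += (nxy / n) * np.log2(n * nxy / (nx * ny))
    return max(total, 0.0)


def _split_entropy(mask: int, n: int) -> float:
    p = mask.bit_count() / n
    if p in (0.0, 1.0):
        return 0.0
    return float(-p * np.log2(p) - (1 - p) * np.log2(1 - p))


def _matched_total(s1: SplitSet, s2: SplitSet,
                   score_fn: Callable[[int, int], float]) -> float:
    """Optimal one-to-one matching total via the assignment problem.
    Scores are nonnegative, so a maximum full matching of the smaller side
    is also the best partial matching."""
    if not s1.masks or not s2.masks:
        return 0.0
    M = np.array([[score_fn(m1, m2) for m2 in s2.masks]
                  for m1 in s1.masks])
    rows, cols = linear_sum_assignment(M, maximize=True)
    return float(M[rows, cols].sum())


# ---------------------------------------------------------------------------
# distances


def jrf_distance(t1: Tree | SplitSet, t2: Tree | SplitSet,
                 concavity_k: float = 1.0) -> float:
    """Normalized generalized Jaccard-Robinson-Foulds distance in [0, 1].

    Degenerate conventions: two split-free trees are at distance 0; a
    split-free tree (star) versus a resolved tree is at distance 1.
    """
    if concavity_k <= 0:
        raise InvalidArgument("concavity_k must be > 0")
    s1, s2 = _as_splitset(t1), _as_splitset(t2)
    _check_same_taxa(s1, s2)
    if not s1.masks and not s2.masks:
        return 0.0
    if not s1.masks or not s2.masks:
        return 1.0
    n = s1.n_taxa
    sim = 2.0 * _matched_total(
        s1, s2, lambda a, b: _jaccard_pair_score(a, b, n, concavity_k))
    total = len(s1) + len(s2)
    return max(0.0, (total - sim) / total)


@dataclass
class TreeComparison:
    jrf: float
    mci: float
    mci_distance: float
    rf: int


def mci(t1: Tree | SplitSet, t2: Tree | SplitSet) -> tuple[float, float]:
    """Mutual clustering information.

    Returns ``(mci_bits, normalized_distance)`` where the distance is
    1 - MCI / max(sum H(S1), sum H(S2)); both values are 0-splits-safe
    (star versus anything has MCI 0 and distance 1 unless both are stars).
    """
    s1, s2 = _as_splitset(t1), _as_splitset(t2)
    _check_same_taxa(s1, s2)
    n = s1.n_taxa
    total = _matched_total(s1, s2, lambda a, b: _mi_pair_score(a, b, n))
    h1 = sum(_split_entropy(m, n) for m in s1.masks)
    h2 = sum(_split_entropy(m, n) for m in s2.masks)
    denom = max(h1, h2)
    if denom == 0.0:
        # both trees are stars: identical (empty) split sets
        return 0.0, 0.0
    return total, 1.0 - total / denom


def compare(t1: Tree, t2: Tree, concavity_k: float = 1.0) -> TreeComparison:
    s1, s2 = splits(t1), splits(t2)
    bits, dist = mci(s1, s2)
    return TreeComparison(jrf_distance(s1, s2, concavity_k), bits, dist,
                          rf_distance(s1, s2))


# ---------------------------------------------------------------------------
# exhaustive oracle


def brute_force_match(s1: SplitSet, s2: SplitSet,
                      pair_score: Callable[[int, int], float]) -> float:
    """Exact optimal partial-matching total by exhaustive enumeration.

    Test oracle for the assignment-solver path; limited to 8 splits a side.
    """
    if len(s1) > 8 or len(s2) > 8:
        raise InvalidArgument("brute_force_match is limited to <= 8 splits")
    m2 = list(s2.masks)

    def best(i: int, used: frozenset[int]) -> float:
        if i == len(s1.masks):
            return 0.0
        # leave split i unmatched
        score = best(i + 1, used)
        for j, mask2 in enumerate(m2):
            if j in used:
                continue
            score = max(score,
                        pair_score(s1.masks[i], mask2)
                        + best(i + 1, used | {j}))
        return score

    return best(0, frozenset())
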