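"""Distance-based tree reconstruction: JC distances, NJ, UPGMA, bootstraps.

All trees the benchmark compares are distance trees: neighbor-joining for
sequence alignments (16S regions, concatenated markers) and UPGMA for the
ANI dendrogram.  NJ here is the canonical Saitou-Nei algorithm with
Studier-Keppler updates, a deterministic tie-break (lexicographically
smallest label pair on equal Q), and clamp-and-transfer handling of negative
branch length estimates: a negative branch is set to zero and its deficit
moved to the sibling branch, preserving the pair's summed length.
"""

from __future__ import annotations

import logging
from typing import Callable, Optional, Sequence

import numpy as np
from skbio import DistanceMatrix

from .errors import DataError, InvalidArgument
from .msa import Alignment
from .tree import Tree, TreeNode

log = logging.getLogger("regionbench")

__all__ = ["jc_distance_matrix", "neighbor_joining", "upgma",
           "bootstrap_support", "bootstrap_ani_dendrogram", "scmg_tree"]

#: JC distance assigned when p-distance saturates (p >= 0.75).
JC_CAP = 5.0


def jc_distance_matrix(aln: Alignment, cap: float = JC_CAP) -> DistanceMatrix:
    """Jukes-Cantor distances d = -(3/4) ln(1 - 4p/3) over columns where
    both rows carry a plain base (gaps and N excluded pairwise)."""
    if aln.n_rows < 2:
        raise InvalidArgument("need at least 2 rows for distances")
    arr = aln.to_array()
    bases = (arr == b"A") | (arr == b"C") | (arr == b"G") | (arr == b"T")
    n = aln.n_rows
    D = np.zeros((n, n))
    for i in range(n):
        shared = bases[i] & bases
        comparable = shared.sum(axis=1)
        diff = ((arr != arr[i]) & shared).sum(axis=1)
        zero = comparable == 0
        zero[i] = False
        if zero.any():
            j = int(np.nonzero(zero)[0][0])
            raise DataError(
                f"no comparable columns between {aln.labels[i]!r} "
                f"and {aln.labels[j]!r}")
        p = diff / np.maximum(comparable, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = -0.75 * np.log1p(-4.0 * p / 3.0)
        saturated = p >= 0.75
        if saturated.any() and not saturated[i]:
            log.warning("jc_distance_matrix: %d saturated pairs for %s "
                        "capped at %g", int(saturated.sum()),
                        aln.labels[i], cap)
        d[saturated] = cap
        D[i] = d
        D[i, i] = 0.0
    D = (D + D.T) / 2.0
    return DistanceMatrix(D, list(aln.labels))


def _as_matrix(D: DistanceMatrix) -> tuple[list[str], np.ndarray]:
    return list(D.ids), np.array(D.data, dtype=float)


def _argmin_pair(score: np.ndarray, labels: Sequence[str],
                 tol: float = 1e-12) -> tuple[int, int]:
    """Index pair minimizing ``score`` (upper triangle); ties resolved by
    the lexicographically smallest sorted label pair."""
    n = score.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = score[iu, ju]
    best = vals.min()
    cand = np.nonzero(vals <= best + tol)[0]
    key = min(cand, key=lambda c: tuple(sorted((labels[iu[c]],
                                                labels[ju[c]]))))
    return int(iu[key]), int(ju[key])


def neighbor_joining(D: DistanceMatrix) -> Tree:
    """Canonical NJ; returns an unrooted tree (trifurcating root node)."""
    labels, mat = _as_matrix(D)
    n = len(labels)
    if n < 3:
        raise InvalidArgument("neighbor_joining needs >= 3 taxa")
    nodes: list[TreeNode] = [TreeNode(l) for l in labels]
    names = list(labels)
    counter = 0
    while len(names) > 3:
        m = len(names)
        r = mat.sum(axis=1)
        Q = (m - 2) * mat - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = _argmin_pair(Q, names)
        dij = mat[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp-and-transfer keeps branch lengths nonnegative
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # Studier-Keppler distance update
        du = (mat[i] + mat[j] - dij) / 2.0
        keep = [k for k in range(m) if k not in (i, j)]
        new_mat = np.empty((m - 1, m - 1))
        new_mat[:-1, :-1] = mat[np.ix_(keep, keep)]
        new_mat[-1, :-1] = new_mat[:-1, -1] = du[keep]
        new_mat[-1, -1] = 0.0
        mat = new_mat
        nodes = [nodes[k] for k in keep] + [parent]
        names = [names[k] for k in keep] + [f"__nj{counter}__"]
        counter += 1
    # resolve the last three nodes around an unrooted center
    a, b, c = 0, 1, 2
    la = (mat[a, b] + mat[a, c] - mat[b, c]) / 2.0
    lb = (mat[a, b] + mat[b, c] - mat[a, c]) / 2.0
    lc = (mat[a, c] + mat[b, c] - mat[a, b]) / 2.0
    for node, ln in zip(nodes, (la, lb, lc)):
        node.length = float(max(ln, 0.0))
    root = TreeNode(children=list(nodes))
    return Tree(root, rooted=False)


def upgma(D: DistanceMatrix) -> Tree:
    """Average-linkage agglomeration; returns a rooted ultrametric
    dendrogram.  Equal candidate merges resolve to the smallest label pair."""
    labels, mat = _as_matrix(D)
    n = len(labels)
    if n < 2:
        raise InvalidArgument("upgma needs >= 2 taxa")
    nodes: list[TreeNode] = [TreeNode(l) for l in labels]
    names = list(labels)
    heights = [0.0] * n
    sizes = [1] * n
    while len(nodes) > 1:
        i, j = _argmin_pair(mat, names)
        h = mat[i, j] / 2.0
        nodes[i].length = h - heights[i]
        nodes[j].length = h - heights[j]
        parent = TreeNode(children=[nodes[i], nodes[j]])
        si, sj = sizes[i], sizes[j]
        merged = (si * mat[i] + sj * mat[j]) / (si + sj)
        m = len(nodes)
        keep = [k for k in range(m) if k not in (i, j)]
        new_mat = np.empty((m - 1, m - 1))
        new_mat[:-1, :-1] = mat[np.ix_(keep, keep)]
        new_mat[-1, :-1] = new_mat[:-1, -1] = merged[keep]
        new_mat[-1, -1] = 0.0
        mat = new_mat
        nodes = [nodes[k] for k in keep] + [parent]
        names = [names[k] for k in keep] + [min(names[i], names[j])]
        heights = [heights[k] for k in keep] + [h]
        sizes = [sizes[k] for k in keep] + [si + sj]
    return Tree(nodes[0], rooted=True)


# ---------------------------------------------------------------------------
# bootstrap support


def _clades(tree: Tree) -> set[frozenset[str]]:
    """Clusters (rooted) or split sides (unrooted) as leaf-name frozensets;
    trivial groups excluded."""
    all_leaves = frozenset(tree.leaf_names())
    out: set[frozenset[str]] = set()

    def collect(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(collect(c) for c in node.children))
        if 1 < len(below) < len(all_leaves):
            if tree.rooted:
                out.add(below)
            else:
                # canonical split side: the side without the smallest leaf
                rest = all_leaves - below
                if len(rest) > 1:
                    side = below if min(all_leaves) in rest else rest
                    out.add(side)
        return below

    collect(tree.root)
    return out


def _builder_fn(builder: str) -> Callable[[DistanceMatrix], Tree]:
    if builder == "nj":
        return neighbor_joining
    if builder == "upgma":
        return upgma
    raise InvalidArgument(f"unknown builder {builder!r}")


def bootstrap_support(aln: Alignment, builder: str = "nj",
                      n_reps: int = 100, seed: int = 0) -> Tree:
    """Column bootstrap: resample alignment columns with replacement,
    rebuild, and annotate each internal node of the point-estimate tree
    with the percentage of replicates containing its bipartition (cluster,
    for rooted dendrograms)."""
    if n_reps < 1:
        raise InvalidArgument("n_reps must be >= 1")
    build = _builder_fn(builder)
    main = build(jc_distance_matrix(aln))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {g: 0 for g in _clades(main)}
    arr = aln.to_array()
    for _ in range(n_reps):
        cols = rng.integers(0, aln.n_cols, size=aln.n_cols)
        rows = ["".join(row) for row in
                arr[:, cols].astype("U1")]
        rep = build(jc_distance_matrix(Alignment(list(aln.labels), rows)))
        for g in _clades(rep):
            if g in counts:
                counts[g] += 1
    _annotate(main, {g: 100.0 * c / n_reps for g, c in counts.items()})
    return main


def bootstrap_ani_dendrogram(fragment_identities: dict[tuple[str, str],
                                                       list[float]],
                             labels: Sequence[str], n_reps: int = 100,
                             seed: int = 0) -> Tree:
    """Bootstrap the ANI dendrogram by resampling each genome pair's
    per-fragment identities with replacement and re-clustering."""
    if n_reps < 1:
        raise InvalidArgument("n_reps must be >= 1")
    labels = list(labels)
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)

    def build(resample: Optional[np.random.Generator]) -> Tree:
        mat = np.zeros((n, n))
        for (a, b), idents in fragment_identities.items():
            vals = np.asarray(idents, dtype=float)
            if resample is not None and len(vals):
                vals = vals[resample.integers(0, len(vals), size=len(vals))]
            ani = float(vals.mean()) if len(vals) else 0.0
            d = 1.0 - ani / 100.0
            mat[index[a], index[b]] = mat[index[b], index[a]] = d
        return upgma(DistanceMatrix(mat, labels))

    main = build(None)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {g: 0 for g in _clades(main)}
    for _ in range(n_reps):
        rep = build(rng)
        for g in _clades(rep):
            if g in counts:
                counts[g] += 1
    _annotate(main, {g: 100.0 * c / n_reps for g, c in counts.items()})
    return main


def _annotate(tree: Tree, supports: dict[frozenset[str], float]) -> None:
    all_leaves = frozenset(tree.leaf_names())

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        key = below
        if not tree.rooted and min(all_leaves) in below:
            key = all_leaves - below
        if 1 < len(below) < len(all_leaves) and key in supports:
            node.support = supports[key]
        return below

    walk(tree.root)


# ---------------------------------------------------------------------------
# concatenated marker-gene (SCMG) tree


def scmg_tree(marker_alignments: list[Alignment], n_reps: int = 100,
              seed: int = 0) -> Tree:
    """Concatenate marker alignments (gap-filling genomes missing from a
    marker), then NJ on JC distances with column-bootstrap supports."""
    if not marker_alignments:
        raise InvalidArgument("no marker alignments")
    sets = [set(a.labels) for a in marker_alignments]
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            if not (sets[i] & sets[j]):
                raise DataError(
                    f"marker alignments {i} and {j} share no genomes")
    genomes = sorted(set().union(*sets))
    rows = {g: [] for g in genomes}
    for aln in marker_alignments:
        index = {l: k for k, l in enumerate(aln.labels)}
        filler = "-" * aln.n_cols
        for g in genomes:
            rows[g].append(aln.rows[index[g]] if g in index else filler)
    concat = Alignment(genomes, ["".join(rows[g]) for g in genomes])
    return bootstrap_support(concat, "nj", n_reps=n_reps, seed=seed)
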