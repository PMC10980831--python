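"""Per-genus benchmarking of variable regions against whole-genome trees.

The central object is a genera x tree-source table of JRF distances to each
genus's ANI dendrogram (columns: full-length 16S and the six variable
regions), its row-wise z-scored companion, and the per-genus best region
(argmin of raw JRF over the variable-region columns).  Supporting statistics
mirror the rest of the study design: the ANI-versus-marker-gene adequacy
check with a paired Wilcoxon signed-rank test, dereplicated subsampling (one
genome per ANI group, repeated), homogeneity/completeness of clusterings,
and correlation of distances with ANI-group counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr, rankdata, spearmanr

from .ani import ANIGroups
from .errors import DataError, InvalidArgument
from .msa import Alignment
from .phylo import jc_distance_matrix, neighbor_joining, upgma
from .regions import PANEL_ORDER
from .tree import Tree
from .treedist import jrf_distance

log = logging.getLogger("regionbench")

__all__ = ["genus_benchmark", "zscore_rows", "best_region", "ani_adequacy",
           "dereplicate_benchmark", "SubsampleResult",
           "wilcoxon_signed_rank", "homogeneity_completeness",
           "heatmap_clusters", "correlate", "FULL_LENGTH_COLUMN"]

FULL_LENGTH_COLUMN = "16S"

#: Fewest genomes shared between two trees for a JRF cell to be computed.
MIN_SHARED_GENOMES = 4


def _tree_from_alignment(aln: Alignment) -> Tree:
    return neighbor_joining(jc_distance_matrix(aln))


def _restricted_jrf(t1: Tree, t2: Tree, concavity_k: float = 1.0
                    ) -> Optional[float]:
    """JRF over the leaf intersection; None when fewer than
    MIN_SHARED_GENOMES genomes are shared."""
    shared = sorted(set(t1.leaf_names()) & set(t2.leaf_names()))
    if len(shared) < MIN_SHARED_GENOMES:
        return None
    r1 = t1.restrict(shared) if len(shared) < t1.n_leaves() else t1
    r2 = t2.restrict(shared) if len(shared) < t2.n_leaves() else t2
    return jrf_distance(r1, r2, concavity_k)


def genus_benchmark(region_alignments: dict[str, Alignment],
                    ani_dendrogram: Tree,
                    concavity_k: float = 1.0) -> dict[str, float]:
    """One benchmark row: per tree source, the JRF distance between its NJ
    tree and the genus ANI dendrogram (leaf sets intersected per cell;
    pruned genomes are logged).  Missing cells are NaN."""
    row: dict[str, float] = {}
    for label, aln in region_alignments.items():
        if aln.n_rows < MIN_SHARED_GENOMES:
            log.warning("genus_benchmark: %s has %d genomes (<%d); cell "
                        "missing", label, aln.n_rows, MIN_SHARED_GENOMES)
            row[label] = math.nan
            continue
        tree = _tree_from_alignment(aln)
        dropped = set(ani_dendrogram.leaf_names()) - set(aln.labels)
        if dropped:
            log.info("genus_benchmark: %s prunes %d genomes from the "
                     "reference", label, len(dropped))
        jrf = _restricted_jrf(tree, ani_dendrogram, concavity_k)
        row[label] = math.nan if jrf is None else jrf
    return row


def zscore_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores with sample sd (ddof=1); missing cells are excluded
    from mean/sd and stay missing; a zero-sd row maps to all zeros."""
    def zrow(row: pd.Series) -> pd.Series:
        vals = row.dropna()
        if len(vals) < 2:
            return row * 0.0
        sd = vals.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            return row * 0.0
        return (row - vals.mean()) / sd

    return table.apply(zrow, axis=1)


def best_region(row: pd.Series | dict[str, float],
                panel_order: Sequence[str] = PANEL_ORDER) -> str:
    """Argmin of raw JRF over the variable-region columns (full-length 16S
    excluded); ties break toward the earliest region in panel order."""
    if isinstance(row, dict):
        row = pd.Series(row)
    candidates = [(row[lab], i, lab) for i, lab in enumerate(panel_order)
                  if lab in row.index and not pd.isna(row[lab])]
    if not candidates:
        raise DataError("best_region: all region cells are missing")
    return min(candidates)[2]


# ---------------------------------------------------------------------------
# ANI adequacy (is the ANI dendrogram a fair stand-in for the marker tree?)


def ani_adequacy(trees_by_genus: dict[str, dict[str, Tree]],
                 scmg_by_genus: dict[str, Tree],
                 concavity_k: float = 1.0
                 ) -> tuple[pd.DataFrame, dict[str, tuple[float, float]],
                            float]:
    """JRF of every tree source (ANI dendrogram, 16S, regions) to the
    marker-gene reference, per genus, plus paired Wilcoxon tests of the ANI
    column against every other column across genera.

    Returns ``(table, {column: (W, p)}, mean ANI-column JRF)``.
    """
    rows = {}
    for genus, sources in trees_by_genus.items():
        if genus not in scmg_by_genus:
            raise InvalidArgument(f"no marker tree for genus {genus!r}")
        ref = scmg_by_genus[genus]
        rows[genus] = {
            label: np.nan if (j := _restricted_jrf(t, ref, concavity_k))
            is None else j
            for label, t in sources.items()}
    table = pd.DataFrame.from_dict(rows, orient="index")
    if "ANI" not in table.columns:
        raise InvalidArgument("tree sources must include an 'ANI' column")
    tests: dict[str, tuple[float, float]] = {}
    for col in table.columns:
        if col == "ANI":
            continue
        paired = table[["ANI", col]].dropna()
        if len(paired) < 2:
            raise DataError(
                f"Wilcoxon needs >= 2 paired genera for column {col!r}")
        tests[col] = wilcoxon_signed_rank(paired["ANI"].to_numpy(),
                                          paired[col].to_numpy())
    return table, tests, float(table["ANI"].mean())


# ---------------------------------------------------------------------------
# dereplicated subsampling


@dataclass
class SubsampleResult:
    genus: str
    full_set_jrf: float
    replicate_jrf: list[float] = field(default_factory=list)
    n_ani_groups: int = 0

    @property
    def mean_replicate_jrf(self) -> float:
        return float(np.mean(self.replicate_jrf))


def dereplicate_benchmark(ssu_alignment: Alignment, ani_matrix,
                          groups: ANIGroups, repeats: int = 10,
                          seed: int = 0, genus: str = "genus",
                          concavity_k: float = 1.0) -> SubsampleResult:
    """Strain-dereplication experiment: per repeat, keep one random genome
    per ANI group, rebuild the full-length 16S tree and the ANI dendrogram
    on the subset, and record their JRF distance alongside the full-set
    value."""
    if repeats < 1:
        raise InvalidArgument("repeats must be >= 1")
    full_tree = _tree_from_alignment(ssu_alignment)
    full_dendro = upgma(ani_matrix)
    full = _restricted_jrf(full_tree, full_dendro, concavity_k)
    if full is None:
        raise DataError("fewer than 4 genomes shared between 16S alignment "
                        "and ANI matrix")
    rng = np.random.default_rng(seed)
    members = groups.members()
    reps: list[float] = []
    for _ in range(repeats):
        chosen = sorted(members[g][int(rng.integers(0, len(members[g])))]
                        for g in sorted(members))
        sub_aln = ssu_alignment.select(chosen)
        sub_dm = ani_matrix.filter(chosen)
        jrf = _restricted_jrf(_tree_from_alignment(sub_aln), upgma(sub_dm),
                              concavity_k)
        if jrf is None:
            raise DataError("subsample smaller than 4 genomes; reduce "
                            "grouping threshold or increase genus size")
        reps.append(jrf)
    return SubsampleResult(genus, full, reps, groups.n_groups)


# ---------------------------------------------------------------------------
# statistics


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]
                         ) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test, two-sided.

    Zero differences are dropped; ties get midranks.  For n <= 12 the p
    value is exact (enumeration over all sign assignments); beyond that a
    normal approximation with tie correction is used.  Returns
    ``(W, p)`` with W the smaller of the two signed-rank sums.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidArgument("paired vectors differ in length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        log.warning("wilcoxon_signed_rank: all differences zero; p = 1")
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= 12:
        # exact: every sign assignment is equally likely under H0
        masks = np.arange(2 ** n)[:, None] >> np.arange(n) & 1
        dist = masks @ ranks
        p = 2.0 * min((dist <= w_plus).mean(), (dist >= w_plus).mean())
        return w, float(min(p, 1.0))
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mean) / math.sqrt(var)
    from scipy.stats import norm
    p = 2.0 * norm.sf(abs(z))
    return w, float(min(p, 1.0))


def _partition_labels(p) -> np.ndarray:
    if isinstance(p, dict):
        return np.array([p[k] for k in sorted(p)])
    return np.asarray(list(p))


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    probs = counts / counts.sum()
    return float(-(probs * np.log2(probs)).sum())


def homogeneity_completeness(predicted, truth) -> tuple[float, float]:
    """Conditional-entropy clustering scores.

    h = 1 - H(truth | predicted) / H(truth): every predicted cluster pure.
    c = 1 - H(predicted | truth) / H(predicted): every class kept whole.
    A zero-entropy denominator yields a score of 1 by convention.  When both
    arguments are dicts they are aligned on sorted keys.
    """
    pred = _partition_labels(predicted)
    true = _partition_labels(truth)
    if pred.shape != true.shape:
        raise InvalidArgument("partitions cover different element counts")
    n = len(pred)
    if n == 0:
        raise InvalidArgument("empty partitions")

    def cond_entropy(a: np.ndarray, given: np.ndarray) -> float:
        total = 0.0
        for g in np.unique(given):
            mask = given == g
            total += mask.mean() * _entropy(a[mask])
        return total

    h_true, h_pred = _entropy(true), _entropy(pred)
    h = 1.0 if h_true == 0 else 1.0 - cond_entropy(true, pred) / h_true
    c = 1.0 if h_pred == 0 else 1.0 - cond_entropy(pred, true) / h_pred
    return float(h), float(c)


def heatmap_clusters(z: pd.DataFrame, k: int = 4) -> dict[str, int]:
    """Average-linkage hierarchical clustering of genera on their z-score
    rows (Euclidean), cut to k clusters."""
    if k < 1 or k > len(z):
        raise InvalidArgument(f"k={k} outside 1..{len(z)}")
    filled = z.fillna(0.0)
    if len(z) == 1:
        return {z.index[0]: 0}
    Z = linkage(pdist(filled.to_numpy()), method="average")
    flat = fcluster(Z, t=k, criterion="maxclust")
    return {genus: int(c - 1) for genus, c in zip(z.index, flat)}


def correlate(jrf_values: Sequence[float], n_groups: Sequence[float],
              method: str = "pearson") -> tuple[float, float]:
    """Correlation between per-genus distances and ANI-group counts, with a
    two-sided p value."""
    x = np.asarray(jrf_values, dtype=float)
    y = np.asarray(n_groups, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InvalidArgument("need >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidArgument("correlation undefined for a constant vector")
    if method == "pearson":
        r, p = pearsonr(x, y)
    elif method == "spearman":
        r, p = spearmanr(x, y)
    else:
        raise InvalidArgument(f"unknown method {method!r}")
    return float(r), float(p)
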