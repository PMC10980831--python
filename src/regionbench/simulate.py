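"""Synthetic bacterial genus generator with known ground truth.

Everything downstream — primer extraction, entropy profiling, ANI grouping,
tree building, region ranking — is exercised against genera produced here,
where the true phylogeny, the planted most-variable region, and the species
partition are known by construction.

The model, briefly:

* A pure-birth (Yule) species tree, rescaled so the mean root-to-tip path
  equals ``tree_depth_target`` substitutions/site.  Speciation times are
  then respaced with two floors — a minimum internal-node separation and a
  minimum terminal-branch fraction — so that no two species are nearly
  identical (which would make 95%-ANI species grouping ill-posed) while the
  tree stays ultrametric.
* Strains grafted under each species tip as shallow Yule subtrees whose
  depth is 0.2x the shortest interspecies branch, giving clean >95%
  within-species / <95% between-species ANI separation.
* A 16S gene evolved along that tree under Jukes-Cantor with per-site rate
  multipliers: conserved primer-binding sites (rate 0) at fixed positions,
  labeled variable windows between them (configurable multipliers; the
  label with the strictly largest multiplier is the planted best region),
  background rate 1 elsewhere.  The primer sites are concrete realizations
  of the default degenerate panel, so in-silico PCR recovers all six
  amplicons from every simulated genome.
* Neutral (rate-1) marker genes and a neutral genome backbone evolved along
  the same tree; pairwise genome ANI therefore decays with patristic
  distance.

No indels by default, so all simulated gene sets are born aligned; an
optional indel mode (geometric lengths) exists to exercise the aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidArgument
from .msa import Alignment
from .records import SequenceRecord
from .tree import Tree, TreeNode

__all__ = ["SimConfig", "SyntheticGenus", "GenomeRecord", "simulate_tree",
           "evolve_alignment", "simulate_genus", "write_genus",
           "DEFAULT_REGION_MAP", "SSU_PRIMER_SITES", "ssu_site_rates"]


# ---------------------------------------------------------------------------
# 16S gene architecture
#
# Concrete primer-binding sites (one valid realization of each degenerate
# primer in the default panel) pasted at fixed positions on the root gene and
# held invariant (rate 0), mimicking the strongly conserved stems flanking
# real variable loops.  Positions are chosen so that every one of the six
# amplicons contains at least one labeled window that no *earlier* amplicon
# shares, which keeps "which region is most informative?" a well-posed
# question on synthetic data.

#: (start, plus-strand site sequence); reverse-primer sites are stored as
#: the reverse complement, i.e. as they appear on the plus strand.
SSU_PRIMER_SITES: tuple[tuple[int, str], ...] = (
    (8, "AGAGTTTGATCCTGGCTCAG"),     # 27F
    (240, "CCAGCAGCCGCGGTAAT"),      # 534R site
    (360, "CCTACGGGAGGCAGCAG"),      # 341F
    (560, "GGATTAGATACCCCAGTAGTC"),  # 805R site
    (600, "GTGTCAGCCGCCGCGGTAA"),    # 515F
    (800, "ATTAGAAACCCCCGTAGTCC"),   # 806R site
    (950, "AAACTCAAATGAATTGACGG"),   # 926F / 926R shared site
    (1300, "GTACACACCGCCCGT"),       # 1392R site
    (1450, "AAGTCGTAACAAGGTAACCGTA"),  # 1492R site
)

#: Fixed bases that block spurious cross-annealing (515F can otherwise
#: anneal on the 534R site, and 805R on the 806R site); kept invariant like
#: the primer sites themselves.
SSU_GUARDS: tuple[tuple[int, str], ...] = ((237, "CAC"), (798, "TT"))

#: Conserved stems: invariant (rate-0) segments standing in for the paired
#: helices that make most of a real rRNA gene strongly conserved.  They
#: dilute every amplicon with invariant columns (keeping pooled divergence
#: well below saturation even over a hot window) and keep the spans private
#: to the longer amplicon of each nested pair (V4/V4-V5, V6-V8/V6-V9) free
#: of background signal, so that pair differs only in its labeled windows.
SSU_STEMS: tuple[tuple[int, int], ...] = (
    (30, 60), (180, 237), (500, 556), (742, 797), (820, 822), (942, 950),
    (1093, 1297), (1315, 1318), (1438, 1450),
)

#: Labeled variable windows (label, start, end), disjoint, 120 bp each,
#: lying in the interior of the namesake amplicon; each amplicon holds
#: exactly one window that no *earlier* amplicon shares.
DEFAULT_REGION_MAP: tuple[tuple[str, int, int], ...] = (
    ("V1-V3", 60, 180),
    ("V3-V4", 380, 500),
    ("V4", 622, 742),
    ("V4-V5", 822, 942),
    ("V6-V8", 973, 1093),
    ("V6-V9", 1318, 1438),
)

_MIN_GENE_LENGTH = max(start + len(site) for start, site in SSU_PRIMER_SITES)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


def default_region_rates(hot: Optional[str] = None, hot_rate: float = 5.0,
                         cold_rate: float = 0.0,
                         base_rate: float = 3.0) -> dict[str, float]:
    """Region multipliers.

    Without ``hot``: every variable window at ``base_rate`` — a generic
    genus whose variable regions are uniformly more variable than the
    scaffold.  With ``hot``: a genus with a taxon-specific mutational hot
    spot — the planted window runs at ``hot_rate`` while the other windows
    are conserved in this taxon (``cold_rate``, 0 by default, mirroring how
    strongly hot spots differ between taxa)."""
    labels = [lab for lab, _, _ in DEFAULT_REGION_MAP]
    if hot is None:
        return {lab: base_rate for lab in labels}
    if hot not in labels:
        raise InvalidArgument(f"unknown region {hot!r}")
    return {lab: (hot_rate if lab == hot else cold_rate) for lab in labels}


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    """Parameters of one synthetic genus.

    Rates are multipliers on the per-site substitution rate; 1.0 is the
    unlabeled background, 0 makes a site invariant.  ``tree_depth_target``
    is the expected root-to-tip path in substitutions/site.
    """

    n_species: int = 10
    strains_per_species: int = 3
    birth_rate: float = 1.0
    tree_depth_target: float = 0.14
    gene_length: int = 1550
    region_map: tuple[tuple[str, int, int], ...] = DEFAULT_REGION_MAP
    region_rate: dict[str, float] = field(default_factory=default_region_rates)
    genome_length: int = 12000
    n_marker_genes: int = 5
    marker_length: int = 400
    seed: int = 0
    # tree shape controls (fractions of the root-to-tip depth)
    min_internal_frac: float = 0.08
    min_terminal_frac: float = 0.30
    strain_branch_frac: float = 0.2
    #: when set, compress all speciation times into the first
    #: ``radiation_span`` fraction of the depth (a rapid-radiation genus
    #: with short internal and long terminal branches)
    radiation_span: Optional[float] = None
    # optional realism knobs
    n_16s_copies: int = 1
    copy_divergence: float = 0.002
    indel_rate: float = 0.0
    indel_mean_len: float = 3.0
    model: str = "JC69"
    kappa: float = 2.0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise InvalidArgument("n_species must be >= 2")
        if self.strains_per_species < 1:
            raise InvalidArgument("strains_per_species must be >= 1")
        if self.gene_length < _MIN_GENE_LENGTH:
            raise InvalidArgument(
                f"gene_length must be >= {_MIN_GENE_LENGTH} to hold the "
                "primer architecture")
        if self.genome_length < 2040:
            raise InvalidArgument("genome_length must be >= 2040 (two ANI "
                                  "fragments)")
        spans = sorted((s, e, lab) for lab, s, e in self.region_map)
        prev_end = 0
        for s, e, lab in spans:
            if s >= e:
                raise InvalidArgument(f"region {lab!r} is empty: [{s}, {e})")
            if s < prev_end:
                raise InvalidArgument(f"region {lab!r} overlaps a previous "
                                      "region")
            if e > self.gene_length:
                raise InvalidArgument(f"region {lab!r} exceeds gene length")
            prev_end = e
        for lab, rate in self.region_rate.items():
            if rate < 0:
                raise InvalidArgument(f"negative rate for region {lab!r}")

    @property
    def planted_best_region(self) -> Optional[str]:
        """Label with the strictly largest multiplier, None on a tie."""
        if not self.region_rate:
            return None
        ordered = [lab for lab, _, _ in self.region_map
                   if lab in self.region_rate]
        best = max(self.region_rate.values())
        winners = [lab for lab in ordered
                   if self.region_rate[lab] == best]
        return winners[0] if len(winners) == 1 else None


@dataclass
class GenomeRecord:
    genome_id: str
    genome: SequenceRecord
    ssu: list[SequenceRecord]
    markers: list[SequenceRecord]


@dataclass
class SyntheticGenus:
    config: SimConfig
    true_tree: Tree
    genomes: list[GenomeRecord]
    planted_best_region: Optional[str]
    true_species_partition: dict[str, int]
    ssu_alignment: Alignment
    marker_alignments: list[Alignment]

    def genome_records(self) -> list[SequenceRecord]:
        return [g.genome for g in self.genomes]

    def ssu_records(self) -> list[SequenceRecord]:
        return [rec for g in self.genomes for rec in g.ssu]


# ---------------------------------------------------------------------------
# tree simulation


def simulate_tree(n_taxa: int, birth_rate: float, depth_target: float,
                  seed: int) -> Tree:
    """Pure-birth tree with leaf labels T1..Tn, rescaled so the (ultrametric)
    root-to-tip path equals ``depth_target``."""
    if n_taxa < 2:
        raise InvalidArgument("simulate_tree needs n_taxa >= 2")
    if birth_rate <= 0 or depth_target <= 0:
        raise InvalidArgument("birth_rate and depth_target must be > 0")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    active: list[tuple[TreeNode, float]] = []  # (node, birth time)
    for _ in range(2):
        child = TreeNode()
        root.children.append(child)
        active.append((child, 0.0))
    t = 0.0
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        idx = int(rng.integers(0, k))
        node, birth = active.pop(idx)
        node.length = t - birth
        for _ in range(2):
            child = TreeNode()
            node.children.append(child)
            active.append((child, t))
    t_end = t + rng.exponential(1.0 / (birth_rate * n_taxa))
    scale = depth_target / t_end if t_end > 0 else 1.0
    for i, (node, birth) in enumerate(active):
        node.name = f"T{i + 1}"
        node.length = t_end - birth
    for node in root.postorder():
        if node.length is not None:
            node.length *= scale
    return Tree(root, rooted=True)


def _apply_time_floors(tree: Tree, depth: float, min_internal_frac: float,
                       min_terminal_frac: float) -> Tree:
    """Respace speciation times on an ultrametric tree: successive internal
    nodes at least ``min_internal_frac`` of the depth apart, and every
    terminal branch at least ``min_terminal_frac`` of the depth.  Keeps the
    tree ultrametric with tips at ``depth``."""
    tree = tree.copy()
    cap = 1.0 - min_terminal_frac
    times: dict[int, float] = {}

    def push(node: TreeNode, t_parent: float) -> None:
        t = t_parent + (node.length or 0.0) / depth
        if node.length is not None:
            t = max(t, t_parent + min_internal_frac)
        times[id(node)] = t
        for c in node.children:
            push(c, t)

    times[id(tree.root)] = 0.0
    for c in tree.root.children:
        if not c.is_leaf:
            push(c, 0.0)
    internal_times = [times[id(n)] for n in tree.root.postorder()
                      if not n.is_leaf]
    t_max = max(internal_times, default=0.0)
    # squeeze proportionally if the floors (or the original times) push the
    # deepest split past the terminal-branch reservation; this shrinks every
    # floor by the same bounded factor instead of collapsing the deepest
    # branches to zero
    scale = cap / t_max if t_max > cap else 1.0

    def apply(node: TreeNode, t_parent: float) -> None:
        if node.is_leaf:
            node.length = (1.0 - t_parent) * depth
            return
        t = times.get(id(node), 0.0) * scale
        if node.length is not None:
            node.length = (t - t_parent) * depth
        for c in node.children:
            apply(c, t)

    apply(tree.root, 0.0)
    return tree


def _compress_radiation(tree: Tree, depth: float, span: float) -> Tree:
    """Rescale speciation times so the deepest internal node sits at
    ``span`` (fraction of the depth): a rapid-radiation genus.  Tips stay
    at the full depth; the tree stays ultrametric."""
    tree = tree.copy()
    times: dict[int, float] = {}

    def collect(node: TreeNode, t_parent: float) -> None:
        t = t_parent + (node.length or 0.0) / depth
        times[id(node)] = t
        for c in node.children:
            collect(c, t)

    collect(tree.root, 0.0)
    internal_times = [times[id(n)] for n in tree.root.postorder()
                      if not n.is_leaf and id(n) != id(tree.root)]
    t_max = max(internal_times, default=0.0)
    if t_max <= span or t_max == 0.0:
        return tree
    factor = span / t_max

    def rescale(node: TreeNode, t_parent: float) -> None:
        if node.is_leaf:
            node.length = (1.0 - t_parent) * depth
            return
        t = times[id(node)] * factor
        if node.length is not None:
            node.length = (t - t_parent) * depth
        for c in node.children:
            rescale(c, t)

    rescale(tree.root, 0.0)
    return tree


def _min_branch_length(tree: Tree) -> float:
    lengths = [n.length for n in tree.root.postorder()
               if n.length is not None and n.length > 0]
    return min(lengths) if lengths else 0.0


# ---------------------------------------------------------------------------
# sequence evolution


def _mutate(parent: np.ndarray, dist: np.ndarray, model: str, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    """One branch of site-independent evolution; ``dist`` is the per-site
    expected substitution count (branch length x site multiplier)."""
    child = parent.copy()
    if model == "JC69":
        p = 0.75 * (1.0 - np.exp(-4.0 * dist / 3.0))
        hit = rng.random(parent.size) < p
        shift = rng.integers(1, 4, size=parent.size)
        child[hit] = (parent[hit] + shift[hit]) % 4
    elif model == "K80":
        beta = 1.0 / (kappa + 2.0)
        alpha = kappa * beta
        e1 = np.exp(-4.0 * beta * dist)
        e2 = np.exp(-2.0 * (alpha + beta) * dist)
        p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
        p_tv = 0.25 - 0.25 * e1          # each of the two transversions
        u = rng.random(parent.size)
        ts = u < p_ts
        tv1 = (~ts) & (u < p_ts + p_tv)
        tv2 = (~ts) & (~tv1) & (u < p_ts + 2 * p_tv)
        child[ts] = parent[ts] ^ 2
        child[tv1] = parent[tv1] ^ 1
        child[tv2] = parent[tv2] ^ 3
    else:
        raise InvalidArgument(f"unknown model {model!r}")
    return child


def evolve_alignment(tree: Tree, length: int, site_rates: Sequence[float],
                     model: str = "JC69", seed: int = 0,
                     kappa: float = 2.0,
                     root_seq: Optional[str] = None) -> Alignment:
    """Evolve one ungapped sequence per leaf along ``tree``.

    ``site_rates`` multiplies each branch length per site; a multiplier of 0
    makes the site invariant.  The root sequence is uniform over {A,C,G,T}
    unless provided.
    """
    rates = np.asarray(site_rates, dtype=float)
    if rates.shape != (length,):
        raise InvalidArgument(
            f"site_rates must have length {length}, got {rates.shape}")
    if (rates < 0).any():
        raise InvalidArgument("site_rates must be nonnegative")
    rng = np.random.default_rng(seed)
    if root_seq is None:
        root = rng.integers(0, 4, size=length)
    else:
        if len(root_seq) != length:
            raise InvalidArgument("root_seq length mismatch")
        root = np.array([_BASE_IDX[c] for c in root_seq.upper()])

    labels: list[str] = []
    rows: list[str] = []

    def decode(arr: np.ndarray) -> str:
        return _BASES[arr].tobytes().decode("ascii")

    def walk(node: TreeNode, seq: np.ndarray) -> None:
        if node.length:
            seq = _mutate(seq, node.length * rates, model, kappa, rng)
        if node.is_leaf:
            labels.append(node.name)
            rows.append(decode(seq))
            return
        for c in node.children:
            walk(c, seq)

    walk(tree.root, root)
    return Alignment(labels, rows)


# ---------------------------------------------------------------------------
# genus assembly


def ssu_site_rates(cfg: SimConfig) -> np.ndarray:
    rates = np.ones(cfg.gene_length)
    for lab, s, e in cfg.region_map:
        rates[s:e] = cfg.region_rate.get(lab, 1.0)
    for start, site in SSU_PRIMER_SITES:
        rates[start:start + len(site)] = 0.0
    for start, bases in SSU_GUARDS:
        rates[start:start + len(bases)] = 0.0
    if cfg.region_map == DEFAULT_REGION_MAP:
        for s, e in SSU_STEMS:
            rates[s:e] = 0.0
    return rates


def _build_ssu_root(cfg: SimConfig, rng: np.random.Generator) -> str:
    seq = rng.integers(0, 4, size=cfg.gene_length)
    chars = list(_BASES[seq].tobytes().decode("ascii"))
    for start, site in SSU_PRIMER_SITES:
        chars[start:start + len(site)] = site
    for start, bases in SSU_GUARDS:
        chars[start:start + len(bases)] = bases
    return "".join(chars)


def _apply_indels(seq: str, rate: float, mean_len: float,
                  rng: np.random.Generator) -> str:
    """Geometric-length indels at a per-site rate (insertion or deletion
    with equal probability)."""
    out: list[str] = []
    i = 0
    p_geom = min(1.0, 1.0 / mean_len)
    while i < len(seq):
        if rng.random() < rate:
            size = int(rng.geometric(p_geom))
            if rng.random() < 0.5:
                i += size                      # deletion
                continue
            ins = rng.integers(0, 4, size=size)
            out.append(_BASES[ins].tobytes().decode("ascii"))
        out.append(seq[i])
        i += 1
    return "".join(out)


def simulate_genus(cfg: SimConfig) -> SyntheticGenus:
    """Build one synthetic genus: tree, 16S genes, markers, genomes."""
    ss = np.random.SeedSequence(cfg.seed)
    (seed_tree, seed_strains, seed_root, seed_ssu, seed_markers,
     seed_genome, seed_copies, seed_indel) = ss.spawn(8)

    species_tree = simulate_tree(cfg.n_species, cfg.birth_rate,
                                 cfg.tree_depth_target, _small(seed_tree))
    if cfg.radiation_span is not None:
        species_tree = _compress_radiation(species_tree,
                                           cfg.tree_depth_target,
                                           cfg.radiation_span)
    species_tree = _apply_time_floors(species_tree, cfg.tree_depth_target,
                                      cfg.min_internal_frac,
                                      cfg.min_terminal_frac)

    # graft strains under each species tip
    partition: dict[str, int] = {}
    min_branch = _min_branch_length(species_tree)
    strain_depth = cfg.strain_branch_frac * min_branch
    strain_rng = np.random.default_rng(_small(seed_strains))
    for leaf in species_tree.leaves():
        sp = int(leaf.name[1:]) - 1          # T1.. -> 0-based species index
        gids = [f"G{sp:02d}_{t:02d}" for t in range(cfg.strains_per_species)]
        for g in gids:
            partition[g] = sp
        if cfg.strains_per_species == 1:
            leaf.name = gids[0]
            continue
        sub = simulate_tree(cfg.strains_per_species, cfg.birth_rate,
                            strain_depth,
                            int(strain_rng.integers(0, 2 ** 31)))
        for i, tip in enumerate(sub.leaves()):
            tip.name = gids[i]
        leaf.name = None
        # shorten the species branch by the subtree depth so all strain
        # tips still sit at the genus depth (the tree stays ultrametric)
        leaf.length = max(leaf.length - strain_depth, 1e-9)
        leaf.children = list(sub.root.children)
    true_tree = Tree(species_tree.root, rooted=True)

    # 16S
    rates = ssu_site_rates(cfg)
    root_rng = np.random.default_rng(_small(seed_root))
    ssu_root = _build_ssu_root(cfg, root_rng)
    ssu_aln = evolve_alignment(true_tree, cfg.gene_length, rates,
                               model=cfg.model, seed=_small(seed_ssu),
                               kappa=cfg.kappa, root_seq=ssu_root)

    # markers (born aligned, no indels)
    marker_alns: list[Alignment] = []
    marker_rng = np.random.default_rng(_small(seed_markers))
    for _ in range(cfg.n_marker_genes):
        marker_alns.append(
            evolve_alignment(true_tree, cfg.marker_length,
                             np.ones(cfg.marker_length), model=cfg.model,
                             seed=int(marker_rng.integers(0, 2 ** 31)),
                             kappa=cfg.kappa))

    # neutral genome backbone
    genome_aln = evolve_alignment(true_tree, cfg.genome_length,
                                  np.ones(cfg.genome_length),
                                  model=cfg.model, seed=_small(seed_genome),
                                  kappa=cfg.kappa)

    copies_rng = np.random.default_rng(_small(seed_copies))
    indel_rng = np.random.default_rng(_small(seed_indel))
    genome_index = {l: i for i, l in enumerate(genome_aln.labels)}
    ssu_index = {l: i for i, l in enumerate(ssu_aln.labels)}
    genomes: list[GenomeRecord] = []
    for gid in sorted(partition):
        gseq = genome_aln.rows[genome_index[gid]]
        base_ssu = ssu_aln.rows[ssu_index[gid]]
        if cfg.n_16s_copies == 1:
            ssu_records = [SequenceRecord(gid, base_ssu, gid)]
        else:
            ssu_records = []
            enc = np.array([_BASE_IDX[c] for c in base_ssu])
            for c in range(cfg.n_16s_copies):
                copy = enc if c == 0 else _mutate(
                    enc, cfg.copy_divergence * rates, cfg.model, cfg.kappa,
                    copies_rng)
                ssu_records.append(SequenceRecord(
                    f"{gid}_rrn{chr(ord('A') + c)}",
                    _BASES[copy].tobytes().decode("ascii"), gid))
        if cfg.indel_rate > 0:
            ssu_records = [
                SequenceRecord(r.id,
                               _apply_indels(r.seq, cfg.indel_rate,
                                             cfg.indel_mean_len, indel_rng),
                               r.genome_id)
                for r in ssu_records]
        markers = [SequenceRecord(f"{gid}|marker{m:02d}",
                                  aln.rows[aln.labels.index(gid)], gid)
                   for m, aln in enumerate(marker_alns)]
        genomes.append(GenomeRecord(gid, SequenceRecord(gid, gseq, gid),
                                    ssu_records, markers))

    return SyntheticGenus(cfg, true_tree, genomes,
                          cfg.planted_best_region, partition,
                          ssu_aln, marker_alns)


def _small(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# on-disk layout


def write_genus(genus: SyntheticGenus, outdir: str | Path) -> None:
    """Write genomes.fasta, ssu.fasta, markers/*.aln.fasta, truth.nwk and
    truth.tsv under ``outdir``."""
    from .io import write_fasta, write_newick

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(genus.genome_records(), outdir / "genomes.fasta")
    write_fasta(genus.ssu_records(), outdir / "ssu.fasta")
    marker_dir = outdir / "markers"
    marker_dir.mkdir(exist_ok=True)
    for m, aln in enumerate(genus.marker_alignments):
        write_fasta([SequenceRecord(l, r) for l, r in
                     zip(aln.labels, aln.rows)],
                    marker_dir / f"marker{m:02d}.aln.fasta")
    write_newick(genus.true_tree, outdir / "truth.nwk")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("genome_id\tspecies\tplanted_best_region\n")
        planted = genus.planted_best_region or "NA"
        for gid, sp in sorted(genus.true_species_partition.items()):
            fh.write(f"{gid}\t{sp}\t{planted}\n")
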