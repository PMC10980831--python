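# Methods

This note documents the models, conventions and numerical choices behind
`regionbench`, in enough detail to reimplement every result bit for bit.

## Problem setting

Given a genus — a set of genomes, each with at least one full-length 16S
rRNA gene — the package asks which primer-defined variable region of the
gene best reproduces whole-genome relationships.  The whole-genome
reference is an average-nucleotide-identity (ANI) dendrogram; region
quality is the generalized Jaccard–Robinson–Foulds (JRF) distance between
the region's phylogeny and that dendrogram.  Everything else (entropy
profiling, ANI grouping, dereplicated subsampling, k-mer PCA) supports or
contextualizes that ranking.

## Tree comparison

Splits are encoded as bitmasks over the sorted leaf set; the canonical
side is the side not containing the first taxon; trivial splits (a side
with fewer than two leaves) are discarded, and rooted dendrograms are
unrooted before extraction so all trees share one split universe.

*JRF.*  The pair score of splits A|B and C|D is the orientation-maximized
minimum side-wise Jaccard index, raised to a concavity exponent k
(default 1):

    s = max( min(J(A,C), J(B,D)), min(J(A,D), J(B,C)) )^k

An optimal one-to-one partial matching between the two split sets
maximizes the summed score — solved exactly as a rectangular assignment
problem (scipy); because scores are nonnegative, a maximum full matching
of the smaller side is also the best partial matching.  The normalized
distance is `(|S1|+|S2| − 2·Σs) / (|S1|+|S2|)`.  Conventions: two
split-free (star) trees are at distance 0; star versus resolved is 1.  As
k → ∞ the score tends to the indicator of split equality and JRF tends to
RF/(|S1|+|S2|); the test suite checks this at k = 64.

*MCI.*  Same matching machinery with the pair score replaced by the mutual
information (bits) between the splits viewed as binary leaf labelings;
reported as total matched bits and as `1 − MCI / max(ΣH(S1), ΣH(S2))`
with H the binary split entropy.

An exhaustive-enumeration matcher (`brute_force_match`, ≤8 splits a side)
serves as the independent oracle; the test suite proves agreement on the
complete 6-leaf topology enumeration (105² ordered pairs) and on random
8-leaf pairs to 1e-9.

## Tree building

Distance trees only: the comparison layer is agnostic to the builder, and
distance methods are fully specifiable (an external-newick import path
lets users substitute ML trees).

*JC distances.*  p-distance over columns where both rows carry a plain
base (gaps and N excluded pairwise), corrected as d = −¾·ln(1 − 4p/3);
p ≥ 0.75 is capped at d = 5.0 with a warning; a pair with no comparable
columns is an error naming the pair.

*Neighbor joining.*  Canonical Q-criterion with Studier–Keppler updates.
Ties on Q resolve to the lexicographically smallest label pair.  Negative
branch estimates are clamped to zero with the deficit transferred to the
sibling branch, preserving the pair's summed length.  On additive
matrices NJ recovers topology and branch lengths exactly (tested to
1e-9 on random 8-leaf trees).

*UPGMA.*  Size-weighted average linkage with the same tie-break; output is
ultrametric by construction and reproduces any ultrametric input's
cophenetic matrix exactly.

*Bootstrap.*  Alignment trees: column resampling; ANI dendrograms: each
pair's per-fragment identity list is resampled and the matrix rebuilt.
Support = percentage of replicates containing the node's bipartition
(cluster, for rooted trees), annotated onto the point-estimate tree.

*Marker-gene (SCMG) tree.*  Column-wise concatenation of per-marker
alignments, gap-filling genomes missing from a marker (an error if two
markers share no genomes), then NJ with column bootstrap.

## ANI

Fragment mapping in the OrthoANI style: the query is cut into
non-overlapping 1020-bp windows; each window is located on the subject by
shared 16-mers on both strands (a sparse seed pass at stride 48, with a
dense stride-4 fallback for divergent pairs; offsets are bucketed to
absorb drift) and aligned with edlib in semi-global mode against a
candidate window padded by 0.1·fragment — the padding plays the role of a
DP band, and the edit distance is capped at 30% of the fragment length,
the bound implied by the 70% identity acceptance rule.  Fragments at
≥70% identity count as aligned; ANI is the mean identity over aligned
fragments, symmetrized as the mean of the two directions.  A pair with no
aligned fragment has undefined ANI and is assigned distance 1.0 (with a
warning) so matrices stay complete.  Grouping at a threshold T (default
95%) is single-linkage: connected components of the graph with edges
where ANI ≥ T.

Calibration: against genomes with i.i.d. 5% substitutions the estimator
tracks the realized identity to <0.1 (edit distance equals substitution
count on indel-free data), so the measured value is 95.0 up to the
binomial fluctuation of the mutation draw itself.

## Alignment and entropy

Progressive MSA: UPGMA guide tree on 6-mer cosine distances, then
profile–profile Needleman–Wunsch with column-average scoring
(match 1, mismatch −1, gap −4, gap–gap 0) and once-a-gap-always-a-gap
semantics.  The stiff gap penalty makes the gap-free alignment the strict
optimum on indel-free homologous input (at −2, off-frame coincidences in
profile-average scores can pay for staggered gaps).  Traceback prefers
diagonal > up > left, so output is deterministic.  The DP fills rows with
a running-maximum trick (linear gap ⇒ H[i,j] = max_k M[i,k] − g(j−k)),
avoiding an inner Python loop.

Entropy is Shannon entropy in bits per column.  Default gap handling
excludes gaps and N from the frequency vector (both are treated as
missing data, not states); `fifth-state` keeps the gap as a symbol.
All-gap columns get entropy 0 and are flagged.  Smoothing is a plain
10-column moving mean reported alongside raw values.  Region annotations
are taken on alignment coordinates; in the pipeline they come from the
extraction coordinates of the alphabetically first genome.

## In-silico PCR

IUPAC-compatibility matching with ≤2 mismatches by default and a
mandatory exact match in the primer's 3′-terminal 5 bases (polymerase
extension requirement); for minus-strand primers that window is the
*start* of the plus-strand footprint.  Extraction uses the leftmost
forward footprint and the rightmost reverse footprint to its right; the
reported region is the amplicon interior (primers excluded — primer-site
bases are constrained and would depress entropy), accepted at 50–1200 bp.
Multi-copy genomes contribute their longest 16S copy (ties: smallest
sequence id).  Coordinates are 0-based half-open internally, 1-based
inclusive in human-facing tables.

The default panel is the standard set for the six windows (27F/534R,
341F/805R, 515F/806R, 515F/926R, 926F/1392R, 926F/1492R), fully
replaceable via TSV.

## Synthetic genus generator

The generator is the package's ground-truth source; its defaults define
the study conditions used by the tests and the reproduction script.

*Species tree.*  Pure birth, rescaled to a root-to-tip depth of
`tree_depth_target` (default 0.14 substitutions/site — deep enough that
between-species ANI falls clearly below 95%).  Speciation times are then
respaced: successive internal nodes at least `min_internal_frac` (0.08)
of the depth apart and terminal branches at least `min_terminal_frac`
(0.30); if the floors push the deepest split past the terminal
reservation, all speciation times are squeezed proportionally rather than
clamped (clamping would collapse the deepest branches to zero).  An
optional `radiation_span` compresses all splits into the first fraction
of the depth — a rapid-radiation genus.  Trees stay ultrametric
throughout, matching the clock-like premise of ANI dendrograms.

*Strains.*  Each species tip is replaced by a shallow pure-birth subtree
whose depth is 0.2× the shortest interspecies branch, and the species
branch is shortened correspondingly.  With the defaults this puts
within-species ANI near 99% and between-species ANI at or below ~93%, so
95% single-linkage grouping recovers the species partition.

*16S gene.*  1550 bp with a fixed architecture: concrete realizations of
the default panel's primer sites pasted at fixed positions and held
invariant (rate 0), invariant "stem" segments standing in for the paired
helices that make most of a real rRNA conserved, and six disjoint 120-bp
variable windows, one per amplicon label.  Guard bases at two positions
block cross-annealing artifacts (515F on the 534R site, 805R on the 806R
site) that an exhaustive primer-vs-architecture scan identified; 806R
also anneals weakly on the 805R site, which is harmless under the
rightmost-reverse rule (the same overlap exists in real 16S).  The stems
also keep the pooled divergence of every amplicon below JC saturation
even over a 5× window, and make the two nested amplicon pairs
(V4 ⊂ V4–V5, V6–V8 ⊂ V6–V9) differ only in invariant columns plus their
own labeled window — without this, the longer amplicon of a nested pair
would dominate its sibling purely by diluting the same substitutions over
more columns (lower p, less JC variance inflation), not by carrying more
information.  Per-site rates: background 1.0, windows per `region_rate`
(default 3.0 — variable regions uniformly hotter than the backbone), 0 on
sites/stems/guards.  The planted best region is the label with the
strictly largest multiplier (none, on ties).  Sequence evolution is
site-independent JC69 (K80 with configurable κ available), root drawn
uniformly per site.

*Markers and genome.*  `n_marker_genes` (5) × 400 bp neutral marker genes
born aligned, and a 12,000-bp neutral genome backbone, all on the same
tree — so genome ANI decays monotonically with patristic distance.  No
indels by default (genes are born aligned); an optional indel mode
(per-site rate, geometric lengths) exercises the aligner.  Identical
configuration and seed give byte-identical output; all stage seeds derive
from one `SeedSequence`.

What the generator does **not** emulate: rRNA secondary-structure
covariation, GC heterogeneity, horizontal transfer, rearrangements,
variable genome sizes, and amplicon-sequencing artifacts (chimeras,
primer bias).  Passing tests therefore demonstrate correctness of the
pipeline's logic under a clean substitution model, not performance on
real amplicon data.

## Canned experiments

*Planted-region recovery.*  Ten single-strain genera, each emulating a
taxon-specific mutational hot spot: one window at 5× the backbone, the
other windows conserved (rate 0) in that genus — variability concentrated
in hot spots that differ between taxa.  Geometry: 10 species, depth 0.06,
`min_internal_frac` 0.2, genome 20,400 bp (the ANI reference is then
essentially exact).  In this regime the planted amplicon carries nearly
all of the gene's phylogenetic signal, amplicons without the hot window
cannot resolve the radiation, and for a hot spot shared by a nested
amplicon pair both members produce identical trees and the documented
panel-order tie-break selects the inner (shorter) one.  The benchmark is
expected to rank the planted region best in at least 9 of 10 genera.

*Dereplicated subsampling.*  A 10-species × 10-strain genus (genome
8,160 bp to keep all-pairs ANI affordable).  Per repeat (10, seeded), one
genome per ANI group is drawn uniformly, the full-length 16S NJ tree and
ANI dendrogram are rebuilt on the subset, and their JRF recorded next to
the full-set value.  Strain-level splits are essentially unresolvable
from 16S, so the full-set distance is inflated by strain noise and
dereplication lowers it — the direction the experiment checks.

## Statistics

*Wilcoxon signed-rank* (paired, two-sided): zero differences dropped,
midranks for ties; exact p by enumeration of all 2ⁿ sign assignments for
n ≤ 12 (p = 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)), capped at 1), normal
approximation with tie correction beyond; all-zero differences give
p = 1 with a warning.  *Homogeneity/completeness*: conditional-entropy
definitions with zero-entropy denominators scoring 1.  *Heatmap
clustering*: scipy average-linkage on Euclidean distances between z-score
rows, cut to k clusters.  *Correlation*: Pearson by default ("R" is
ambiguous in common usage), Spearman behind a flag, both via scipy.
*z-scores*: row-wise, sample sd (n−1); zero-sd rows map to zeros; missing
cells are excluded from the moments and stay missing.

## Scale choices

All simulations run at desk scale: genera of 10–100 genomes, genomes of
8–20 kb, genes of 1550 bp.  These sizes were chosen so the complete test
suite and the reproduction script each finish in minutes on one CPU while
leaving every calibration margin (ANI grouping separation, planted-region
contrast, subsampling direction) wide.  The pipeline itself has no
hard-coded size assumptions beyond the ANI fragment length.

## Known limitations

- Distance-based trees only; very heterogeneous rates across lineages
  would favor ML methods (import external newicks for that).
- The ANI estimator is exact on substitution-only data but has no
  repeat/paralog masking; highly repetitive real genomes could mis-seed
  fragments.
- The progressive aligner is adequate for near-aligned input; heavily
  indel-ridden or truncated 16S sets should be aligned externally and
  imported as aligned FASTA.
- JRF/MCI are defined here with one concrete pair-score and normalization
  (documented above); other published variants of the generalized-RF
  family will give numerically different, though correlated, values.
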