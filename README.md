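# regionbench

Which window of the 16S rRNA gene should you sequence to tell the members
of a bacterial genus apart?  Amplicon studies target one of a handful of
variable regions (V1–V3, V3–V4, V4, V4–V5, V6–V8, V6–V9), and the choice
matters: sequence variability clusters in taxon-specific hot spots, so the
region that resolves one genus can be uninformative in another.

`regionbench` ranks the candidate regions for a genus by comparing, tree
against tree, how faithfully each region's phylogeny reproduces
whole-genome relationships.  It is aimed at microbial ecologists designing
genus-targeted metabarcoding assays, and at method developers who need a
fully specified, deterministic reference implementation of the underlying
machinery.

## The method

For one genus with genomes *g₁…gₙ* (each contributing a full-length 16S
gene):

1. **In-silico PCR** extracts each variable-region amplicon with a
   degenerate primer panel (IUPAC matching, ≤2 mismatches, exact
   3′-terminal 5 bases).
2. **Whole-genome reference**: pairwise ANI (fragment mapping, 1020-bp
   windows) gives a distance matrix *d = 1 − ANI/100*; UPGMA on it yields
   the reference dendrogram.  Single-linkage components at ANI ≥ 95% define
   species-like *ANI groups*.
3. **Region trees**: each amplicon alignment gives Jukes–Cantor distances
   and a neighbor-joining tree.
4. **Tree comparison** uses the generalized Jaccard–Robinson–Foulds
   distance.  For split sets *S₁, S₂* an optimal one-to-one matching
   maximizes the per-pair agreement
   *s(A|B, C|D) = [max over orientations of min(J(A,C), J(B,D))]^k*
   (Jaccard index J, concavity k = 1), and

   ```
   jrf = (|S₁| + |S₂| − 2·Σ matched s) / (|S₁| + |S₂|)   ∈ [0, 1].
   ```

   Mutual clustering information (MCI, bits) is computed the same way with
   mutual-information pair scores.
5. **Ranking**: per genus, the row of JRF distances to the ANI dendrogram
   is z-scored for display; the best region is the argmin over raw
   variable-region distances (ties resolve to the earliest region in panel
   order).  Supporting statistics: exact paired Wilcoxon signed-rank tests,
   homogeneity/completeness of clusterings, correlation of distances with
   ANI-group counts, and a strain-dereplication experiment (one random
   genome per ANI group, repeated).

A synthetic-genus generator produces the ground truth to validate all of
this without downloads: a pure-birth species tree with grafted strains, a
16S gene with conserved primer sites and configurable hot windows, neutral
marker genes, and a genome backbone whose ANI decays with tree distance.

## Worked example

Simulate a genus of 10 species whose 16S variability is concentrated in
the V1–V3 window (a taxon-specific hot spot, 5× the backbone rate), then
benchmark every region against the genome-wide reference:

```bash
cat > genus.yaml <<EOF
n_species: 10
strains_per_species: 1
tree_depth_target: 0.06
min_internal_frac: 0.2
genome_length: 20400
seed: 4
region_rate: {V1-V3: 5.0, V3-V4: 0.0, V4: 0.0, V4-V5: 0.0, V6-V8: 0.0, V6-V9: 0.0}
EOF
regionbench simulate  --config genus.yaml --out sim
regionbench extract   --ssu sim/ssu.fasta --out amplicons
regionbench benchmark --dir sim --seed 1  --out bench
```

which prints

```
wrote synthetic genus (10 genomes) to sim
extracted 60 amplicons, 0 drops
best=V1-V3 16S=0.000 V1-V3=0.107 V3-V4=0.442 V4=0.288 V4-V5=0.288 V6-V8=0.468 V6-V9=0.468
```

Reading the numbers: the full-length gene reproduces the ANI dendrogram
exactly (JRF 0.000, it sees every informative site); among the amplicons
the planted V1–V3 region is clearly best (0.107), while regions whose
windows are conserved in this genus sit at 0.29–0.47 — they simply carry
too few substitutions to resolve the radiation.  `bench/` holds the raw
and z-scored tables, the best-region call, and the dereplicated
subsampling results as TSV.

Every subcommand (`simulate`, `extract`, `entropy`, `ani`, `trees`,
`compare`, `onf`, `benchmark`) echoes its configuration to
`run_config.echo.yaml` in the output directory; identical invocations are
byte-identical.

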