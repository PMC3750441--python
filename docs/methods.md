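# Methods

## Scope and model

`organphylo` operates on panels of complete, broadly collinear organelle
genomes from one genus: a handful of strains (typically 4–9), genomes of
~40–120 kb, intragenus divergence of a few percent, conspecific divergence of
~0.1% or less. Everything downstream — alignment strategy, exhaustive tree
search, window sizes — exploits this regime and is *not* designed for deep
divergences or rearranged genomes.

## Region extraction

Genomes are linearized at position 1 of the FASTA record; a feature with
end < start on a circular genome wraps the origin. Coordinates are GFF3
1-based inclusive at every interface and 0-based half-open internally; the
conversion lives in one audited function pair (`_util.to_internal` /
`to_gff`). Orthology is by exact feature-name match — organelle locus names
are stable within a genus — so duplicated loci (inverted-repeat gene copies)
must carry distinct names (`psbV` vs `psbV_1`); no similarity clustering is
attempted. Intergenic spacers are named `<left>-<right>` from the flanking
features; pairs whose features overlap or touch yield no spacer. A feature
that wraps the origin contributes no right-hand spacer.

## Alignment and distances

Regions within a genus are near-identical, so multiple alignment is a
deterministic center-star merge: all pairwise global affine alignments are
computed (Biopython `PairwiseAligner`; defaults match +1, mismatch −1,
gap open −4, gap extend −1, a stiff scheme appropriate for ~1–5% divergent
sequences and overridable), the center is the member minimizing summed
pairwise p-distance (ties: input order), and the other members are merged on
the center coordinate with once-a-gap-always-a-gap semantics. A guide-tree
progressive scheme adds nothing at these divergences. Ties between equally
optimal pairwise alignments are resolved by the aligner's deterministic
first-optimum order; tests assert score-optimality against a brute-force
enumeration rather than one specific gap placement.

Whole genomes are aligned by anchoring on k-mers (default k = 21) unique in
both sequences, chaining anchors with a longest-increasing-subsequence pass,
and closing inter-anchor gaps with the affine aligner. Non-collinear input
(no anchors) falls back to plain global alignment below 50 kb and errors
above it.

p-distance is the proportion of differing sites over comparable sites;
`deletion_mode="pairwise"` (default, the common convention) excludes columns
gapped or ambiguous in either row of a pair, `"complete"` in any row. `N` is
always treated as missing. The sensitivity index ("% difference") defaults to
the proportion of polymorphic columns (≥2 distinct non-N characters, a
gap/base contrast counts) × 100; a mean-pairwise-p-distance variant is
available behind `mode="mean_pairwise"` since either reading is defensible
for per-region difference percentages.

SNP classification partitions variant columns exactly: columns containing a
gap are indels; biallelic base columns are transitions or transversions;
columns with ≥3 bases are tallied separately as multiallelic rather than
force-classified. With a codon frame, substitution effects are called by
mutating the first row's codon, and gap runs are `triplet_indel` when every
run length at the column is divisible by 3, else `frameshift`.

## Phylogenetics

Trees are unrooted objects identified by their internal splits; outgroup
rooting is display-only. Neighbor joining is standard Saitou–Nei with the
Q-criterion and a deterministic tie-break on the lexicographically smallest
leaf under each node; negative branch estimates are clamped to zero with the
deficit shifted to the sister edge, preserving the path length through the
new node.

Maximum parsimony enumerates all (2n−5)!! unrooted topologies for 4–9 taxa by
stepwise edge insertion and scores each with Fitch counts vectorized over
unique column patterns (gap and N are union-compatible at no cost). Because
per-pattern counts are independent of column weights, the count matrix
(topologies × patterns) is computed once; bootstrap replicates reduce to
reweighting pattern counts by a resampled column multiset and taking the
weighted argmin — 100 replicates cost little more than one search. Beyond 9
taxa an NNI hill climb from the NJ tree is used and the result is flagged
heuristic. Bootstrap supports are the percentage of replicate trees
containing each split of the tree built on the original data; B defaults to
100.

Marker **consistency** is defined exactly: the reference topology (restricted
to the strains the marker covers) must attain the minimal Fitch score among
all enumerated topologies for that marker, ties allowed. This avoids any
tie-breaking when several topologies are equally parsimonious. Invariant
regions, for which every topology ties, are never called consistent. Tree
similarity is quantified as the Euclidean distance between p-distance
matrices (square root of the sum of squared entry differences over unordered
pairs, optionally normalized by pair count); Robinson–Foulds distance on
split sets is also provided.

The reference phylogeny is the exhaustive-MP tree of the strain-wise
concatenation of all per-gene alignments; its p-distance matrix is the
reference matrix. The screen's specificity index is the arithmetic mean of
bootstrap supports over the *internal* splits of the marker's own MP tree
(leaf edges carry no topological information). The intraspecies difference
column is computed only over strain pairs declared conspecific in the
configuration.

## MLST discovery and typing

The window statistic S counts segregating columns (both characters non-gap,
non-N, and different) in windows of 500 alignment sites stepped by 25; gap
columns are excluded from S (the segregating-sites convention) and tallied
separately. Windows with S ≥ 6 are merged when overlapping or adjacent, and
each merged interval is reported with its variant positions on 1-based
reference-strain coordinates (insertions relative to the reference map to the
preceding reference base). Indel alleles are retained as '-' genotype
characters. Loci are named by the containing gene, or by the flanking
features joined `left-right`. Allele vectors over all variant positions give
pairwise difference counts (missing alleles excluded) and, for ≥3 strains, an
NJ tree on normalized differences.

## SSR detection

An SSR is a maximal perfect tandem repeat of a primitive 1–6 nt motif whose
total length (full copies × unit) meets the per-unit threshold — defaults
mono ≥ 10, di ≥ 10, tri–hexa ≥ 12 nt, inferred from the shortest loci such
panels report and configurable, since no universal criterion exists. Motifs
are canonicalized to the lexicographically smallest rotation; a run is
reported once at its primitive period (poly-A is mononucleotide, never
`(AA)`). Circular genomes are scanned on the doubled sequence and
origin-crossing loci deduplicated. Every reported locus re-validates as an
exact integer number of motif copies not extendable by a full copy on either
side. Cross-strain orthology is keyed on (organelle, canonical motif, locus
context name); shared loci with differing lengths are flagged as copy-number
polymorphic. Compound or adjacent SSRs are reported separately, and
imperfect/interrupted repeats are out of scope.

## NG86 Ka/Ks

Per-codon site counts give each position one site split into synonymous and
nonsynonymous fractions; mutations to stop codons are excluded from the
per-position denominator (a position where all mutations create stops counts
as fully nonsynonymous), so S + N = 3 per codon. Differences between codons
are averaged with equal weight over all minimal mutational pathways,
discarding pathways through stop codons (a codon pair whose pathways all hit
stops is skipped with a warning). Site totals are averaged over the two
sequences; proportions are Jukes–Cantor corrected, undefined at p ≥ 3/4
(flagged, not extrapolated). ω = Ka/Ks is undefined when Ks = 0. The genetic
code is selectable by NCBI translation-table id (default 1); codons containing
gaps or N in either sequence are dropped pairwise. Rate summaries are
arithmetic means of per-gene rates per group with pairwise percentage ratios
rounded to whole percent; nonsynonymous rate (Ka) is the "evolutionary rate"
compared across compartments.

## Simulator

The generator is the package's test harness: it produces what the analysis
modules assume and records ground truth for recovery checks.

* **Ancestor.** Genes are valid ORFs (ATG start, TAA stop, no internal stop
  under the configured code, inner codons uniform over sense codons);
  intergenic spacers are i.i.d. bases at a target GC (default 0.333, typical
  of AT-rich organelle genomes); planted SSRs are inserted verbatim with
  period-breaking flanks so they remain maximal.
* **Evolution.** Along each branch the substitution count per region is
  Poisson(branch length × rate multiplier × region length); substitutions are
  applied sequentially at uniformly resampled positions (multiple hits
  allowed), transitions proposed with probability κ/(κ+2) (default κ = 1.5,
  matching the mild transition excess organelle coding regions show). In
  genes, a proposed nonsynonymous change is accepted with probability
  min(1, ω); synonymous changes always (rejection triggers resampling).
  Indels are Poisson at `indel_rate` (default 0); inside genes they are
  codon-aligned triplets and — because an in-frame indel alters the protein —
  gated by ω like nonsynonymous substitutions, so ω = 0 provably preserves
  every gene's translation. The truth object stores realized (accepted)
  events only, and replaying them from the ancestor reproduces each leaf
  byte-identically.
* **What it does not emulate.** Rearrangements, inverted-repeat dynamics and
  copy-number hotspots, codon-usage and context-dependent mutation,
  recombination, gene transfer to the nucleus, sequencing error. Passing
  recovery tests therefore demonstrates correctness of the analysis under the
  stated generative model, not robustness to structural variation or
  alignment error on real genomes.

### Standard fixtures and problem sizes

Fixture sizes were chosen to exercise each analysis at full algorithmic depth
(six taxa for exhaustive MP, multi-kilobase hotspots for windowed scans)
while staying desk-scale:

* **hotspot** — six strains on a balanced tree (terminal branches 0.03–0.04
  substitutions/site), 12 genes (300–600 bp, ω = 0.3) alternating with 12
  spacers (120–240 bp), three regions at 5× the background rate. The marker
  screen must rank the three hotspots first; note the spacer hotspot is
  extracted under its flanking-gene name.
* **conspecific-pair** — two strains at 0.1% background divergence
  (~26 kb genomes) with three 6 kb regions at 25× rate, sized so the
  windowed scan's boundary uncertainty (~±½ window) leaves interval recovery
  at Jaccard ≥ 0.8.
* **ssr-panel** — two identical strains carrying five planted SSRs (mono
  through tetranucleotide, at and above threshold); background sequence is
  scrubbed of chance repeats so planted-SSR precision and recall are exactly 1.

ω recovery uses 300-codon gene pairs at 0.2 substitutions/site per branch:
divergent enough that the Jukes–Cantor correction matters, low enough that it
remains accurate.

## Numerical and degenerate-input choices

* All randomness flows from `numpy.random.default_rng` seeded from a single
  configuration seed; bootstrap, simulation and fixture generation are
  reproducible bit-for-bit.
* Alignments with zero comparable sites for a pair, empty sequences, <3 NJ
  labels (unless a permissive flag requests the degenerate 2-taxon edge), <4
  MP leaves, B = 0 bootstrap replicates, and out-of-range feature coordinates
  are hard errors; degenerate marker regions produce partially filled,
  flagged evaluation rows instead.
* Coding-effect annotation is dropped with a warning when the ungapped
  reference row is not a codon multiple.
* An alignment shorter than the window length yields a single full-length
  window with a warning.

## Known limitations

* Exhaustive MP is capped at 9 taxa; larger panels get a flagged NNI
  heuristic, and markers evaluated heuristically are never called consistent.
* Center-star alignment can be suboptimal around clustered indels; organelle
  coding regions, where the analyses operate, rarely exhibit these.
* Anchored whole-genome alignment assumes collinearity; genomes with large
  inversions or repeat-mediated rearrangements must be split at breakpoints
  first.
* SSR orthology by (organelle, motif, context) can conflate distinct loci
  that share a motif within the same intergenic context.
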