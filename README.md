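# organphylo

Intragenus phylotyping of organelle genomes for microalgae and other taxa with
small, conserved plastid (pt) and mitochondrial (mt) genomes.

Closely related microalgal species and strains — the motivating case is the
oleaginous genus *Nannochloropsis* — are hard to tell apart with the commonly
used barcode markers (*ITS2*, *18S*, *cox1*, *rbcL*, *psbA*): their SNP density
within a genus is too low, and different markers can encode conflicting
phylogenies. Given complete organelle genomes for a panel of strains,
`organphylo` screens **every** genic and intergenic region for better markers
and builds a three-tier typing strategy:

1. **Interspecies markers** — each orthologous region is aligned and scored for
   *consistency* (its exhaustive maximum-parsimony tree set must contain the
   reference topology built from the concatenation of all protein-coding
   genes), *sensitivity* (% nucleotide difference: polymorphic columns /
   alignment length) and *specificity* (mean bootstrap support over the
   internal splits of the region's own MP tree). Consistent regions are ranked
   by sensitivity against a baseline marker such as *ITS2*.
2. **Intraspecies MLST** — the two conspecific genomes are aligned end-to-end
   (unique *k*-mer anchoring), segregating sites *S* are counted in sliding
   windows (500 sites, step 25), and windows with *S* ≥ 6 are merged into
   multi-locus sequence typing (MLST) loci whose allele vectors type further
   strains.
3. **Strain-level SSRs** — perfect microsatellites (unit 1–6 nt; mono/di ≥ 10
   nt, tri–hexa ≥ 12 nt) are detected per genome and compared across strains by
   (organelle, motif, locus context); strain-specific loci and copy-number
   polymorphisms identify individual strains.

Supporting statistics: p-distance matrices (pairwise or complete deletion), SNP
classification into the exact partition {transition, transversion, indel,
multiallelic} with coding effects (synonymous / nonsynonymous / triplet_indel /
frameshift), and Nei–Gojobori (NG86) Ka/Ks with equal-weight pathway averaging
and Jukes–Cantor correction:

    ps = Sd / S,   pn = Nd / N,   d = -(3/4) ln(1 - (4/3) p),   ω = Ka / Ks

Phylogenetics is self-contained: neighbor-joining (Saitou–Nei), Fitch small
parsimony vectorized over unique column patterns, exhaustive MP over all
(2n−5)!! unrooted topologies for 4–9 taxa (NNI hill climb beyond), column
bootstrap, Robinson–Foulds distance and Euclidean distance between p-distance
matrices.

A seeded simulator (`organphylo.simulate`) generates annotated organelle-like
genomes evolved along a known tree with rate hotspots, transition bias κ,
purifying selection (nonsynonymous changes accepted with probability min(1, ω)),
triplet indels in genes and planted SSRs, recording every accepted mutation in
a replayable truth object — the ground truth behind the test suite.

## Worked example

Typing three conspecific strains at the three MLST loci (`rps11_mt-nad4`,
`rps3_mt`, `cox2-rrn16_mt`) from the bundled allele table:

```python
from organphylo.examples import mlst_example_loci, MLST_STRAINS
from organphylo.mlst import genotype_mlst, locus_difference_counts

loci = mlst_example_loci()
profile, tree = genotype_mlst(loci, MLST_STRAINS)
print("variant positions:", len(profile.positions))
print("CCMP531 vs IMET1 :", profile.difference_count("CCMP531", "IMET1"))
print("IMET1 vs CCMP1779:", profile.difference_count("IMET1", "CCMP1779"))
print("per locus (531 vs IMET1):", locus_difference_counts(profile, "CCMP531", "IMET1"))
print(tree.to_newick())
```

prints

```
variant positions: 29
CCMP531 vs IMET1 : 28
IMET1 vs CCMP1779: 1
per locus (531 vs IMET1): {'rps11_mt-nad4': 4, 'nad4': 4, 'rps3_mt': 6, 'cox2-rrn16_mt': 14}
(CCMP1779:0.034483,CCMP531:0.965517,IMET1:0.000000);
```

CCMP531 is separated from IMET1 by 28 allele differences (8 in
`rps11_mt-nad4` + `nad4`, 6 in `rps3_mt`, 14 in `cox2-rrn16_mt`), while IMET1
and CCMP1779 — indistinguishable by the standard markers — differ at exactly
one position (34995), enough for the NJ tree on the allele vectors to resolve
all three strains.

## Command line

```bash
organphylo simulate --fixture hotspot --seed 1 --outdir fix/
organphylo screen --genomes A.fasta --genomes B.fasta ... --gff A.gff3 ... \
                  --baseline ITS2.fasta --outdir screen/
organphylo mlst --ref IMET1.fasta --alt CCMP531.fasta --gff IMET1.gff3 --outdir mlst/
organphylo ssr --genomes IMET1.fasta --genomes CCMP531.fasta --outdir ssr/
organphylo kaks --regions genic/ --code 1 --outdir kaks/
organphylo run --config pipeline.yaml --outdir out/
```

All reports are TSV; every run writes a manifest (config hash, seed, version,
per-stage status), and identical config + seed reproduce byte-identical
outputs.

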