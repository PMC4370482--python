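# orfdecay

Tools for testing whether a protein-coding gene arose **de novo** from
previously non-coding DNA, by dissecting its homology to non-coding loci.

A de novo origin claim rests on showing that the genomic regions homologous
to a candidate gene — on other chromosomes or in outgroup species — carry
the *ancestral, non-coding* state: their reading frames are broken by
**disablers** (missing start codon, missing stop codon, premature stop
codons, frame-shifting indels), the same disablers are shared across taxa,
and parsimony places a single *gain* of coding ability on one branch of the
species tree. `orfdecay` implements that entire argument as testable code:

- **candidate filtering** over tabular homology-hit files: lineage orphans
  (no protein hit with E ≤ 10⁻⁴ and identity > 35%), exclusion of genes
  with coding homologs on autosomes/chrX, retention of genomic fragments
  longer than 4 kb with identity above 80%;
- **putative-ORF reconstruction**: each coding exon of the reference gene
  model is aligned (affine-gap, semi-global) against both strands of a
  homologous region, placements are chained collinearly, and homolog exons
  are joined in reference order and orientation — tandem copies yield
  ORF "a", ORF "b", …;
- **disabler/enabler scanning**: artificial translation of the putative ORF
  in the reference-defined frame (continuing through internal stops), with
  every ORF-disrupting difference classified and placed at the 0-based
  offset of its codon's first base in the reference spliced CDS;
- **comparative analysis**: a shared-disabler matrix across taxa and
  Fitch/Sankoff parsimony for the coding/non-coding character, with every
  minimal labeling enumerated;
- **phylogenetics**: K2P and TN93 distances (pairwise deletion),
  neighbor joining with deterministic tie-breaking, column bootstrap
  (default 500 replicates), Robinson–Foulds comparison;
- **genome structure**: windowed dot-plots (exact or ≤ *k* mismatches),
  duplicated-segment calling, anchor-based synteny blocks (forward or
  inverted);
- **a sequence-evolution simulator** that builds a coding locus, disables
  it on a chosen branch, evolves it along a tree under a K2P substitution
  process with indels, transposes/duplicates it between genomic
  compartments, optionally re-enables it on one branch — and emits a
  machine-readable truth table, so every stage of the pipeline is testable
  without any external data.

## Worked example

The packaged demo emulates a five-species primate-like history: a coding
locus is disabled at the root (start loss, stop loss, premature stops 42
and 81 nt downstream of the start, and a 4-nt frameshifting deletion),
transposed from an autosome to the Y chromosome on the catarrhine stem,
duplicated in tandem on the human/chimpanzee stem, and re-enabled (every
disabler reverted) on the ape stem — on the Y copy only.

```bash
orfdecay demo --out demo_out --seed 0
# demo ok: single coding-ability gain on the ape stem; 11 ORFs scanned
```

`demo_out/disablers.tsv` lists each scanned ORF's disablers. For the
outgroup's autosomal ORF (seed 0):

```text
orf_id  type                         exon  ref_nt_offset  ref_codon  obs    indel_len
a       START_LOSS                   0     0              ATG        TTG    0
a       PREMATURE_STOP_SUBSTITUTION  0     42             GCC        TAA    0
a       PREMATURE_STOP_SUBSTITUTION  0     81             GAC        TAA    0
a       FRAMESHIFT_INDEL             1     141            GAA        -AGCT  -4
a       PREMATURE_STOP_FRAMESHIFT    1     178            TAG        TAG    0
a       STOP_LOSS                    3     354            TAA        AAA    0
```

Reading: the start codon is TTG instead of ATG; two substitutions create
in-frame TAA stops at CDS offsets 42 and 81; a 4-nt deletion in exon 2
shifts the frame, exposing a stop readable only in the shifted frame at
offset 178; and the terminal TAA has decayed to AAA. The ape Y-chromosome
ORFs report no disablers (`is_coding` true). `demo_out/history.txt` then
summarizes the parsimony reconstruction:

```text
parsimony score 1; 1 minimal labeling(s)
gain of coding ability after the ape-Old World monkey split
```

and `demo_out/shared_disablers.tsv` shows each disabler present in every
non-coding compartment and absent from the enabled Y copies — the
shared-disabler signature of a common non-coding ancestor.

The same stages are available individually (`orfdecay filter`,
`reconstruct`, `scan`, `compare`, `tree`, `dotplot`, `synteny`,
`simulate`, `run`) and as library functions.

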