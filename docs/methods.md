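# Methods

This note documents the models, conventions and design choices behind
`orfdecay`, in the order the pipeline runs them.

## Candidate filtering

Filtering is pure decision logic over precomputed tabular homology hits
(the standard 12-column dialect, 1-based inclusive coordinates in the file,
converted to 0-based half-open on load). A gene is a lineage orphan iff no
out-lineage protein hit has E-value ≤ `e_max` (default 10⁻⁴) **and**
identity strictly greater than `identity_min` (default 35%). A qualifying
within-lineage protein hit whose subject lies on an autosome or chrX
excludes the gene; the chromosome class comes from an explicit mapping file
because assembly naming is not standardized. Genomic fragments are retained
when strictly longer than 4 000 bp and strictly above 80% identity,
applied per hit (not merged regions). "Over" and "greater than" are read as
strict inequalities throughout and the boundary behaviour is unit-tested.
The identity filter applies per hit (per-HSP); the hit table does not carry
enough information to re-aggregate full-query identity.

## ORF reconstruction

Each reference coding exon is aligned semi-globally (exon end-to-end,
region overhangs free) against both strands of the candidate region with
affine gaps: match +2, mismatch −3, gap open −5 (first gap position), gap
extension −2. N and all other ambiguity codes score 0 against everything,
so unknown bases neither fabricate nor destroy identity. Among co-optimal
alignments the one with fewest internal gap columns, then the leftmost, is
chosen — this prevents a terminal mismatch from being reported as an indel
when a flanking base happens to match. Additional placements of the same
exon (tandem copies) are found by masking each accepted placement with N
and realigning; placements below a 60% identity floor are discarded.

Placements are chained collinearly (same strand, region order consistent
with exon order, no overlaps) by dynamic programming; a large per-exon
bonus makes coverage dominate alignment score, and ties resolve toward
smaller region coordinates. Chains are extracted greedily, consuming their
placements, so a region with two tandem locus copies yields two disjoint
complete ORFs labeled "a" and "b" in coordinate order. The joined sequence
is the concatenation of homolog exon sequences oriented to the reference
strand. Offsets in the joined sequence project to reference spliced-CDS
offsets through the per-exon alignments; positions inside homolog-only
insertions project to the preceding reference base and carry an
`inserted` flag.

## Disabler scanning

Scanning consumes a reference-CDS-scale alignment. Two canonicalization
passes precede classification:

1. **Gap-pair collapse.** An insertion and a deletion of equal length
   within six columns of each other are rewritten as direct base pairing.
   Two frame-shifting indels that exactly cancel within a codon or two is
   not a credible evolutionary parse — the parsimonious reading is a run of
   substitutions — and affine aligners produce exactly this artifact around
   clustered substitutions. The collapse may lower the raw alignment score;
   it is a classification choice, not an alignment-score choice.
2. **Left normalization.** Every gap run is shifted to its leftmost
   sequence-equivalent placement, within its exon, so indel offsets are
   deterministic and comparable across taxa. The simulator plants indels
   under the same convention.

Classification then emits: START_LOSS when the codon aligned to the
reference ATG is not ATG; STOP_LOSS when the codon aligned to the terminal
stop is not in {TAA, TAG, TGA}; FRAMESHIFT_INDEL for each gap run whose
length is not a multiple of 3 (signed length, + for homolog insertions);
PREMATURE_STOP_SUBSTITUTION for each homolog stop codon read in net frame
0 against a reference sense codon; and PREMATURE_STOP_FRAMESHIFT for stops
readable only in a shifted frame. The net frame at any position is the
signed sum of upstream indel lengths mod 3. Frame-preserving indels are
recorded as notes, not disablers. Codons containing N translate to X and
are never called stops.

**Offset convention.** `ref_nt_offset` is the 0-based offset of the
affected codon's first base in the reference spliced CDS, with the start
codon at offset 0 — under this convention premature stops land on
multiples of 3 unless an upstream frameshift intervenes. For indels the
offset is the codon containing the first affected reference base (first
deleted base; for insertions, the first reference base after the gap),
taken after left normalization. Output headers state the convention so
alternative conventions (e.g. counting from the base after ATG) can be
derived; where a different counting convention would disagree, the package
reports its own and does not force agreement.

Artificial translation renders the homolog in the reference-anchored frame
and continues through internal stops ('*'), as the alignment renderings
show; `is_coding` is decided from the disabler list, never from the
translation. Enabler scanning reverses the roles: the derived coding
sequence supplies the frame, and every disabler found in the non-coding
sequence relative to it is one enabling change on the branch to the coding
state. Text renderings are fixed-width, codon-aligned, deterministic, with
one marker per disabler.

## Comparative analysis

The shared-disabler matrix keys disablers by (type, projected reference
offset); a tolerance window (default 0 nt, configurable) clusters nearby
offsets of the same type for diverged real data — exact projection is
achievable on synthetic data, so the default stays strict. Rows present in
every column with known state are flagged ancestral candidates.

Ancestral coding state is inferred by unit-cost small parsimony
(Sankoff recursion) on the binary coding/non-coding character. "absent"
and "unknown" are missing data: such leaves may take either state at no
cost. All minimum-change labelings are enumerated and deduplicated, so
ties are explicit; events (gain_coding / loss_coding) are read off each
labeling, with branches named by the node they lead to. The textual
summary maps branches to user-supplied split labels; no dating is
computed. This operationalizes a verbal ancestry argument as a testable
computation; the output states the method used.

## Phylogenetics

K2P: with transition proportion P and transversion proportion Q over
pairwise-included columns, d = −½·ln((1−2P−Q)·√(1−2Q)). TN93 uses the
standard closed form with empirical base frequencies and separate purine
and pyrimidine transition proportions; it reduces toward K2P at equal
frequencies and falls back to K2P when a base class is absent. Columns
with a gap or ambiguity in either sequence of a pair are excluded for that
pair (pairwise deletion), maximizing usable signal on short alignments.
Log arguments ≤ 0 raise a saturation error rather than returning a
truncated distance. Both closed forms were verified against R `ape`'s
`dist.dna` (K80 and TN93) to seven decimals on simulated data.

Neighbor joining is the canonical algorithm; ties in the Q-criterion
resolve to the lowest taxon-index pair, making tree construction fully
deterministic. Negative branch lengths are clamped to zero and counted in
a tree annotation. The bootstrap resamples alignment columns with
replacement (seeded), rebuilds the NJ tree, and reports per-bipartition
support as the percentage of replicates containing that bipartition;
saturated replicates are skipped and the effective replicate count is
recorded. NJ with a distance model stands in for a likelihood tree search:
it is desk-scale, fully testable, and uses the same distance family;
topology agreement on clean synthetic data is the test surface, and output
metadata states the substitution.

## Genome structure

A dot at (i, j) means the two length-`window` substrings starting at i
and j differ at ≤ `max_mismatch` positions. Dots are indexed by 0-based
window start; the implementation walks diagonals with cumulative-sum
window counts and is verified against an all-window-pairs brute force.
Repeat segments merge runs of same-offset off-diagonal dots (gap tolerance
configurable) into intervals; reverse-strand runs group by anti-diagonal.
The segment-calling thresholds (`min_segment`, gap tolerance) are free
parameters — segment boundaries in real data are read off the plot, and no
published calling rule exists to pin them.

Synteny blocks partition the anchors shared by two ordered gene lists
into maximal runs whose order in the second list is monotone — increasing
with all relative strands '+' (forward) or decreasing with all '−'
(inverted). Pseudogene-suffix normalization ("P"/"_P") is opt-in per run,
since suffix conventions differ between annotation sources.

## The simulator

The generator defines the test conditions; everything is derived from one
seed. The ancestral locus is a random CDS of sense codons (ATG first, one
of the three stops last) split across exons (defaults 90/121/83/63 bp —
deliberately not all multiples of 3, so codons straddle junctions) with
random introns (150/140/130 bp) and 200-bp flanks. Substitutions follow a
continuous-time K2P process (κ = 2 by default) calibrated so branch length
equals expected substitutions per site. Indels occur at `indel_rate`
events per site per unit branch length (default 0.002 in the demo),
geometric length (p = 0.5, capped at 6), never straddling segment
boundaries so truth offsets remain well defined.

Disablers are planted by minimal edits: one substitution for
start/stop/premature-stop losses, one short indel for frameshifts,
positions left-normalized exactly as the scanner normalizes. A planted
frameshift deterministically exposes stop codons in the shifted frame
downstream; the generator computes these from its exact edit coordinates
(no alignment involved) and emits them as *derived* truth rows, since any
correct scanner necessarily reports them.

Every planted edit is tracked through subsequent evolution at base
resolution. The truth table marks a row `intact` only if its diagnostic
state survives in the leaf: the start codon is still broken, a planted
stop is still a stop **and** still readable in the expected frame (no
later frame-changing indel upstream), a planted indel is not confounded by
a later indel in the same exon. Recovery statistics use intact rows as the
denominator — a disabler erased by later neutral evolution is not
recoverable by any scanner, and at 0.05 substitutions/site roughly 10% of
planted stop codons mutate away, so the raw planted set would conflate
scanner accuracy with simulation attrition.

Transposition copies a locus into another compartment (optionally
inverted; inversion is applied at emission, with minus-strand gene models).
Duplication creates tandem copies emitted as one concatenated region per
compartment. Enabling on a branch reverts every planted edit (right to
left, so positions stay valid), reverts evolved exon indels, restores any
divergence-created stop to the ancestral codon, and thereafter rejects
mutations that would re-disable the ORF — substitutions creating a stop
are reverted codon-wise, and exon indels are rejected outright. This hard
rejection rule is the simplest mechanism guaranteeing a coding leaf
exists; it is an idealization of purifying selection, not a fitness model.

The substitution process is K2P, matching the analysis distance exactly;
the TN93 analysis option therefore has a deliberate model mismatch on
simulated data, which the tests account for by comparing the two
distances rather than assuming identity.

**What the simulator does not emulate:** gene conversion and non-allelic
homologous recombination between amplicon copies, codon-usage and
composition biases, rate heterogeneity across sites, splice-site evolution,
and population-level processes. Passing tests therefore demonstrate that
the pipeline's logic is correct under a clean substitution+indel model,
not that it is robust to every feature of real Y-chromosome data.

## Demo scenario and problem sizes

The packaged scenario uses five taxa (three apes, one Old World monkey,
one New World monkey outgroup) with all leaves equidistant from the root;
the `divergence` parameter is that root-to-leaf substitution load. Plants
at the root: START_LOSS, STOP_LOSS, premature stops at offsets 42 and 81,
and a 4-nt deletion in exon 2; transposition autosome→chrY on the
catarrhine stem; tandem duplication (2 copies) of the Y locus on the
human/chimpanzee stem; enabling on the ape stem, Y compartment only.

Problem sizes used by the test suite and acceptance script — chosen as
comfortable desk-scale settings: locus ≈ 1.8 kb; 50 seeds for recovery
under 0.05 substitutions/site; 100 seeds × 10 kb alignments for NJ
topology recovery and K2P calibration; 500 bootstrap replicates on a 2-kb
quartet alignment; brute-force oracle comparisons on sequences ≤ 400 bp,
trees ≤ 6 leaves.

## Known limitations

- Putative-ORF reconstruction assumes exon-sized homology is recoverable
  by pairwise alignment; it does not model splice sites, and heavily
  shuffled or truncated loci surface only as incomplete ORFs.
- Exact-offset recovery of frameshifts can fail when substitutions near an
  indel create new repeat structure that changes the left-normalized gap
  placement; at 5% divergence this costs a few percent of indel rows.
- Parsimony reconstruction treats each taxon's chosen compartment as one
  character state; it does not model gene copies individually.
- The NJ/bootstrap stack is a distance method; very short alignments (such
  as a single-exon region) can saturate or leave bipartitions unresolved,
  and the pipeline then records a warning rather than a tree.
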