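"""Putative-ORF reconstruction from homologous genomic regions.

Each protein-coding exon of a reference gene model is aligned (affine-gap,
semi-global: the exon fully aligned, the region end-gap free) against both
strands of a candidate homologous region. The best placements are chained
collinearly — all chosen placements in consistent order and a common
orientation along the region — and the chained homolog exon sequences are
joined in reference exon order and orientation to form putative ORFs. A
region carrying tandem copies of the locus yields one putative ORF per copy,
labelled "a", "b", ... in region coordinate order.

Alignment scoring defaults: match +2, mismatch -3, gap open -5, gap extend
-2. N (or any ambiguity code) scores 0 against everything so unknown bases
neither fabricate nor destroy identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from orfdecay.core_io import (
    AlignmentPair,
    GeneModel,
    GenomicInterval,
    SeqRecord,
    revcomp,
)

_ALPHABET = "ACGTNRYSWKMBDHV"


@dataclass(frozen=True)
class AlignParams:
    """Nucleotide alignment scoring; N/ambiguity scores 0 everywhere."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    min_identity: float = 60.0  # identity floor (%) for a reported placement
    max_placements: int = 8


def _substitution_matrix(params: AlignParams):
    m = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            if a in "ACGT" and b in "ACGT":
                m[a, b] = params.match if a == b else params.mismatch
            else:
                m[a, b] = 0.0
    return m


def _make_aligner(params: AlignParams, semi_global: bool = True) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _substitution_matrix(params)
    # gap open = score of the first gap position; extensions add gap_extend
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    if semi_global:
        # query = exon aligned end to end; region (target) overhangs are free,
        # i.e. end gaps in the query row cost nothing
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    return aligner


@dataclass
class Placement:
    """One candidate location of a reference exon in the region."""

    interval: GenomicInterval  # region coordinates, strand = orientation of the copy
    alignment: AlignmentPair  # ref row = exon (coding strand), hom row oriented to it
    pct_identity: float
    score: float

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class ExonMap:
    """The chosen placement of one exon (or the record that none was found)."""

    exon_index: int
    hom_interval: GenomicInterval | None = None
    alignment: AlignmentPair | None = None
    pct_identity: float = 0.0
    found: bool = False


@dataclass
class PutativeORF:
    """A homolog-derived candidate coding sequence joined in reference exon order."""

    orf_id: str
    exon_maps: list[ExonMap]
    joined_seq: str = ""
    complete: bool = False

    def __post_init__(self) -> None:
        if not self.joined_seq:
            self.joined_seq = "".join(
                m.alignment.hom_seq for m in self.exon_maps if m.found
            )
        self.complete = all(m.found for m in self.exon_maps)

    def spliced_alignment(self) -> tuple[AlignmentPair, list[int]]:
        """Concatenate per-exon alignments into one reference-CDS-scale alignment.

        Returns the alignment plus the cumulative reference offsets at which
        each found exon starts (used for exon attribution of disablers).
        """
        ref_parts, hom_parts, bounds = [], [], []
        acc = 0
        for m in self.exon_maps:
            if not m.found:
                continue
            bounds.append(acc)
            ref_parts.append(m.alignment.ref_aln)
            hom_parts.append(m.alignment.hom_aln)
            acc += len(m.alignment.ref_seq)
        return AlignmentPair("".join(ref_parts), "".join(hom_parts)), bounds


def _pick_alignment(alns, limit: int = 16):
    """Deterministic choice among co-optimal alignments: fewest internal gap
    columns, then leftmost target start (avoids spurious indel calls when a
    terminal mismatch ties with a gap into the flanking sequence)."""
    import itertools as _it

    best = None
    for aln in _it.islice(alns, limit):
        t_row = str(aln[0])
        q_row = str(aln[1])
        left = 0
        while left < len(q_row) and q_row[left] == "-":
            left += 1
        right = len(q_row)
        while right > left and q_row[right - 1] == "-":
            right -= 1
        gaps = t_row[left:right].count("-") + q_row[left:right].count("-")
        start = len(t_row[:left].replace("-", ""))
        key = (gaps, start)
        if best is None or key < best[0]:
            best = (key, aln)
    return best[1]


def _trim_to_query(aln) -> tuple[int, int, str, str]:
    """Extract the target span and row strings covering the full query from a
    Biopython alignment (target = region, query = exon)."""
    target_aln = str(aln[0])
    query_aln = str(aln[1])
    # strip columns where the query has end gaps (free region overhangs)
    left = 0
    while left < len(query_aln) and query_aln[left] == "-":
        left += 1
    right = len(query_aln)
    while right > left and query_aln[right - 1] == "-":
        right -= 1
    t_row = target_aln[left:right]
    q_row = query_aln[left:right]
    t_start = len(target_aln[:left].replace("-", ""))
    t_end = t_start + len(t_row.replace("-", ""))
    return t_start, t_end, t_row, q_row


def _identity(ref_row: str, hom_row: str) -> float:
    n = len(ref_row)
    if n == 0:
        return 0.0
    matches = sum(1 for a, b in zip(ref_row, hom_row) if a == b and a != "-")
    return 100.0 * matches / n


def align_exon(
    ref_exon_seq: str,
    region_seq: str,
    params: AlignParams = AlignParams(),
    region_id: str = "region",
) -> list[Placement]:
    """Find the best placements of an exon on both strands of a region.

    Placements are discovered iteratively: after each best placement the
    covered window is masked with N and the alignment repeated, so tandem
    copies surface as separate placements. Results are sorted by score
    descending, ties broken by leftmost region start then + strand.
    """
    if len(ref_exon_seq) < 10:
        raise ValueError("reference exon shorter than 10 bp")
    if len(region_seq) < len(ref_exon_seq):
        return []
    aligner = _make_aligner(params)
    fwd = region_seq.upper()
    rev = revcomp(fwd)
    n = len(fwd)
    placements: list[Placement] = []
    for _ in range(params.max_placements):
        candidates = []
        for strand, target in (("+", fwd), ("-", rev)):
            alns = aligner.align(target, ref_exon_seq)
            aln = _pick_alignment(alns)
            t_start, t_end, t_row, q_row = _trim_to_query(aln)
            if t_end == t_start:
                continue
            if strand == "+":
                start, end = t_start, t_end
            else:
                start, end = n - t_end, n - t_start
            pair = AlignmentPair(ref_aln=q_row, hom_aln=t_row, score=float(aln.score))
            ident = _identity(q_row, t_row)
            candidates.append(
                Placement(
                    interval=GenomicInterval(region_id, start, end, strand),
                    alignment=pair,
                    pct_identity=ident,
                    score=float(aln.score),
                )
            )
        if not candidates:
            break
        candidates.sort(key=lambda p: (-p.score, p.interval.start, p.strand))
        best = candidates[0]
        if best.pct_identity < params.min_identity or best.score <= 0:
            break
        placements.append(best)
        # mask the placed window on both strand copies before the next round
        s, e = best.interval.start, best.interval.end
        fwd = fwd[:s] + "N" * (e - s) + fwd[e:]
        rev = rev[: n - e] + "N" * (e - s) + rev[n - s :]
    placements.sort(key=lambda p: (-p.score, p.interval.start, p.strand))
    return placements


_COVER_BONUS = 10_000.0  # chain DP strongly prefers covering more exons


def _best_chain(
    placements_per_exon: Sequence[Sequence[Placement]],
) -> list[tuple[int, Placement]]:
    """Maximum-score collinear chain over per-exon placements.

    All placements in a chain share a strand; placements occur along the
    region in exon order for +, reverse order for -. Ties are broken towards
    smaller region starts (deterministic).
    """
    best_overall: list[tuple[int, Placement]] = []
    best_score = 0.0
    for strand in ("+", "-"):
        nodes: list[tuple[int, Placement]] = [
            (i, p)
            for i, plist in enumerate(placements_per_exon)
            for p in plist
            if p.strand == strand
        ]
        # DP over nodes sorted by exon index then region start
        nodes.sort(key=lambda t: (t[0], t[1].interval.start))
        score = [0.0] * len(nodes)
        prev = [-1] * len(nodes)
        for j, (ej, pj) in enumerate(nodes):
            score[j] = pj.score + _COVER_BONUS
            for i, (ei, pi) in enumerate(nodes[:j]):
                if ei >= ej:
                    continue
                if strand == "+":
                    ok = pi.interval.end <= pj.interval.start
                else:
                    ok = pj.interval.end <= pi.interval.start
                if ok and score[i] + pj.score + _COVER_BONUS > score[j]:
                    score[j] = score[i] + pj.score + _COVER_BONUS
                    prev[j] = i
        if nodes:
            jbest = max(range(len(nodes)), key=lambda j: score[j])
            if score[jbest] > best_score:
                chain = []
                j = jbest
                while j != -1:
                    chain.append(nodes[j])
                    j = prev[j]
                chain.reverse()
                best_overall = chain
                best_score = score[jbest]
    return best_overall


def map_exons(
    gene_model: GeneModel,
    ref_genome: dict[str, SeqRecord] | SeqRecord,
    region: SeqRecord,
    params: AlignParams = AlignParams(),
) -> list[ExonMap]:
    """Best collinear placement of every exon of the gene model in the region."""
    placements = [
        align_exon(exon_seq, region.seq, params, region_id=region.id)
        for exon_seq in _exon_seqs(gene_model, ref_genome)
    ]
    chain = dict(_best_chain(placements))
    return [
        ExonMap(
            exon_index=i,
            hom_interval=chain[i].interval if i in chain else None,
            alignment=chain[i].alignment if i in chain else None,
            pct_identity=chain[i].pct_identity if i in chain else 0.0,
            found=i in chain,
        )
        for i in range(len(gene_model.exons))
    ]


def _exon_seqs(gene_model: GeneModel, ref_genome) -> list[str]:
    from orfdecay.core_io import extract_interval

    rec = ref_genome if isinstance(ref_genome, SeqRecord) else ref_genome[gene_model.seq_id]
    return [extract_interval(rec, e) for e in gene_model.exons]


def enumerate_orfs(
    placements_per_exon: Sequence[Sequence[Placement]],
) -> list[PutativeORF]:
    """Partition placements into maximal collinear chains, one putative ORF each.

    Chains are extracted greedily by total score; consumed placements are
    removed before the next extraction, so tandem locus copies yield disjoint
    complete ORFs. ORF ids "a", "b", ... follow region coordinate order.
    """
    remaining = [list(pl) for pl in placements_per_exon]
    n_exons = len(placements_per_exon)
    chains: list[list[tuple[int, Placement]]] = []
    while True:
        chain = _best_chain(remaining)
        if not chain:
            break
        chains.append(chain)
        used = {(i, id(p)) for i, p in chain}
        remaining = [
            [p for p in plist if (i, id(p)) not in used]
            for i, plist in enumerate(remaining)
        ]
        if len(chains) > 26:
            break
    chains.sort(key=lambda c: min(p.interval.start for _, p in c))
    orfs = []
    for label_idx, chain in enumerate(chains):
        by_exon = dict(chain)
        maps = [
            ExonMap(
                exon_index=i,
                hom_interval=by_exon[i].interval if i in by_exon else None,
                alignment=by_exon[i].alignment if i in by_exon else None,
                pct_identity=by_exon[i].pct_identity if i in by_exon else 0.0,
                found=i in by_exon,
            )
            for i in range(n_exons)
        ]
        orfs.append(PutativeORF(orf_id=chr(ord("a") + label_idx), exon_maps=maps))
    return orfs


def reconstruct_orfs(
    gene_model: GeneModel,
    ref_genome: dict[str, SeqRecord] | SeqRecord,
    region: SeqRecord,
    params: AlignParams = AlignParams(),
) -> list[PutativeORF]:
    """End-to-end: align every exon against the region and enumerate putative ORFs."""
    placements = [
        align_exon(exon_seq, region.seq, params, region_id=region.id)
        for exon_seq in _exon_seqs(gene_model, ref_genome)
    ]
    return enumerate_orfs(placements)


def project_position(putative_orf: PutativeORF, hom_offset: int) -> tuple[int, bool]:
    """Map a 0-based offset in joined_seq to the reference spliced-CDS offset.

    Positions inside homolog-only insertions map to the offset of the
    preceding reference base and are flagged (ref_offset, inserted=True).
    """
    if hom_offset < 0:
        raise IndexError("negative offset")
    acc_hom = 0
    acc_ref = 0
    for m in putative_orf.exon_maps:
        if not m.found:
            continue
        hom_len = len(m.alignment.hom_seq)
        ref_len = len(m.alignment.ref_seq)
        if hom_offset < acc_hom + hom_len:
            within = hom_offset - acc_hom
            hom_i = -1
            ref_i = -1
            for a, b in zip(m.alignment.ref_aln, m.alignment.hom_aln):
                if b != "-":
                    hom_i += 1
                if a != "-":
                    ref_i += 1
                if hom_i == within:
                    if a == "-":
                        return acc_ref + max(ref_i, 0), True
                    return acc_ref + ref_i, False
            raise IndexError("offset not reached; inconsistent alignment")
        acc_hom += hom_len
        acc_ref += ref_len
    raise IndexError(f"offset {hom_offset} beyond joined sequence length {acc_hom}")


def unproject_position(putative_orf: PutativeORF, ref_offset: int) -> int | None:
    """Inverse of :func:`project_position` for non-deleted reference positions.

    Returns None when the reference base is deleted in the homolog.
    """
    if ref_offset < 0:
        raise IndexError("negative offset")
    acc_hom = 0
    acc_ref = 0
    for m in putative_orf.exon_maps:
        if not m.found:
            continue
        hom_len = len(m.alignment.hom_seq)
        ref_len = len(m.alignment.ref_seq)
        if ref_offset < acc_ref + ref_len:
            within = ref_offset - acc_ref
            hom_i = -1
            ref_i = -1
            for a, b in zip(m.alignment.ref_aln, m.alignment.hom_aln):
                if b != "-":
                    hom_i += 1
                if a != "-":
                    ref_i += 1
                    if ref_i == within:
                        return acc_hom + hom_i if b != "-" else None
            raise IndexError("offset not reached; inconsistent alignment")
        acc_hom += hom_len
        acc_ref += ref_len
    raise IndexError(f"offset {ref_offset} beyond reference spliced length {acc_ref}")
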