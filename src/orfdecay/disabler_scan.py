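"""Artificial translation and disabler/enabler detection.

A *disabler* is a sequence difference that disrupts an open reading frame
relative to a coding reference: loss of the start codon, loss of the stop
codon, an in-frame premature stop codon introduced by substitution, a
frame-shifting indel, or a premature stop arising only in the shifted frame
downstream of such an indel. An *enabler* is the converse — a change that
removes a disabler, contributing to acquisition of coding ability.

Artificial translation renders the homolog in the reference-defined reading
frame and continues through internal stop codons (shown as '*'), so every
disabler is visible in one display; coding status is decided from the
disabler list, not from the translation.

Coordinate convention: ``ref_nt_offset`` is the 0-based offset of the
affected codon's first base in the reference spliced CDS, with the start
codon occupying offsets 0..2. Indels are left-normalized (shifted to their
leftmost sequence-equivalent placement) before the offset is taken.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from Bio.Data import CodonTable

from orfdecay.core_io import AlignmentPair

_TABLE = CodonTable.unambiguous_dna_by_id[1]
START_CODONS = {"ATG"}
STOP_CODONS = set(_TABLE.stop_codons)  # {TAA, TAG, TGA}


class DisablerType(enum.Enum):
    START_LOSS = "START_LOSS"
    STOP_LOSS = "STOP_LOSS"
    PREMATURE_STOP_SUBSTITUTION = "PREMATURE_STOP_SUBSTITUTION"
    PREMATURE_STOP_FRAMESHIFT = "PREMATURE_STOP_FRAMESHIFT"
    FRAMESHIFT_INDEL = "FRAMESHIFT_INDEL"


@dataclass(frozen=True)
class Disabler:
    type: DisablerType
    exon_index: int
    ref_nt_offset: int
    ref_codon: str = ""
    obs_codon_or_indel: str = ""
    indel_len: int = 0  # signed: + insertion in homolog, - deletion; frameshifts only
    note: str = ""

    def key(self) -> tuple[str, int]:
        """Identity used for cross-taxon matching."""
        return (self.type.value, self.ref_nt_offset)


@dataclass
class DisablerReport:
    orf_id: str
    disablers: list[Disabler]
    is_coding: bool
    translation: str
    alignment: AlignmentPair | None = None
    exon_bounds: list[int] = field(default_factory=list)  # ref CDS offsets at exon starts
    warnings: list[str] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "orf_id": [self.orf_id] * len(self.disablers),
                "type": [d.type.value for d in self.disablers],
                "exon": [d.exon_index for d in self.disablers],
                "ref_nt_offset": [d.ref_nt_offset for d in self.disablers],
                "ref_codon": [d.ref_codon for d in self.disablers],
                "obs": [d.obs_codon_or_indel for d in self.disablers],
                "indel_len": [d.indel_len for d in self.disablers],
                "note": [d.note for d in self.disablers],
            }
        )


@dataclass
class EnablerReport:
    enablers: list[tuple[Disabler, str]]


def translate(nt_seq: str, frame: int = 0) -> str:
    """Artificial translation: standard code, '*' for stops, continues past
    internal stops; codons containing N/ambiguity render 'X'; trailing 1-2 nt
    dropped."""
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    seq = nt_seq.upper()[frame:]
    out = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            out.append("*")
        elif codon in _TABLE.forward_table:
            out.append(_TABLE.forward_table[codon])
        else:
            out.append("X")
    return "".join(out)


def left_align_gaps(aln: AlignmentPair) -> AlignmentPair:
    """Shift every gap run to its leftmost sequence-equivalent placement.

    Among score-equivalent alignments of an indel inside a repeat, the
    reported indel position is otherwise arbitrary; left normalization makes
    disabler offsets deterministic and comparable across taxa.
    """
    ref = list(aln.ref_aln)
    hom = list(aln.hom_aln)
    for row, other in ((ref, hom), (hom, ref)):
        i = 0
        n = len(row)
        while i < n:
            if row[i] != "-":
                i += 1
                continue
            j = i
            while j < n and row[j] == "-":
                j += 1
            # gap run [i, j): shifting it one left pairs row[i-1] with
            # other[j-1] instead of other[i-1]; score-equivalent iff those
            # two other-row bases are equal. Only the gapped row changes.
            while (
                i > 0
                and row[i - 1] != "-"
                and other[i - 1] != "-"
                and other[j - 1] != "-"
                and other[i - 1] == other[j - 1]
            ):
                row[j - 1] = row[i - 1]
                row[i - 1] = "-"
                i -= 1
                j -= 1
            i = j
    return AlignmentPair("".join(ref), "".join(hom), aln.score)


def collapse_gap_pairs(aln: AlignmentPair, max_sep: int = 6) -> AlignmentPair:
    """Replace compensating equal-length gap pairs with direct base pairing.

    An insertion and a deletion of the same length within ``max_sep`` columns
    of each other are almost always an alignment artifact around clustered
    substitutions: the evolutionarily parsimonious reading is a run of
    substitutions, not two frame-shifting indels that cancel. Collapsing them
    (which may lower the raw alignment score) prevents spurious frameshift
    calls and keeps downstream offset projection exact.
    """
    ref = aln.ref_aln
    hom = aln.hom_aln
    changed = True
    while changed:
        changed = False
        runs: list[tuple[int, int, str]] = []  # (start, end, row with the gap)
        col = 0
        n = len(ref)
        while col < n:
            if ref[col] == "-" or hom[col] == "-":
                row = "ref" if ref[col] == "-" else "hom"
                j = col
                while j < n and (ref[j] == "-" if row == "ref" else hom[j] == "-"):
                    j += 1
                runs.append((col, j, row))
                col = j
            else:
                col += 1
        for (s1, e1, r1), (s2, e2, r2) in zip(runs, runs[1:]):
            if r1 == r2 or (e1 - s1) != (e2 - s2) or s2 - e1 > max_sep:
                continue
            ref_seg = ref[s1:e2].replace("-", "")
            hom_seg = hom[s1:e2].replace("-", "")
            if len(ref_seg) != len(hom_seg):  # pragma: no cover - defensive
                continue
            ref = ref[:s1] + ref_seg + ref[e2:]
            hom = hom[:s1] + hom_seg + hom[e2:]
            changed = True
            break
    return AlignmentPair(ref, hom, aln.score)


def _exon_of(offset: int, exon_bounds: Sequence[int]) -> int:
    if not exon_bounds:
        return 0
    idx = 0
    for i, b in enumerate(exon_bounds):
        if offset >= b:
            idx = i
    return idx


def scan_disablers(
    ref_cds: str,
    alignment: AlignmentPair,
    exon_bounds: Sequence[int] = (),
    orf_id: str = "orf",
    ref_start: int = 0,
    normalize: bool = True,
) -> DisablerReport:
    """Detect and classify every ORF-disrupting difference in an aligned homolog.

    ``alignment`` pairs (part of) the reference spliced CDS with the homolog
    putative ORF; ``ref_start`` gives the CDS offset of the alignment's first
    reference base. Start/stop checks are skipped (with a warning) when the
    alignment does not cover the respective codon. Disablers are reported
    sorted by ``ref_nt_offset``.
    """
    ref_cds = ref_cds.upper()
    if normalize:
        alignment = left_align_gaps(collapse_gap_pairs(alignment))
    ref_aln, hom_aln = alignment.ref_aln.upper(), alignment.hom_aln.upper()
    ref_seq = ref_aln.replace("-", "")
    hom_seq = hom_aln.replace("-", "")
    if ref_cds[ref_start : ref_start + len(ref_seq)] != ref_seq:
        raise ValueError("alignment reference row does not match ref_cds at ref_start")
    warnings: list[str] = []
    disablers: list[Disabler] = []
    L = len(ref_cds)

    # per-column bookkeeping: ref offset and hom index at each column
    ref_off_at_col: list[int] = []  # offset of ref base at column, or -1 for gap
    hom_idx_at_col: list[int] = []
    r = ref_start - 1
    h = -1
    for a, b in zip(ref_aln, hom_aln):
        if a != "-":
            r += 1
        if b != "-":
            h += 1
        ref_off_at_col.append(r if a != "-" else -1)
        hom_idx_at_col.append(h if b != "-" else -1)

    # hom base aligned to each covered ref offset ('-' if deleted)
    hom_at_ref: dict[int, str] = {}
    for col, (a, b) in enumerate(zip(ref_aln, hom_aln)):
        if a != "-":
            hom_at_ref[ref_off_at_col[col]] = b
    # projected ref offset (preceding ref base for insertions) per hom index
    ref_at_hom: dict[int, tuple[int, bool]] = {}
    last_ref = ref_start - 1
    for col, (a, b) in enumerate(zip(ref_aln, hom_aln)):
        if a != "-":
            last_ref = ref_off_at_col[col]
        if b != "-":
            ref_at_hom[hom_idx_at_col[col]] = (
                (last_ref, False) if a != "-" else (max(last_ref, 0), True)
            )

    covers_start = ref_start == 0 and all(o in hom_at_ref for o in (0, 1, 2))
    covers_stop = all(o in hom_at_ref for o in (L - 3, L - 2, L - 1))

    # (i) start-codon check
    if covers_start:
        obs_start = "".join(hom_at_ref[o] for o in (0, 1, 2))
        if obs_start != "ATG":
            disablers.append(
                Disabler(
                    DisablerType.START_LOSS,
                    _exon_of(0, exon_bounds),
                    0,
                    ref_codon=ref_cds[0:3],
                    obs_codon_or_indel=obs_start,
                )
            )
    else:
        warnings.append("alignment does not cover the start codon; start check skipped")

    # (ii) stop-codon check
    if covers_stop:
        obs_stop = "".join(hom_at_ref[o] for o in (L - 3, L - 2, L - 1))
        if obs_stop not in STOP_CODONS:
            disablers.append(
                Disabler(
                    DisablerType.STOP_LOSS,
                    _exon_of(L - 3, exon_bounds),
                    L - 3,
                    ref_codon=ref_cds[L - 3 : L],
                    obs_codon_or_indel=obs_stop,
                )
            )
    else:
        warnings.append("alignment does not cover the stop codon; stop check skipped")

    # (iv) indels: gap runs in either row
    notes: list[str] = []
    col = 0
    ncol = len(ref_aln)
    while col < ncol:
        if ref_aln[col] == "-" or hom_aln[col] == "-":
            row = "ref" if ref_aln[col] == "-" else "hom"
            j = col
            while j < ncol and (ref_aln[j] == "-" if row == "ref" else hom_aln[j] == "-"):
                j += 1
            run = j - col
            if row == "ref":
                # insertion in homolog between ref bases; affected codon is the
                # one containing the next reference base
                nxt = next((ref_off_at_col[c] for c in range(j, ncol) if ref_off_at_col[c] >= 0), L)
                off = (min(nxt, L - 1) // 3) * 3
                signed = run
                obs = "+" + hom_aln[col:j]
            else:
                first_del = next(ref_off_at_col[c] for c in range(col, j) if ref_off_at_col[c] >= 0)
                off = (first_del // 3) * 3
                signed = -run
                obs = "-" + ref_aln[col:j]
            if run % 3 != 0:
                disablers.append(
                    Disabler(
                        DisablerType.FRAMESHIFT_INDEL,
                        _exon_of(off, exon_bounds),
                        off,
                        ref_codon=ref_cds[off : off + 3],
                        obs_codon_or_indel=obs,
                        indel_len=signed,
                    )
                )
            else:
                notes.append(f"frame-preserving indel of {signed:+d} nt at offset {off}")
            col = j
        else:
            col += 1

    # (iii)+(v) premature stops, frame tracked through upstream indels.
    # Reading starts at the homolog base aligned to reference offset ref_start
    # (or the first homolog base if leading columns are homolog-only).
    anchor = next(
        (hom_idx_at_col[c] for c in range(ncol) if ref_off_at_col[c] == ref_start and hom_idx_at_col[c] >= 0),
        None,
    )
    if anchor is None:
        anchor = min(
            (h for h, (ro, ins) in ref_at_hom.items() if not ins and ro >= ref_start),
            default=0,
        )
    for k in range(0, (len(hom_seq) - anchor) // 3):
        hpos = anchor + 3 * k
        codon = hom_seq[hpos : hpos + 3]
        if codon not in STOP_CODONS:
            continue
        ref_off, inserted = ref_at_hom[hpos]
        if ref_off >= L - 3:
            continue  # terminal stop position: handled by the stop-codon check
        net_frame = (3 * k + ref_start - ref_off) % 3
        if net_frame == 0 and not inserted:
            ref_codon = ref_cds[ref_off : ref_off + 3]
            if ref_codon in STOP_CODONS:
                continue
            disablers.append(
                Disabler(
                    DisablerType.PREMATURE_STOP_SUBSTITUTION,
                    _exon_of(ref_off, exon_bounds),
                    ref_off,
                    ref_codon=ref_codon,
                    obs_codon_or_indel=codon,
                )
            )
        else:
            disablers.append(
                Disabler(
                    DisablerType.PREMATURE_STOP_FRAMESHIFT,
                    _exon_of(ref_off, exon_bounds),
                    ref_off,
                    ref_codon=ref_cds[ref_off : ref_off + 3],
                    obs_codon_or_indel=codon,
                    note="stop in shifted frame",
                )
            )

    order = {t: i for i, t in enumerate(DisablerType)}
    disablers.sort(key=lambda d: (d.ref_nt_offset, order[d.type]))
    return DisablerReport(
        orf_id=orf_id,
        disablers=disablers,
        is_coding=not disablers,
        translation=translate(hom_seq[anchor:]),
        alignment=AlignmentPair(ref_aln, hom_aln, alignment.score),
        exon_bounds=list(exon_bounds),
        warnings=warnings + [f"note: {n}" for n in notes],
    )


def scan_orf(
    ref_cds: str,
    putative_orf,
    exon_ref_lengths: Sequence[int] | None = None,
    orf_id: str | None = None,
) -> DisablerReport:
    """Scan a reconstructed putative ORF against the reference spliced CDS.

    For incomplete ORFs ``exon_ref_lengths`` (reference exon lengths in
    transcription order) is required to place the alignment in CDS
    coordinates; only the first contiguous run of found exons is scanned and
    a warning records the truncation.
    """
    if putative_orf.complete:
        # normalize indel placement within each exon alignment before
        # concatenation so gaps cannot drift across exon junctions
        ref_parts, hom_parts, bounds = [], [], []
        acc = 0
        for m in putative_orf.exon_maps:
            norm = left_align_gaps(collapse_gap_pairs(m.alignment))
            bounds.append(acc)
            ref_parts.append(norm.ref_aln)
            hom_parts.append(norm.hom_aln)
            acc += len(norm.ref_seq)
        aln = AlignmentPair("".join(ref_parts), "".join(hom_parts))
        return scan_disablers(
            ref_cds,
            aln,
            exon_bounds=bounds,
            orf_id=orf_id or putative_orf.orf_id,
            normalize=False,
        )
    if exon_ref_lengths is None:
        raise ValueError("exon_ref_lengths is required to scan an incomplete ORF")
    full_bounds = [0]
    for ln in exon_ref_lengths[:-1]:
        full_bounds.append(full_bounds[-1] + ln)
    found = [m.exon_index for m in putative_orf.exon_maps if m.found]
    if not found:
        raise ValueError("no exon of the putative ORF was found in the region")
    first = found[0]
    run = [first]
    for i in found[1:]:
        if i == run[-1] + 1:
            run.append(i)
        else:
            break
    ref_parts, hom_parts = [], []
    for i in run:
        norm = left_align_gaps(collapse_gap_pairs(putative_orf.exon_maps[i].alignment))
        ref_parts.append(norm.ref_aln)
        hom_parts.append(norm.hom_aln)
    aln = AlignmentPair("".join(ref_parts), "".join(hom_parts))
    report = scan_disablers(
        ref_cds,
        aln,
        exon_bounds=full_bounds,
        orf_id=orf_id or putative_orf.orf_id,
        ref_start=full_bounds[first],
        normalize=False,
    )
    missing = [i for i in range(len(putative_orf.exon_maps)) if i not in run]
    report.warnings.append(
        f"incomplete ORF: exons {missing} not scanned (unfound or non-contiguous)"
    )
    return report


def _global_align(seq_a: str, seq_b: str) -> AlignmentPair:
    from orfdecay.orf_reconstruction import AlignParams, _make_aligner

    aligner = _make_aligner(AlignParams(), semi_global=False)
    aln = aligner.align(seq_b, seq_a)[0]
    return AlignmentPair(ref_aln=str(aln[1]), hom_aln=str(aln[0]), score=float(aln.score))


def scan_enablers(
    noncoding_ref_orf: str,
    coding_derived_orf: str,
    exon_bounds: Sequence[int] = (),
) -> EnablerReport:
    """Report each change in the derived coding sequence that removes a disabler
    present in the non-coding reference.

    The derived sequence supplies the coding frame; every disabler found in
    the non-coding sequence relative to it corresponds to one enabler on the
    branch leading to the derived (coding) state.
    """
    aln = _global_align(coding_derived_orf.upper(), noncoding_ref_orf.upper())
    report = scan_disablers(
        coding_derived_orf.upper(), aln, exon_bounds=exon_bounds, orf_id="enabler-scan"
    )
    enablers: list[tuple[Disabler, str]] = []
    for d in report.disablers:
        coding_state = coding_derived_orf[d.ref_nt_offset : d.ref_nt_offset + 3].upper()
        if d.type is DisablerType.START_LOSS:
            desc = f"substitution(s) restoring the ATG start codon ({d.obs_codon_or_indel} -> ATG)"
        elif d.type is DisablerType.STOP_LOSS:
            desc = f"substitution(s) restoring a stop codon ({d.obs_codon_or_indel} -> {coding_state})"
        elif d.type is DisablerType.PREMATURE_STOP_SUBSTITUTION:
            desc = (
                f"substitution {d.obs_codon_or_indel} -> {coding_state} at offset "
                f"{d.ref_nt_offset} removing a premature stop"
            )
        elif d.type is DisablerType.FRAMESHIFT_INDEL:
            kind = "deletion" if d.indel_len > 0 else "insertion"
            desc = (
                f"{kind} of {abs(d.indel_len)} nt near offset {d.ref_nt_offset} "
                "restoring the reading frame"
            )
        else:
            desc = (
                f"frame restoration upstream removes the shifted-frame stop at offset "
                f"{d.ref_nt_offset}"
            )
        enablers.append((d, desc))
    return EnablerReport(enablers=enablers)


def render_alignment(report: DisablerReport, width: int = 60) -> str:
    """Fixed-width codon-aligned text rendering of the scanned alignment.

    Four rows per block — reference translation, reference nucleotides,
    homolog nucleotides, homolog (artificial) translation — plus a marker row
    flagging each disabler column with the initial of its type. Output is
    deterministic.
    """
    if report.alignment is None:
        raise ValueError("report carries no alignment to render")
    ref_aln, hom_aln = report.alignment.ref_aln, report.alignment.hom_aln
    ncol = len(ref_aln)

    # column of each reference offset
    col_of_ref: dict[int, int] = {}
    r = -1
    for col, a in enumerate(ref_aln):
        if a != "-":
            r += 1
            col_of_ref[r] = col
    # translation rows: amino acid at the column of each codon's first base
    ref_seq = ref_aln.replace("-", "")
    hom_seq = hom_aln.replace("-", "")
    ref_tr_row = [" "] * ncol
    for k, aa in enumerate(translate(ref_seq)):
        ref_tr_row[col_of_ref[3 * k]] = aa
    col_of_hom: dict[int, int] = {}
    h = -1
    for col, b in enumerate(hom_aln):
        if b != "-":
            h += 1
            col_of_hom[h] = col
    hom_tr_row = [" "] * ncol
    for k, aa in enumerate(translate(hom_seq)):
        hom_tr_row[col_of_hom[3 * k]] = aa
    mark_row = [" "] * ncol
    for d in report.disablers:
        col = col_of_ref.get(d.ref_nt_offset)
        if col is not None:
            mark_row[col] = d.type.value[0]  # S/P/F initials

    exon_starts = {b: i for i, b in enumerate(report.exon_bounds)}
    lines = [f"# orf={report.orf_id} is_coding={report.is_coding} "
             f"offsets: 0-based in reference spliced CDS, start codon = 0"]
    for block in range(0, ncol, width):
        sl = slice(block, min(block + width, ncol))
        ref_off_here = [i for i, c in col_of_ref.items() if sl.start <= c < sl.stop]
        exon_here = sorted({exon_starts[b] for b in exon_starts if b in ref_off_here})
        tag = f" exon {','.join(str(e + 1) for e in exon_here)} starts" if exon_here else ""
        lines.append(f"@ cols {sl.start}-{sl.stop - 1}{tag}")
        lines.append("refaa " + "".join(ref_tr_row[sl]))
        lines.append("refnt " + ref_aln[sl])
        lines.append("homnt " + hom_aln[sl])
        lines.append("homaa " + "".join(hom_tr_row[sl]))
        marks = "".join(mark_row[sl])
        if marks.strip():
            lines.append("disab " + marks)
    return "\n".join(lines) + "\n"
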