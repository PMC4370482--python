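"""Sequence, interval, gene-model and homology-hit data types plus file I/O.

All internal coordinates are 0-based half-open; the 1-based inclusive
conventions of GFF3 and tabular homology-hit files are converted exactly
once, at the file boundary. IUPAC ambiguity codes are preserved (never
collapsed to N) so that downstream disabler calls can distinguish
"unknown base" from "mismatch".
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_letters
from Bio.Seq import Seq

IUPAC_DNA = set(ambiguous_dna_letters.upper())  # ACGT + ambiguity codes (incl. N)


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


@dataclass
class SeqRecord:
    """A named nucleotide sequence over the IUPAC DNA alphabet."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - IUPAC_DNA
        if bad:
            raise FormatError(f"record {self.id!r}: non-IUPAC characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open stranded interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must be > start, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.seq_id == other.seq_id and self.start < other.end and other.start < self.end


@dataclass
class GeneModel:
    """A reference CDS as ordered, stranded exons on one genomic sequence.

    Exons are stored in transcription order (reverse-coordinate order for the
    minus strand) so that concatenating their extracted sequences yields the
    spliced CDS directly, already on the coding strand.
    """

    gene_id: str
    exons: list[GenomicInterval]
    cds_phase: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        seq_ids = {e.seq_id for e in self.exons}
        if len(seq_ids) > 1:
            raise FormatError(f"gene {self.gene_id}: exons span multiple sequences {sorted(seq_ids)}")
        strands = {e.strand for e in self.exons}
        if len(strands) > 1:
            raise FormatError(f"gene {self.gene_id}: exons on both strands")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.overlaps(b):
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        if sum(len(e) for e in self.exons) < 3:
            raise ValueError(f"gene {self.gene_id}: CDS shorter than one codon")
        if not self.cds_phase:
            self.cds_phase = self._derive_phases()
        if any(p not in (0, 1, 2) for p in self.cds_phase):
            raise ValueError("cds_phase entries must be in {0,1,2}")

    def _derive_phases(self) -> list[int]:
        phases, acc = [], 0
        for e in self.exons:
            phases.append((3 - acc % 3) % 3)
            acc += len(e)
        return phases

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def seq_id(self) -> str:
        return self.exons[0].seq_id

    def spliced_cds(self, genome: dict[str, SeqRecord] | SeqRecord) -> str:
        """Concatenated exon sequences on the coding strand."""
        if isinstance(genome, SeqRecord):
            rec = genome
        else:
            rec = genome[self.seq_id]
        return "".join(extract_interval(rec, e) for e in self.exons)

    def cds_offset_to_genomic(self, offset: int) -> tuple[int, int]:
        """Map a 0-based spliced-CDS offset to (exon_index, genomic position)."""
        acc = 0
        for i, e in enumerate(self.exons):
            if offset < acc + len(e):
                within = offset - acc
                if e.strand == "+":
                    return i, e.start + within
                return i, e.end - 1 - within
            acc += len(e)
        raise IndexError(f"CDS offset {offset} beyond spliced length {acc}")

    def exon_index_of_offset(self, offset: int) -> int:
        return self.cds_offset_to_genomic(offset)[0]


@dataclass
class HitRecord:
    """One tabular homology hit (the standard 12-column dialect), 0-based half-open."""

    query_id: str
    subject_id: str
    pct_identity: float
    align_length: int
    e_value: float
    bit_score: float
    query: GenomicInterval
    subject: GenomicInterval

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity out of range: {self.pct_identity}")
        if self.e_value < 0:
            raise ValueError(f"negative E-value: {self.e_value}")

    @property
    def strand(self) -> str:
        return self.subject.strand


@dataclass
class AlignmentPair:
    """A gapped pairwise alignment: reference row and homolog row."""

    ref_aln: str
    hom_aln: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if len(self.ref_aln) != len(self.hom_aln):
            raise ValueError("alignment rows differ in length")
        for i, (a, b) in enumerate(zip(self.ref_aln, self.hom_aln)):
            if a == "-" and b == "-":
                raise ValueError(f"column {i}: gap in both rows")

    def __len__(self) -> int:
        return len(self.ref_aln)

    @property
    def ref_seq(self) -> str:
        return self.ref_aln.replace("-", "")

    @property
    def hom_seq(self) -> str:
        return self.hom_aln.replace("-", "")

    def pct_identity(self) -> float:
        matches = sum(
            1 for a, b in zip(self.ref_aln, self.hom_aln) if a == b and a != "-"
        )
        return 100.0 * matches / len(self.ref_aln) if self.ref_aln else 0.0


# ---------------------------------------------------------------------------
# readers / writers


def read_fasta(path: str | Path | io.TextIOBase) -> list[SeqRecord]:
    """Read a multi-FASTA file into validated records.

    Sequences are uppercased and U is mapped to T; record ids must be unique
    within the file.
    """
    if isinstance(path, (str, Path)):
        handle = open(path)
        close = True
    else:
        handle, close = path, False
    records: list[SeqRecord] = []
    seen: set[str] = set()
    try:
        rec_id = None
        desc = ""
        chunks: list[str] = []
        lineno = 0

        def flush() -> None:
            if rec_id is None:
                return
            seq = "".join(chunks).upper().replace("U", "T")
            if not seq:
                raise FormatError(f"line {header_line}: record {rec_id!r} has empty sequence")
            if rec_id in seen:
                raise FormatError(f"line {header_line}: duplicate record id {rec_id!r}")
            seen.add(rec_id)
            records.append(SeqRecord(id=rec_id, seq=seq, description=desc))

        header_line = 0
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                if not parts:
                    raise FormatError(f"line {lineno}: empty FASTA header")
                rec_id = parts[0]
                desc = parts[1] if len(parts) > 1 else ""
                chunks = []
                header_line = lineno
            else:
                if rec_id is None:
                    raise FormatError(f"line {lineno}: sequence before first header")
                chunks.append(line.strip())
        flush()
    finally:
        if close:
            handle.close()
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    """Write records in input order, wrapped at `width` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


_GFF_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def _gff_attributes(raw: str) -> dict[str, str]:
    out = {}
    for part in raw.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff_exons(path: str | Path, gene_id: str) -> GeneModel:
    """Build a GeneModel from the exon/CDS features of one gene in a GFF3 file.

    CDS features are preferred; plain exon features are used when the file has
    no CDS lines for the gene. Exons are returned in transcription order.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", names=_GFF_COLS, dtype=str, keep_default_na=False
    )
    if df.empty:
        raise FormatError(f"{path}: no GFF3 feature lines")
    feats: list[tuple[str, GenomicInterval, int]] = []
    for _, row in df.iterrows():
        if row["type"] not in ("exon", "CDS"):
            continue
        attrs = _gff_attributes(row["attributes"])
        owner = attrs.get("gene_id") or attrs.get("Parent") or attrs.get("ID", "")
        if gene_id not in {owner, attrs.get("gene_id", ""), attrs.get("Parent", "")}:
            continue
        strand = row["strand"] if row["strand"] in ("+", "-") else "+"
        iv = GenomicInterval(row["seqid"], int(row["start"]) - 1, int(row["end"]), strand)
        phase = int(row["phase"]) if row["phase"] in ("0", "1", "2") else 0
        feats.append((row["type"], iv, phase))
    if not feats:
        raise KeyError(f"gene {gene_id!r} not found in {path}")
    kinds = {k for k, _, _ in feats}
    use = "CDS" if "CDS" in kinds else "exon"
    chosen = [(iv, ph) for k, iv, ph in feats if k == use]
    seq_ids = {iv.seq_id for iv, _ in chosen}
    if len(seq_ids) > 1:
        raise FormatError(f"gene {gene_id}: features on multiple sequences {sorted(seq_ids)}")
    minus = chosen[0][0].strand == "-"
    chosen.sort(key=lambda t: t[0].start, reverse=minus)
    return GeneModel(gene_id, [iv for iv, _ in chosen], [ph for _, ph in chosen])


def read_hits_tabular(path: str | Path) -> list[HitRecord]:
    """Read a 12-column tabular homology-hit file.

    File coordinates are 1-based inclusive; they are converted to 0-based
    half-open. Subject strand is inferred from coordinate order (start > end
    means minus strand).
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            (qid, sid, pident, length, _mism, _gaps, qs, qe, ss, se, ev, bits) = cols
            qs_i, qe_i, ss_i, se_i = int(qs), int(qe), int(ss), int(se)
            q_iv = GenomicInterval(qid, min(qs_i, qe_i) - 1, max(qs_i, qe_i), "+")
            s_strand = "+" if ss_i <= se_i else "-"
            s_iv = GenomicInterval(sid, min(ss_i, se_i) - 1, max(ss_i, se_i), s_strand)
            hits.append(
                HitRecord(
                    query_id=qid,
                    subject_id=sid,
                    pct_identity=float(pident),
                    align_length=int(length),
                    e_value=float(ev),
                    bit_score=float(bits),
                    query=q_iv,
                    subject=s_iv,
                )
            )
    return hits


def write_hits_tabular(hits: Sequence[HitRecord], path: str | Path) -> None:
    """Write hits back to the 12-column dialect (1-based inclusive, strand by coordinate order)."""
    with open(path, "w") as fh:
        for h in hits:
            if h.subject.strand == "+":
                ss, se = h.subject.start + 1, h.subject.end
            else:
                ss, se = h.subject.end, h.subject.start + 1
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.subject_id, h.pct_identity, h.align_length,
                        0, 0, h.query.start + 1, h.query.end, ss, se,
                        h.e_value, h.bit_score,
                    )
                )
                + "\n"
            )


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path, names: Iterable[str] | None = None) -> None:
    names = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"frag{i}"
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# sequence primitives


def revcomp(seq: str) -> str:
    """Reverse complement with IUPAC ambiguity codes complemented properly."""
    return str(Seq(seq).reverse_complement())


def extract_interval(record: SeqRecord, interval: GenomicInterval) -> str:
    """Substring [start, end) of the record, reverse-complemented for minus strand."""
    if interval.end > len(record.seq):
        raise IndexError(
            f"interval [{interval.start},{interval.end}) exceeds {record.id} length {len(record.seq)}"
        )
    sub = record.seq[interval.start : interval.end]
    return revcomp(sub) if interval.strand == "-" else sub
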