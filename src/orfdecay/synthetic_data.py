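"""Synthetic evolutionary scenarios with machine-readable ground truth.

The generator builds a multi-exon coding locus (ATG start, clean reading
frame, terminal stop), disables it on a designated branch by planting
disablers (minimal edits: one substitution for start/stop/premature-stop
losses, one short indel for frameshifts), evolves it along a species tree
under a K2P substitution process with optional geometric-length indels,
copies it between genomic compartments (transposition, optionally inverted)
and into tandem duplicates, and can re-enable coding on one branch by
reverting every disabler and enforcing ORF integrity thereafter (a hard
rejection rule standing in for purifying selection).

Every planted edit is tracked through subsequent evolution at base-level
resolution, so the emitted truth table states, per leaf and compartment,
which disablers a correct scanner should recover and whether later neutral
evolution left them intact. Frame-shifting plants also emit their
deterministic consequences (stop codons readable in the shifted frame) as
derived truth rows, since a scanner necessarily reports those too.

Indel conventions match the scanner: placements are left-normalized within
their exon, and the reported offset is the first base of the affected codon
in the reference spliced CDS.
"""

from __future__ import annotations

import copy as _copy
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from orfdecay.core_io import GeneModel, GenomicInterval, SeqRecord, revcomp, write_fasta
from orfdecay.disabler_scan import STOP_CODONS, DisablerType

_BASES = "ACGT"
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in STOP_CODONS
]


@dataclass
class PlantSpec:
    branch: str
    type: DisablerType
    exon: int | None = None
    offset: int | None = None  # reference spliced-CDS offset; None = choose randomly
    indel_len: int = -2  # signed (+ insert, - delete); frameshifts only


@dataclass
class TranspositionEvent:
    branch: str
    source: str
    dest: str
    inverted: bool = False


@dataclass
class DuplicationEvent:
    branch: str
    compartment: str
    copies: int = 2


@dataclass
class SimConfig:
    seed: int
    tree: str
    kappa: float = 2.0
    indel_rate: float = 0.0  # events per site per unit branch length
    indel_len_p: float = 0.5  # geometric(p), truncated
    indel_len_max: int = 6
    exon_lengths: tuple[int, ...] = (90, 121, 83, 63)
    intron_lengths: tuple[int, ...] = (150, 140, 130)
    flank_length: int = 200
    plants: list[PlantSpec] = field(default_factory=list)
    enable_branch: str | None = None
    enable_compartment: str = "chrY"
    transpositions: list[TranspositionEvent] = field(default_factory=list)
    duplications: list[DuplicationEvent] = field(default_factory=list)
    root_compartment: str = "autosome"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if sum(self.exon_lengths) % 3 != 0:
            raise ValueError("total exon length must be a multiple of 3")
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need one intron fewer than exons")


@dataclass
class PlantedRecord:
    """One planted disabler (or a derived consequence row), tracked through evolution."""

    dtype: DisablerType
    exon: int
    ref_nt_offset: int
    positions: list[int]  # current genomic positions of the edited/diagnostic bases
    kind: str  # sub | ins | del | none (derived rows)
    orig: str = ""
    new: str = ""
    indel_len: int = 0
    derived: bool = False
    destroyed: bool = False
    reverted: bool = False
    origin_branch: str = ""


@dataclass
class EvolvedIndel:
    gpos: int
    length: int  # signed
    content: str  # inserted bases, or the deleted bases
    in_exon: bool


@dataclass
class LocusCopy:
    seq: str  # stored in coding orientation; `inverted` applies at emission
    seg_kinds: list[str]
    seg_lengths: list[int]
    ref_map: np.ndarray  # original locus position -> current position (-1 deleted)
    inverted: bool = False
    enabled: bool = False
    copy_id: str = "c0"
    planted: list[PlantedRecord] = field(default_factory=list)
    evolved_indels: list[EvolvedIndel] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def seg_starts(self) -> list[int]:
        starts, acc = [], 0
        for ln in self.seg_lengths:
            starts.append(acc)
            acc += ln
        return starts

    def exon_ranges(self) -> list[tuple[int, int]]:
        out = []
        for kind, start, ln in zip(
            self.seg_kinds, self.seg_starts(), self.seg_lengths
        ):
            if kind == "exon":
                out.append((start, start + ln))
        return out

    def cds(self) -> str:
        return "".join(self.seq[s:e] for s, e in self.exon_ranges())


# ---------------------------------------------------------------------------
# ancestral locus


def make_ancestral_locus(config: SimConfig, rng: np.random.Generator | None = None) -> tuple[GeneModel, SeqRecord, LocusCopy]:
    """Random coding locus: ATG + sense codons + stop, split across exons with introns."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_codons = sum(config.exon_lengths) // 3
    body = [ _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2) ]
    cds = "ATG" + "".join(body) + ["TAA", "TAG", "TGA"][int(rng.integers(0, 3))]
    seg_kinds: list[str] = ["flank"]
    seg_seqs: list[str] = ["".join(_BASES[i] for i in rng.integers(0, 4, size=config.flank_length))]
    pos = 0
    for k, ex_len in enumerate(config.exon_lengths):
        seg_kinds.append("exon")
        seg_seqs.append(cds[pos : pos + ex_len])
        pos += ex_len
        if k < len(config.intron_lengths):
            seg_kinds.append("intron")
            seg_seqs.append(
                "".join(_BASES[i] for i in rng.integers(0, 4, size=config.intron_lengths[k]))
            )
    seg_kinds.append("flank")
    seg_seqs.append("".join(_BASES[i] for i in rng.integers(0, 4, size=config.flank_length)))
    seq = "".join(seg_seqs)
    seg_lengths = [len(s) for s in seg_seqs]
    copy = LocusCopy(
        seq=seq,
        seg_kinds=seg_kinds,
        seg_lengths=seg_lengths,
        ref_map=np.arange(len(seq)),
    )
    exons = []
    acc = 0
    for kind, ln in zip(seg_kinds, seg_lengths):
        if kind == "exon":
            exons.append(GenomicInterval("locus", acc, acc + ln, "+"))
        acc += ln
    model = GeneModel("simgene", exons)
    orig_cds_map: dict[int, int] = {}
    ci = 0
    for e in exons:
        for g in range(e.start, e.end):
            orig_cds_map[g] = ci
            ci += 1
    copy._orig_cds_map = orig_cds_map  # original genomic pos -> ref CDS offset
    record = SeqRecord(id="locus", seq=seq, description="ancestral coding locus")
    return model, record, copy


# ---------------------------------------------------------------------------
# coordinate bookkeeping


def _exon_bounds(config: SimConfig) -> list[int]:
    bounds, acc = [], 0
    for ln in config.exon_lengths:
        bounds.append(acc)
        acc += ln
    return bounds


def _exon_of_offset(offset: int, bounds: Sequence[int]) -> int:
    idx = 0
    for i, b in enumerate(bounds):
        if offset >= b:
            idx = i
    return idx


def _cds_to_genomic(copy: LocusCopy, cds_offset: int) -> int:
    acc = 0
    for kind, start, ln in zip(copy.seg_kinds, copy.seg_starts(), copy.seg_lengths):
        if kind != "exon":
            continue
        if cds_offset < acc + ln:
            return start + (cds_offset - acc)
        acc += ln
    raise IndexError(f"CDS offset {cds_offset} beyond spliced length {acc}")


def _genomic_to_cds(copy: LocusCopy, g: int) -> int | None:
    acc = 0
    for kind, start, ln in zip(copy.seg_kinds, copy.seg_starts(), copy.seg_lengths):
        if kind == "exon":
            if start <= g < start + ln:
                return acc + (g - start)
            acc += ln
    return None


def _seg_of(copy: LocusCopy, g: int) -> int:
    for i, (start, ln) in enumerate(zip(copy.seg_starts(), copy.seg_lengths)):
        if start <= g < start + ln:
            return i
    raise IndexError(f"position {g} outside locus")


def _apply_insertion(copy: LocusCopy, g: int, bases: str) -> None:
    copy.seq = copy.seq[:g] + bases + copy.seq[g:]
    copy.seg_lengths[_seg_of(copy, g)] += len(bases)
    ln = len(bases)
    copy.ref_map = np.where(copy.ref_map >= g, copy.ref_map + ln, copy.ref_map)
    for rec in copy.planted:
        rec.positions = [p + ln if p >= g else p for p in rec.positions]
    for ev in copy.evolved_indels:
        if ev.gpos >= g:
            ev.gpos += ln


def _apply_deletion(copy: LocusCopy, g: int, length: int) -> str:
    deleted = copy.seq[g : g + length]
    seg = _seg_of(copy, g)
    copy.seq = copy.seq[:g] + copy.seq[g + length :]
    copy.seg_lengths[seg] -= length
    rm = copy.ref_map
    copy.ref_map = np.where(
        (rm >= g) & (rm < g + length), -1, np.where(rm >= g + length, rm - length, rm)
    )
    for rec in copy.planted:
        if any(g <= p < g + length for p in rec.positions):
            rec.destroyed = True
        rec.positions = [p - length if p >= g + length else p for p in rec.positions]
    for ev in copy.evolved_indels:
        if ev.gpos >= g + length:
            ev.gpos -= length
    return deleted


def _substitute(copy: LocusCopy, g: int, base: str) -> None:
    copy.seq = copy.seq[:g] + base + copy.seq[g + 1 :]


# ---------------------------------------------------------------------------
# disabler planting


def _single_sub_stops(codon: str, rng: np.random.Generator) -> tuple[int, str] | None:
    """A (position, base) substitution turning codon into a stop, or None."""
    options = []
    for stop in sorted(STOP_CODONS):
        diff = [i for i in range(3) if codon[i] != stop[i]]
        if len(diff) == 1:
            options.append((diff[0], stop[diff[0]]))
    if not options:
        return None
    return options[int(rng.integers(0, len(options)))]


def disable_locus(
    copy: LocusCopy,
    plant_spec: Sequence[PlantSpec],
    config: SimConfig,
    rng: np.random.Generator,
    branch: str = "root",
) -> list[PlantedRecord]:
    """Apply planted disablers by minimal edits and record exact truth.

    Frame-shifting plants additionally produce derived truth rows for every
    stop codon readable in the shifted frame downstream (a correct scanner
    reports those as well). Raises on offset collisions.
    """
    bounds = _exon_bounds(config)
    L = sum(config.exon_lengths)
    taken: set[int] = set()  # claimed codon-start offsets
    new_records: list[PlantedRecord] = []
    for spec in plant_spec:
        cds = copy.cds()
        if spec.type in (
            DisablerType.START_LOSS,
            DisablerType.STOP_LOSS,
            DisablerType.PREMATURE_STOP_SUBSTITUTION,
        ):
            if spec.type is DisablerType.START_LOSS:
                off = 0
                pos_in_codon = int(rng.integers(0, 3))
                cur = cds[0:3]
                while True:
                    base = _BASES[int(rng.integers(0, 4))]
                    cand = cur[:pos_in_codon] + base + cur[pos_in_codon + 1 :]
                    if cand != cur and cand != "ATG" and cand not in STOP_CODONS:
                        break
                new_codon = cand
            elif spec.type is DisablerType.STOP_LOSS:
                off = L - 3
                cur = cds[off : off + 3]
                while True:
                    pos_in_codon = int(rng.integers(0, 3))
                    base = _BASES[int(rng.integers(0, 4))]
                    cand = cur[:pos_in_codon] + base + cur[pos_in_codon + 1 :]
                    if cand != cur and cand not in STOP_CODONS:
                        break
                new_codon = cand
            else:
                off = spec.offset
                if off is None:
                    candidates = [
                        3 * k
                        for k in range(1, L // 3 - 1)
                        if (spec.exon is None or _exon_of_offset(3 * k, bounds) == spec.exon)
                        and 3 * k not in taken
                        and _single_sub_stops(cds[3 * k : 3 * k + 3], rng) is not None
                    ]
                    if not candidates:
                        raise ValueError("no plantable codon for premature stop")
                    off = int(candidates[int(rng.integers(0, len(candidates)))])
                if off % 3 != 0 or not 3 <= off <= L - 6:
                    raise ValueError(f"invalid premature-stop offset {off}")
                cur = cds[off : off + 3]
                hit = _single_sub_stops(cur, rng)
                if hit is None:
                    # minimal edit: closest stop by Hamming distance
                    stop = min(
                        sorted(STOP_CODONS),
                        key=lambda s: sum(a != b for a, b in zip(s, cur)),
                    )
                    new_codon = stop
                else:
                    new_codon = cur[: hit[0]] + hit[1] + cur[hit[0] + 1 :]
            if off in taken:
                raise ValueError(f"plant collision at offset {off}")
            taken.add(off)
            positions = [_cds_to_genomic(copy, off + i) for i in range(3)]
            for p, b in zip(positions, new_codon):
                _substitute(copy, p, b)
            rec = PlantedRecord(
                dtype=spec.type,
                exon=_exon_of_offset(off, bounds),
                ref_nt_offset=off,
                positions=positions,
                kind="sub",
                orig=cds[off : off + 3],
                new=new_codon,
                origin_branch=branch,
            )
            copy.planted.append(rec)
            new_records.append(rec)
        elif spec.type is DisablerType.FRAMESHIFT_INDEL:
            ln = spec.indel_len
            if ln == 0 or abs(ln) % 3 == 0:
                raise ValueError("frameshift plant length must be non-multiple of 3")
            off = spec.offset
            if off is None:
                exon = spec.exon if spec.exon is not None else int(rng.integers(0, len(bounds)))
                lo = bounds[exon] + 3
                hi = bounds[exon] + config.exon_lengths[exon] - abs(ln) - 3
                off = int(rng.integers(lo, hi))
            exon = _exon_of_offset(off, bounds)
            exon_start_off = bounds[exon]
            cds = copy.cds()
            if ln < 0:
                length = -ln
                if _exon_of_offset(off + length - 1, bounds) != exon:
                    raise ValueError("planted deletion must stay within one exon")
                while off > exon_start_off and cds[off - 1] == cds[off + length - 1]:
                    off -= 1  # left-normalize the gap placement
                truth_off = (off // 3) * 3
                g = _cds_to_genomic(copy, off)
                deleted = _apply_deletion(copy, g, length)
                rec = PlantedRecord(
                    dtype=spec.type,
                    exon=exon,
                    ref_nt_offset=truth_off,
                    positions=[g],
                    kind="del",
                    orig=deleted,
                    indel_len=-length,
                    origin_branch=branch,
                )
            else:
                length = ln
                bases = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
                # left-normalize: shifting an insertion left one step rotates it
                # (keep >= 1 exon base before the insertion as an alignment anchor)
                while off > exon_start_off + 1 and bases[-1] == cds[off - 1]:
                    bases = cds[off - 1] + bases[:-1]
                    off -= 1
                truth_off = (min(off, L - 1) // 3) * 3
                g = _cds_to_genomic(copy, off)
                _apply_insertion(copy, g, bases)
                rec = PlantedRecord(
                    dtype=spec.type,
                    exon=exon,
                    ref_nt_offset=truth_off,
                    positions=[g + i for i in range(length)],
                    kind="ins",
                    orig="",
                    new=bases,
                    indel_len=length,
                    origin_branch=branch,
                )
            if rec.ref_nt_offset in taken:
                raise ValueError(f"plant collision at offset {rec.ref_nt_offset}")
            taken.add(rec.ref_nt_offset)
            copy.planted.append(rec)
            new_records.append(rec)
        else:
            raise ValueError(f"cannot plant disabler type {spec.type}")
    derived = _derived_stop_rows(copy, config, branch)
    copy.planted.extend(derived)
    new_records.extend(derived)
    copy.provenance.append(f"{branch}: planted {len(new_records)} truth rows")
    return new_records


def _ref_offset_walk(copy: LocusCopy):
    """Yield (cds_index, ref_offset, inserted) for the current spliced CDS.

    The reference offset of an inserted base is that of the preceding
    reference base (matching the scanner's projection convention).
    """
    image = {}  # current genomic pos -> original locus pos
    for orig, cur in enumerate(copy.ref_map):
        if cur >= 0:
            image[int(cur)] = orig
    ref_of_orig = copy._orig_cds_map  # type: ignore[attr-defined]
    cds_index = 0
    last_ref = 0
    for s, e in copy.exon_ranges():
        for g in range(s, e):
            if g in image and image[g] in ref_of_orig:
                ref = ref_of_orig[image[g]]
                last_ref = ref
                yield cds_index, ref, False
            else:
                yield cds_index, last_ref, True
            cds_index += 1


def _derived_stop_rows(copy: LocusCopy, config: SimConfig, branch: str) -> list[PlantedRecord]:
    """Stop codons readable in a shifted frame downstream of planted frameshifts."""
    if not any(r.dtype is DisablerType.FRAMESHIFT_INDEL for r in copy.planted):
        return []
    bounds = _exon_bounds(config)
    L = sum(config.exon_lengths)
    cds = copy.cds()
    walk = list(_ref_offset_walk(copy))
    existing = {(r.dtype, r.ref_nt_offset) for r in copy.planted}
    rows: list[PlantedRecord] = []
    exon_ranges = copy.exon_ranges()

    def genomic_of_cds(ci: int) -> int:
        acc = 0
        for s, e in exon_ranges:
            if ci < acc + (e - s):
                return s + (ci - acc)
            acc += e - s
        raise IndexError(ci)

    for k in range(len(cds) // 3):
        codon = cds[3 * k : 3 * k + 3]
        if codon not in STOP_CODONS:
            continue
        _, ref, inserted = walk[3 * k]
        if ref >= L - 3:
            continue
        net = (3 * k - ref) % 3
        if net == 0 and not inserted:
            dtype = DisablerType.PREMATURE_STOP_SUBSTITUTION
        else:
            dtype = DisablerType.PREMATURE_STOP_FRAMESHIFT
        if (dtype, ref) in existing:
            continue
        rows.append(
            PlantedRecord(
                dtype=dtype,
                exon=_exon_of_offset(ref, bounds),
                ref_nt_offset=ref,
                positions=[genomic_of_cds(3 * k + i) for i in range(3)],
                kind="none",
                orig=codon,
                derived=True,
                origin_branch=branch,
            )
        )
        existing.add((dtype, ref))
    return rows


# ---------------------------------------------------------------------------
# evolution along the tree


def _k2p_step_probs(t: float, kappa: float) -> tuple[float, float, float]:
    """(stay, transition, each-transversion) probabilities after branch length t
    (expected substitutions per site)."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_ti = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1
    return 1.0 - p_ti - 2.0 * p_tv_each, p_ti, p_tv_each


_ENC = {b: i for i, b in enumerate(_BASES)}
_TI_PARTNER = np.array([2, 3, 0, 1])
_TV1 = np.array([1, 0, 1, 0])
_TV2 = np.array([3, 2, 3, 2])


def _mutate_substitutions(copy: LocusCopy, t: float, kappa: float, rng: np.random.Generator) -> None:
    if t <= 0:
        return
    arr = np.array([_ENC[b] for b in copy.seq], dtype=np.int8)
    p_stay, p_ti, p_tv = _k2p_step_probs(t, kappa)
    u = rng.random(len(arr))
    out = arr.copy()
    ti_mask = (u >= p_stay) & (u < p_stay + p_ti)
    tv1_mask = (u >= p_stay + p_ti) & (u < p_stay + p_ti + p_tv)
    tv2_mask = u >= p_stay + p_ti + p_tv
    out[ti_mask] = _TI_PARTNER[arr[ti_mask]]
    out[tv1_mask] = _TV1[arr[tv1_mask]]
    out[tv2_mask] = _TV2[arr[tv2_mask]]
    if copy.enabled:
        snapshot = copy.seq
        copy.seq = "".join(_BASES[i] for i in out)
        _repair_coding(copy, snapshot)
    else:
        copy.seq = "".join(_BASES[i] for i in out)


def _repair_coding(copy: LocusCopy, snapshot: str) -> None:
    """Reject substitutions that would re-disable an enabled copy by reverting
    the affected codon to its pre-branch state."""
    for _ in range(4):
        cds = copy.cds()
        exon_ranges = copy.exon_ranges()

        def genomic_of(ci: int) -> int:
            acc = 0
            for s, e in exon_ranges:
                if ci < acc + (e - s):
                    return s + (ci - acc)
                acc += e - s
            raise IndexError(ci)

        bad: list[int] = []
        if cds[:3] != "ATG":
            bad.append(0)
        if cds[-3:] not in STOP_CODONS:
            bad.append(len(cds) - 3)
        for k in range(len(cds) // 3 - 1):
            if cds[3 * k : 3 * k + 3] in STOP_CODONS and 3 * k not in bad:
                bad.append(3 * k)
        if not bad:
            return
        for off in bad:
            for i in range(3):
                g = genomic_of(off + i)
                _substitute(copy, g, snapshot[g])
    raise RuntimeError("could not restore coding integrity")  # pragma: no cover


def _mutate_indels(copy: LocusCopy, t: float, config: SimConfig, rng: np.random.Generator) -> None:
    if config.indel_rate <= 0 or t <= 0:
        return
    n = rng.poisson(config.indel_rate * t * len(copy.seq))
    for _ in range(n):
        seg_idx = int(
            rng.choice(len(copy.seg_lengths), p=np.array(copy.seg_lengths) / len(copy.seq))
        )
        kind = copy.seg_kinds[seg_idx]
        if copy.enabled and kind == "exon":
            continue  # rejected: would disrupt the enforced ORF
        start = copy.seg_starts()[seg_idx]
        seg_len = copy.seg_lengths[seg_idx]
        if seg_len < 8:
            continue
        length = min(int(rng.geometric(config.indel_len_p)), config.indel_len_max)
        if rng.random() < 0.5 and seg_len - length > 6:
            g = start + 1 + int(rng.integers(0, seg_len - length - 2))
            deleted = _apply_deletion(copy, g, length)
            copy.evolved_indels.append(EvolvedIndel(g, -length, deleted, kind == "exon"))
        else:
            g = start + 1 + int(rng.integers(0, seg_len - 2))
            bases = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
            _apply_insertion(copy, g, bases)
            copy.evolved_indels.append(EvolvedIndel(g, length, bases, kind == "exon"))


def _enable_copy(copy: LocusCopy, ref_cds: str, branch: str) -> None:
    """Revert all planted disablers and repair any other disabling state.

    Non-derived plants are inverted edit-by-edit (right-to-left so positions
    stay valid); evolved exon indels are reverted; any remaining internal
    stop or broken start/stop codon is restored to the ancestral codon.
    """
    edits = [r for r in copy.planted if not r.derived and not r.destroyed and not r.reverted]
    for rec in sorted(edits, key=lambda r: -min(r.positions)):
        if rec.kind == "sub":
            for p, b in zip(rec.positions, rec.orig):
                _substitute(copy, p, b)
        elif rec.kind == "ins":
            _apply_deletion(copy, min(rec.positions), len(rec.new))
        elif rec.kind == "del":
            _apply_insertion(copy, rec.positions[0], rec.orig)
    for rec in copy.planted:
        rec.reverted = True
    for ev in sorted([e for e in copy.evolved_indels if e.in_exon], key=lambda e: -e.gpos):
        if ev.length > 0:
            _apply_deletion(copy, ev.gpos, ev.length)
        else:
            _apply_insertion(copy, ev.gpos, ev.content)
    copy.evolved_indels = [e for e in copy.evolved_indels if not e.in_exon]
    # final repair against the ancestral codons (divergence may have created stops)
    cds = copy.cds()
    exon_ranges = copy.exon_ranges()

    def genomic_of(ci: int) -> int:
        acc = 0
        for s, e in exon_ranges:
            if ci < acc + (e - s):
                return s + (ci - acc)
            acc += e - s
        raise IndexError(ci)

    targets = []
    if cds[:3] != "ATG":
        targets.append(0)
    if cds[-3:] not in STOP_CODONS:
        targets.append(len(cds) - 3)
    targets += [3 * k for k in range(len(cds) // 3 - 1) if cds[3 * k : 3 * k + 3] in STOP_CODONS]
    for off in targets:
        for i in range(3):
            _substitute(copy, genomic_of(off + i), ref_cds[off + i])
    copy.enabled = True
    copy.provenance.append(f"{branch}: coding ability enabled ({len(edits)} disablers reverted)")


# ---------------------------------------------------------------------------
# the simulator


@dataclass
class SimResult:
    config: SimConfig
    gene_model: GeneModel
    ancestral_record: SeqRecord
    ref_cds: str
    tree: dendropy.Tree
    leaves: dict[str, dict[str, list[LocusCopy]]]  # taxon -> compartment -> copies
    truth: pd.DataFrame


def _label_tree(tree: dendropy.Tree) -> None:
    i = 0
    for node in tree.preorder_node_iter():
        if node.taxon is not None:
            node.label = node.taxon.label
        elif not node.label:
            node.label = f"node{i}"
        i += 1


def simulate(config: SimConfig) -> SimResult:
    """Run the full scenario and assemble per-leaf copies plus the truth table."""
    rng = np.random.default_rng(config.seed)
    model, record, root_copy = make_ancestral_locus(config, rng)
    # original genomic position -> reference CDS offset (static map used by truth rows)
    orig_cds_map: dict[int, int] = {}
    acc = 0
    for e in model.exons:
        for g in range(e.start, e.end):
            orig_cds_map[g] = acc
            acc += 1
    root_copy._orig_cds_map = orig_cds_map  # type: ignore[attr-defined]

    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    _label_tree(tree)
    labels = {n.label for n in tree.preorder_node_iter()}
    for spec in config.plants:
        if spec.branch not in labels:
            raise ValueError(f"plant branch {spec.branch!r} not in tree")
    for ev in config.transpositions + config.duplications:
        if ev.branch not in labels:
            raise ValueError(f"event branch {ev.branch!r} not in tree")
    if config.enable_branch is not None and config.enable_branch not in labels:
        raise ValueError(f"enable branch {config.enable_branch!r} not in tree")

    ref_cds = root_copy.cds()
    root_label = tree.seed_node.label
    state0 = {config.root_compartment: [root_copy]}
    root_plants = [p for p in config.plants if p.branch == root_label]
    if root_plants:
        disable_locus(root_copy, root_plants, config, rng, branch=root_label)

    leaves: dict[str, dict[str, list[LocusCopy]]] = {}
    states: dict[int, dict[str, list[LocusCopy]]] = {id(tree.seed_node): state0}
    counter = [1]

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            state = states[id(node)]
        else:
            parent_state = states[id(node.parent_node)]
            state = {
                comp: [_clone_copy(c) for c in copies]
                for comp, copies in parent_state.items()
            }
            branch = node.label
            t = node.edge.length or 0.0
            for spec in [p for p in config.plants if p.branch == branch]:
                for copies in state.values():
                    for c in copies:
                        disable_locus(c, [spec], config, rng, branch=branch)
            for ev in [e for e in config.transpositions if e.branch == branch]:
                for src in state.get(ev.source, []):
                    moved = _clone_copy(src)
                    moved.inverted = src.inverted != ev.inverted
                    moved.copy_id = f"c{counter[0]}"
                    counter[0] += 1
                    moved.provenance.append(
                        f"{branch}: transposed {ev.source}->{ev.dest}"
                        + (" (inverted)" if ev.inverted else "")
                    )
                    state.setdefault(ev.dest, []).append(moved)
            for ev in [e for e in config.duplications if e.branch == branch]:
                existing = list(state.get(ev.compartment, []))
                for src in existing:
                    for _ in range(ev.copies - 1):
                        dup = _clone_copy(src)
                        dup.copy_id = f"c{counter[0]}"
                        counter[0] += 1
                        dup.provenance.append(f"{branch}: tandem duplicate of {src.copy_id}")
                        state[ev.compartment].append(dup)
            if config.enable_branch == branch:
                for c in state.get(config.enable_compartment, []):
                    _enable_copy(c, ref_cds, branch)
            for copies in state.values():
                for c in copies:
                    _mutate_substitutions(c, t, config.kappa, rng)
                    _mutate_indels(c, t, config, rng)
            states[id(node)] = state
        if node.is_leaf():
            leaves[node.label] = state

    truth = _truth_table(leaves, ref_cds)
    return SimResult(
        config=config,
        gene_model=model,
        ancestral_record=record,
        ref_cds=ref_cds,
        tree=tree,
        leaves=leaves,
        truth=truth,
    )


def _clone_copy(c: LocusCopy) -> LocusCopy:
    new = _copy.deepcopy(c)
    if hasattr(c, "_orig_cds_map"):
        new._orig_cds_map = c._orig_cds_map  # shared, immutable
    return new


def _net_evolved_frame(copy: LocusCopy, gpos: int) -> int:
    return sum(e.length for e in copy.evolved_indels if e.in_exon and e.gpos < gpos) % 3


def _record_intact(copy: LocusCopy, rec: PlantedRecord) -> bool:
    if rec.destroyed or rec.reverted:
        return False
    try:
        bases = "".join(copy.seq[p] for p in rec.positions)
    except IndexError:  # pragma: no cover - defensive
        return False
    if rec.dtype is DisablerType.START_LOSS:
        return bases != "ATG"
    if rec.dtype is DisablerType.STOP_LOSS:
        return bases not in STOP_CODONS
    if rec.dtype is DisablerType.PREMATURE_STOP_SUBSTITUTION and not rec.derived:
        return bases in STOP_CODONS and _net_evolved_frame(copy, rec.positions[0]) == 0
    if rec.derived:
        # a shifted-frame stop is only readable if no later indel moved the frame
        return bases in STOP_CODONS and _net_evolved_frame(copy, rec.positions[0]) == 0
    if rec.dtype is DisablerType.FRAMESHIFT_INDEL:
        exon_ranges = copy.exon_ranges()
        g = rec.positions[0]
        same_exon = [
            e
            for e in copy.evolved_indels
            if e.in_exon
            and any(s <= e.gpos < t and s <= g < t for s, t in exon_ranges)
        ]
        return not same_exon
    return True  # pragma: no cover


def _truth_table(
    leaves: dict[str, dict[str, list[LocusCopy]]], ref_cds: str
) -> pd.DataFrame:
    rows = []
    for taxon in sorted(leaves):
        for comp in sorted(leaves[taxon]):
            for c in leaves[taxon][comp]:
                for rec in c.planted:
                    rows.append(
                        {
                            "taxon": taxon,
                            "compartment": comp,
                            "copy_id": c.copy_id,
                            "type": rec.dtype.value,
                            "exon": rec.exon,
                            "ref_nt_offset": rec.ref_nt_offset,
                            "origin_branch": rec.origin_branch,
                            "derived": rec.derived,
                            "reverted": rec.reverted,
                            "destroyed": rec.destroyed,
                            "intact": _record_intact(c, rec),
                            "coding": c.enabled,
                            "inverted": c.inverted,
                        }
                    )
    cols = [
        "taxon", "compartment", "copy_id", "type", "exon", "ref_nt_offset",
        "origin_branch", "derived", "reverted", "destroyed", "intact",
        "coding", "inverted",
    ]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# emission


def region_record(taxon: str, comp: str, copies: Sequence[LocusCopy], spacer: str = "") -> tuple[SeqRecord, list[GeneModel]]:
    """One FASTA record per compartment: tandem copies concatenated, inverted
    copies reverse-complemented, plus a gene model per copy."""
    parts: list[str] = []
    models: list[GeneModel] = []
    offset = 0
    rec_id = f"{taxon}|{comp}"
    for c in copies:
        seq = revcomp(c.seq) if c.inverted else c.seq
        exon_ivs = []
        n = len(c.seq)
        for s, e in c.exon_ranges():
            if c.inverted:
                exon_ivs.append(GenomicInterval(rec_id, offset + n - e, offset + n - s, "-"))
            else:
                exon_ivs.append(GenomicInterval(rec_id, offset + s, offset + e, "+"))
        if c.inverted:
            exon_ivs.sort(key=lambda iv: iv.start, reverse=True)
        models.append(GeneModel(f"{taxon}_{comp}_{c.copy_id}", exon_ivs))
        parts.append(seq)
        offset += len(seq) + len(spacer)
        parts.append(spacer)
    joined = "".join(parts[:-1]) if spacer else "".join(parts)
    return SeqRecord(id=rec_id, seq=joined, description=f"{len(copies)} copies"), models


def emit(result: SimResult, outdir: str | Path) -> dict[str, list[str]]:
    """Write per-leaf FASTA/GFF3, the truth TSV and a provenance JSON; returns a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str]] = {"fasta": [], "gff3": [], "tables": []}
    write_fasta([result.ancestral_record], outdir / "ancestral_locus.fa")
    manifest["fasta"].append("ancestral_locus.fa")
    gff_lines = ["##gff-version 3"]
    for taxon in sorted(result.leaves):
        for comp in sorted(result.leaves[taxon]):
            copies = result.leaves[taxon][comp]
            rec, models = region_record(taxon, comp, copies)
            fname = f"{taxon}.{comp}.fa"
            write_fasta([rec], outdir / fname)
            manifest["fasta"].append(fname)
            for model in models:
                for iv in model.exons:
                    gff_lines.append(
                        "\t".join(
                            [
                                rec.id, "orfdecay-sim", "CDS",
                                str(iv.start + 1), str(iv.end), ".", iv.strand, "0",
                                f"ID={model.gene_id};gene_id={model.gene_id}",
                            ]
                        )
                    )
    (outdir / "annotations.gff3").write_text("\n".join(gff_lines) + "\n")
    manifest["gff3"].append("annotations.gff3")
    result.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    manifest["tables"].append("truth.tsv")
    cfg = asdict(result.config)
    cfg["plants"] = [
        {**asdict(p), "type": p.type.value} for p in result.config.plants
    ]
    (outdir / "provenance.json").write_text(json.dumps(cfg, indent=2, default=str) + "\n")
    manifest["tables"].append("provenance.json")
    return manifest


# ---------------------------------------------------------------------------
# gapless alignment simulation (for distance/tree calibration experiments)


def simulate_k2p_alignment(
    tree: str | dendropy.Tree, length: int, kappa: float, seed: int
) -> list[tuple[str, str]]:
    """Evolve a random sequence along a tree under K2P substitutions only.

    Returns (taxon, sequence) pairs for the leaves; useful for calibrating
    distance estimators and topology recovery against known branch lengths.
    """
    rng = np.random.default_rng(seed)
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    _label_tree(tree)
    root_seq = rng.integers(0, 4, size=length).astype(np.int8)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    out: list[tuple[str, str]] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            arr = seqs[id(node)]
        else:
            parent = seqs[id(node.parent_node)]
            t = node.edge.length or 0.0
            arr = parent.copy()
            if t > 0:
                p_stay, p_ti, p_tv = _k2p_step_probs(t, kappa)
                u = rng.random(length)
                ti_mask = (u >= p_stay) & (u < p_stay + p_ti)
                tv1_mask = (u >= p_stay + p_ti) & (u < p_stay + p_ti + p_tv)
                tv2_mask = u >= p_stay + p_ti + p_tv
                arr[ti_mask] = _TI_PARTNER[parent[ti_mask]]
                arr[tv1_mask] = _TV1[parent[tv1_mask]]
                arr[tv2_mask] = _TV2[parent[tv2_mask]]
            seqs[id(node)] = arr
        if node.is_leaf():
            out.append((node.label, "".join(_BASES[i] for i in arr)))
    return out
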