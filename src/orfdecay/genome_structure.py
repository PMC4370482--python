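"""Windowed dot-plot comparison with repeat-segment calling, and anchor-based
gene-order synteny blocks.

A dot at (i, j) means the length-``window`` substring of sequence A starting
at i matches the one of B starting at j with at most ``max_mismatch``
mismatches (Hamming distance). Dots are indexed by 0-based window start.
Reverse-strand dots compare the A window against the reverse complement of
the B window. Runs of collinear off-diagonal dots in a self-comparison are
merged into duplicated-segment calls.

Synteny blocks are maximal runs of anchors (gene names shared between two
ordered gene lists) whose order in the second list is monotone — increasing
for a forward block, decreasing for an inverted one — with all relative
strands agreeing with the block orientation.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from orfdecay.core_io import GenomicInterval, revcomp


@dataclass(frozen=True)
class DotPlotParams:
    window: int
    max_mismatch: int = 0
    both_strands: bool = False

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if not 0 <= self.max_mismatch < self.window:
            raise ValueError("max_mismatch must be in [0, window)")


@dataclass
class DotPlot:
    params: DotPlotParams
    dots: set[tuple[int, int, str]]  # (i, j, strand), window-start coordinates
    len_a: int
    len_b: int
    is_self: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.dots)
        return pd.DataFrame(rows, columns=["i", "j", "strand"])


@dataclass
class RepeatSegment:
    interval_a: GenomicInterval
    interval_b: GenomicInterval
    diagonal_offset: int
    length: int
    strand: str


@dataclass(frozen=True)
class GeneOrderEntry:
    name: str
    strand: str


@dataclass
class SyntenyBlock:
    anchors: list[tuple[str, int, int]]  # (name, index in A, index in B)
    orientation: str  # '+' forward, '-' inverted

    def __len__(self) -> int:
        return len(self.anchors)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _forward_dots(a: np.ndarray, b: np.ndarray, w: int, max_mm: int) -> set[tuple[int, int]]:
    """All (i, j) with Hamming(a[i:i+w], b[j:j+w]) <= max_mm, per diagonal."""
    na, nb = len(a), len(b)
    out: set[tuple[int, int]] = set()
    for off in range(-(na - w), nb - w + 1):
        i0 = max(0, -off)
        j0 = i0 + off
        m = min(na - i0, nb - j0)
        if m < w:
            continue
        neq = (a[i0 : i0 + m] != b[j0 : j0 + m]).astype(np.int32)
        cs = np.concatenate(([0], np.cumsum(neq)))
        wins = cs[w:] - cs[:-w]  # mismatches of each window on this diagonal
        for k in np.nonzero(wins <= max_mm)[0]:
            out.add((i0 + int(k), j0 + int(k)))
    return out


def dotplot(seq_a: str, seq_b: str, params: DotPlotParams) -> DotPlot:
    """Windowed Hamming-distance dot-plot of two sequences.

    Returns an empty plot with a warning when the window exceeds either
    sequence length.
    """
    w = params.window
    is_self = seq_a == seq_b
    if w > min(len(seq_a), len(seq_b)):
        _warnings.warn("window longer than a sequence: empty dot-plot")
        return DotPlot(params, set(), len(seq_a), len(seq_b), is_self)
    a = _encode(seq_a)
    b = _encode(seq_b)
    dots: set[tuple[int, int, str]] = {
        (i, j, "+") for i, j in _forward_dots(a, b, w, params.max_mismatch)
    }
    if params.both_strands:
        brc = _encode(revcomp(seq_b))
        nb = len(seq_b)
        for i, jr in _forward_dots(a, brc, w, params.max_mismatch):
            dots.add((i, nb - w - jr, "-"))
    return DotPlot(params, dots, len(seq_a), len(seq_b), is_self)


def call_repeat_segments(
    self_plot: DotPlot, min_segment: int, gap_tolerance: int = 0
) -> list[RepeatSegment]:
    """Merge runs of same-offset off-diagonal dots of a self-plot into segments.

    Consecutive dots along a diagonal may be separated by up to
    ``gap_tolerance`` missing window starts. Each duplicated segment is
    reported once, with interval_a upstream of interval_b.
    """
    if not self_plot.is_self:
        raise ValueError("repeat segments are called on a self-comparison plot")
    w = self_plot.params.window
    segments: list[RepeatSegment] = []
    # forward-strand off-diagonal dots, upper triangle only (j > i)
    by_offset: dict[int, list[int]] = {}
    for i, j, s in self_plot.dots:
        if s == "+" and j > i:
            by_offset.setdefault(j - i, []).append(i)
    # reverse-strand dots grouped by anti-diagonal (i + j); keep i < j side
    by_anti: dict[int, list[int]] = {}
    for i, j, s in self_plot.dots:
        if s == "-" and j >= i:
            by_anti.setdefault(i + j, []).append(i)

    def runs(starts: list[int]):
        starts = sorted(set(starts))
        run = [starts[0]]
        for x in starts[1:]:
            if x - run[-1] <= 1 + gap_tolerance:
                run.append(x)
            else:
                yield run
                run = [x]
        yield run

    for off, starts in sorted(by_offset.items()):
        for run in runs(starts):
            length = run[-1] - run[0] + w
            if length < min_segment:
                continue
            i0 = run[0]
            segments.append(
                RepeatSegment(
                    interval_a=GenomicInterval("self", i0, i0 + length, "+"),
                    interval_b=GenomicInterval("self", i0 + off, i0 + off + length, "+"),
                    diagonal_offset=off,
                    length=length,
                    strand="+",
                )
            )
    for anti, starts in sorted(by_anti.items()):
        for run in runs(starts):
            length = run[-1] - run[0] + w
            if length < min_segment:
                continue
            i0 = run[0]
            j1 = anti - i0  # j of the first dot (largest j in the run)
            segments.append(
                RepeatSegment(
                    interval_a=GenomicInterval("self", i0, i0 + length, "+"),
                    interval_b=GenomicInterval("self", j1 + w - length, j1 + w, "-"),
                    diagonal_offset=anti,
                    length=length,
                    strand="-",
                )
            )
    return segments


def _normalize_name(name: str, normalize_pseudogene: bool) -> str:
    key = name.upper()
    if normalize_pseudogene:
        if key.endswith("_P"):
            key = key[:-2]
        elif key.endswith("P") and len(key) > 1:
            key = key[:-1]
    return key


def synteny_blocks(
    list_a: Sequence[GeneOrderEntry],
    list_b: Sequence[GeneOrderEntry],
    normalize_pseudogene: bool = False,
) -> list[SyntenyBlock]:
    """Partition the shared anchors of two gene-order lists into maximal
    order-consistent blocks.

    Anchors are gene names present in both lists (case-insensitive; an
    opt-in rule additionally strips a trailing pseudogene suffix "P"/"_P").
    A forward block requires anchor order in B increasing and every anchor's
    relative strand '+' (same strand in both lists); an inverted block
    requires decreasing order and relative strand '-'.
    """
    pos_b: dict[str, int] = {}
    for idx, e in enumerate(list_b):
        key = _normalize_name(e.name, normalize_pseudogene)
        pos_b.setdefault(key, idx)
    anchors = []
    seen = set()
    for idx, e in enumerate(list_a):
        key = _normalize_name(e.name, normalize_pseudogene)
        if key in pos_b and key not in seen:
            seen.add(key)
            bi = pos_b[key]
            rel = "+" if e.strand == list_b[bi].strand else "-"
            anchors.append((e.name, idx, bi, rel))
    if not anchors:
        return []
    blocks: list[SyntenyBlock] = []
    cur = [anchors[0]]
    cur_orient: str | None = None
    for nxt in anchors[1:]:
        prev = cur[-1]
        fwd_ok = nxt[2] > prev[2] and prev[3] == "+" and nxt[3] == "+"
        inv_ok = nxt[2] < prev[2] and prev[3] == "-" and nxt[3] == "-"
        if cur_orient is None and (fwd_ok or inv_ok):
            cur_orient = "+" if fwd_ok else "-"
            cur.append(nxt)
        elif cur_orient == "+" and fwd_ok:
            cur.append(nxt)
        elif cur_orient == "-" and inv_ok:
            cur.append(nxt)
        else:
            blocks.append(_finish_block(cur, cur_orient))
            cur = [nxt]
            cur_orient = None
    blocks.append(_finish_block(cur, cur_orient))
    return blocks


def _finish_block(anchors, orient: str | None) -> SyntenyBlock:
    if orient is None:
        orient = anchors[0][3]  # singleton: orientation = its relative strand
    return SyntenyBlock(anchors=[(n, ia, ib) for n, ia, ib, _ in anchors], orientation=orient)


def read_gene_order_tsv(path) -> list[GeneOrderEntry]:
    """BED-like TSV (name, start, end, strand) or (chrom, start, end, name, score, strand)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] >= 6:
        names, strands, starts = df[3], df[5], df[1].astype(int)
    elif df.shape[1] == 4:
        names, strands, starts = df[0], df[3], df[1].astype(int)
    else:
        raise ValueError("gene-order TSV needs 4 or 6+ columns")
    order = sorted(range(len(df)), key=lambda i: starts.iloc[i])
    return [GeneOrderEntry(names.iloc[i], strands.iloc[i]) for i in order]
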