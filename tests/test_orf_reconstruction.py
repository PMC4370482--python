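"""Exon placement, collinear chaining, ORF enumeration and position projection."""

import numpy as np
import pytest

from conftest import random_seq
from orfdecay.core_io import AlignmentPair, SeqRecord, revcomp
from orfdecay.orf_reconstruction import (
    AlignParams,
    ExonMap,
    PutativeORF,
    align_exon,
    enumerate_orfs,
    map_exons,
    project_position,
    reconstruct_orfs,
    unproject_position,
)
from orfdecay.synthetic_data import SimConfig, make_ancestral_locus


def mutate(seq, rng, n_subs):
    s = list(seq)
    for pos in rng.choice(len(s), size=n_subs, replace=False):
        s[pos] = "ACGT"[(("ACGT".index(s[pos])) + 1 + int(rng.integers(0, 3))) % 4]
    return "".join(s)


def test_exact_copy_alignment_is_gap_free_and_perfect(rng):
    exon = random_seq(rng, 60)
    region = random_seq(rng, 80) + exon + random_seq(rng, 70)
    placements = align_exon(exon, region)
    assert placements
    top = placements[0]
    assert top.pct_identity == 100.0
    assert (top.interval.start, top.interval.end, top.strand) == (80, 140, "+")
    assert "-" not in top.alignment.ref_aln + top.alignment.hom_aln


def test_minus_strand_copy_found(rng):
    exon = random_seq(rng, 60)
    region = random_seq(rng, 50) + revcomp(exon) + random_seq(rng, 50)
    top = align_exon(exon, region)[0]
    assert top.strand == "-"
    assert top.pct_identity == 100.0
    assert (top.interval.start, top.interval.end) == (50, 110)
    assert top.alignment.hom_seq == exon  # oriented to the reference strand


def test_region_shorter_than_exon_yields_empty(rng):
    assert align_exon(random_seq(rng, 50), random_seq(rng, 20)) == []


def test_alignment_scores_match_quadratic_dp_oracle(rng):
    from oracles import semiglobal_score

    params = AlignParams(min_identity=0.0, max_placements=1)
    for _ in range(30):
        exon = random_seq(rng, int(rng.integers(40, 100)))
        region = (
            random_seq(rng, int(rng.integers(20, 80)))
            + mutate(exon, rng, int(rng.integers(0, 8)))
            + random_seq(rng, int(rng.integers(20, 80)))
        )
        if len(region) > 300:
            region = region[:300]
        placements = align_exon(exon, region, params)
        assert placements, "top placement must exist at identity floor 0"
        want = max(
            semiglobal_score(exon, region), semiglobal_score(exon, revcomp(region))
        )
        assert placements[0].score == pytest.approx(want)


def test_map_exons_collinear_chain(small_locus, rng):
    cfg, model, record, copy = small_locus
    maps = map_exons(model, record, SeqRecord("region", record.seq))
    assert all(m.found for m in maps)
    starts = [m.hom_interval.start for m in maps]
    assert starts == sorted(starts)
    for m, exon in zip(maps, model.exons):
        assert m.pct_identity == 100.0
        assert (m.hom_interval.start, m.hom_interval.end) == (exon.start, exon.end)


def test_enumerate_orfs_single_and_tandem_and_missing(small_locus, rng):
    cfg, model, record, copy = small_locus
    # single copy -> exactly one complete ORF reproducing the reference CDS
    orfs = reconstruct_orfs(model, record, SeqRecord("r1", record.seq))
    assert len(orfs) == 1 and orfs[0].complete
    assert orfs[0].joined_seq == model.spliced_cds(record)

    # two tandem copies -> two complete ORFs labeled a, b in coordinate order
    tandem = record.seq + random_seq(rng, 120) + record.seq
    orfs2 = reconstruct_orfs(model, record, SeqRecord("r2", tandem))
    complete = [o for o in orfs2 if o.complete]
    assert len(complete) == 2
    assert [o.orf_id for o in complete] == ["a", "b"]
    assert all(o.joined_seq == model.spliced_cds(record) for o in complete)
    a_end = max(m.hom_interval.end for m in complete[0].exon_maps)
    b_start = min(m.hom_interval.start for m in complete[1].exon_maps)
    assert a_end <= b_start

    # region missing exon 2 -> one incomplete ORF
    e2 = model.exons[2]
    gutted = record.seq[: e2.start] + record.seq[e2.end :]
    orfs3 = reconstruct_orfs(model, record, SeqRecord("r3", gutted))
    assert len(orfs3) == 1 and not orfs3[0].complete
    assert [m.found for m in orfs3[0].exon_maps] == [True, True, False, True]


def test_inverted_region_yields_minus_strand_orf(small_locus, rng):
    cfg, model, record, copy = small_locus
    region = SeqRecord("rc", revcomp(record.seq))
    orfs = reconstruct_orfs(model, record, region)
    assert len(orfs) == 1 and orfs[0].complete
    assert all(m.hom_interval.strand == "-" for m in orfs[0].exon_maps)
    assert orfs[0].joined_seq == model.spliced_cds(record)


def _orf_from_alignments(pairs):
    maps = [
        ExonMap(i, None, pair, 100.0, True) for i, pair in enumerate(pairs)
    ]
    return PutativeORF("a", maps)


def test_project_position_identity_and_insertion_shift():
    orf = _orf_from_alignments([AlignmentPair("ATGCCC", "ATGCCC")])
    assert [project_position(orf, i) for i in range(6)] == [(i, False) for i in range(6)]

    # 4-base homolog insertion after ref offset 2
    orf2 = _orf_from_alignments([AlignmentPair("ATG----CCC", "ATGTTTTCCC")])
    assert project_position(orf2, 2) == (2, False)
    assert project_position(orf2, 3) == (2, True)  # inside the insertion
    assert project_position(orf2, 7) == (3, False)  # downstream shifted by -4


def test_project_unproject_round_trip(rng):
    for _ in range(20):
        ref = random_seq(rng, 30)
        # random gapping of both rows
        cols = []
        i = 0
        while i < len(ref):
            r = rng.random()
            if r < 0.15:
                cols.append(("-", "ACGT"[int(rng.integers(0, 4))]))  # insertion
            elif r < 0.3:
                cols.append((ref[i], "-"))  # deletion
                i += 1
            else:
                cols.append((ref[i], ref[i]))
                i += 1
        pair = AlignmentPair("".join(a for a, _ in cols), "".join(b for _, b in cols))
        orf = _orf_from_alignments([pair])
        for ref_off in range(len(pair.ref_seq)):
            hom_off = unproject_position(orf, ref_off)
            if hom_off is not None:
                assert project_position(orf, hom_off) == (ref_off, False)


def test_joined_seq_is_concatenation_and_strands_agree(small_locus, rng):
    cfg, model, record, copy = small_locus
    orfs = reconstruct_orfs(model, record, SeqRecord("r", record.seq))
    orf = orfs[0]
    assert orf.joined_seq == "".join(m.alignment.hom_seq for m in orf.exon_maps)
    assert len({m.hom_interval.strand for m in orf.exon_maps}) == 1
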