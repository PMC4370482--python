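"""Artificial translation, disabler classification, enablers, rendering."""

import numpy as np
import pytest

from conftest import random_seq
from orfdecay.core_io import AlignmentPair, SeqRecord
from orfdecay.disabler_scan import (
    Disabler,
    DisablerType,
    left_align_gaps,
    render_alignment,
    scan_disablers,
    scan_enablers,
    scan_orf,
    translate,
)
from orfdecay.orf_reconstruction import reconstruct_orfs
from orfdecay.synthetic_data import (
    PlantSpec,
    SimConfig,
    disable_locus,
    make_ancestral_locus,
    region_record,
)


@pytest.mark.parametrize(
    "seq,frame,expected",
    [
        ("ATGAAATAA", 0, "MK*"),
        ("ATGTAAGGG", 0, "M*G"),  # continues past internal stop
        ("ATGANAGGG", 0, "MXG"),  # ambiguity renders X
        ("ATGAA", 0, "M"),  # trailing bases dropped
        ("TATGAAA", 1, "MK"),
    ],
)
def test_artificial_translation(seq, frame, expected):
    assert translate(seq, frame) == expected


def make_cds(rng, n_codons=40):
    cfg = SimConfig(
        seed=int(rng.integers(0, 2**31)),
        tree="(A:0.0,B:0.0)R;",
        exon_lengths=(n_codons * 3,),
        intron_lengths=(),
    )
    _, _, copy = make_ancestral_locus(cfg)
    return copy.cds()


def test_scan_is_reflexively_empty(rng):
    for _ in range(5):
        cds = make_cds(rng)
        rep = scan_disablers(cds, AlignmentPair(cds, cds))
        assert rep.is_coding and rep.disablers == []
        assert rep.translation.startswith("M")
        assert rep.translation.count("*") == 1 and rep.translation.endswith("*")


@pytest.mark.parametrize("obs_start", ["ATA", "ATT", "GTG"])
def test_start_loss_variants(rng, obs_start):
    cds = make_cds(rng)
    hom = obs_start + cds[3:]
    rep = scan_disablers(cds, AlignmentPair(cds, hom))
    assert [d.type for d in rep.disablers] == [DisablerType.START_LOSS]
    assert rep.disablers[0].ref_nt_offset == 0
    assert rep.disablers[0].obs_codon_or_indel == obs_start


def test_stop_loss_substituted_with_sense_codon(rng):
    cds = make_cds(rng)
    hom = cds[:-3] + "AAA"
    rep = scan_disablers(cds, AlignmentPair(cds, hom))
    assert [d.type for d in rep.disablers] == [DisablerType.STOP_LOSS]
    d = rep.disablers[0]
    assert d.ref_nt_offset == len(cds) - 3
    assert d.obs_codon_or_indel == "AAA"


def test_premature_stop_by_substitution_at_codon_15(rng):
    cds = make_cds(rng)
    # force codon 15 to CAA in the reference, TAA in the homolog
    cds = cds[:45] + "CAA" + cds[48:]
    hom = cds[:45] + "TAA" + cds[48:]
    rep = scan_disablers(cds, AlignmentPair(cds, hom))
    assert [(d.type, d.ref_nt_offset) for d in rep.disablers] == [
        (DisablerType.PREMATURE_STOP_SUBSTITUTION, 45)
    ]
    # verify by direct translation: the homolog really stops early
    assert "*" in translate(hom)[:-1]


def test_frameshift_deletion_and_shifted_frame_stops(rng):
    cds = make_cds(rng, n_codons=60)
    # 2-nt deletion at offset 30
    hom = cds[:30] + cds[32:]
    aln = AlignmentPair(cds, cds[:30] + "--" + cds[32:])
    rep = scan_disablers(cds, aln, normalize=False)
    fs = [d for d in rep.disablers if d.type is DisablerType.FRAMESHIFT_INDEL]
    assert len(fs) == 1
    assert fs[0].indel_len == -2
    assert fs[0].ref_nt_offset == 30
    # every reported shifted-frame stop is a real stop in the shifted translation
    shifted = [d for d in rep.disablers if d.type is DisablerType.PREMATURE_STOP_FRAMESHIFT]
    hom_translation = translate(hom)
    for d in shifted:
        # position in homolog frame: offset shifted by the upstream deletion
        k = (d.ref_nt_offset - 2) // 3
        assert hom_translation[k] == "*"
    # the shifted translation must contain at least the reported stops
    assert len(shifted) == hom_translation[:-1].count("*")


def test_frame_preserving_indel_is_a_note_not_a_disabler(rng):
    cds = make_cds(rng)
    aln = AlignmentPair(cds, cds[:30] + "---" + cds[33:])
    rep = scan_disablers(cds, aln, normalize=False)
    assert all(d.type is not DisablerType.FRAMESHIFT_INDEL for d in rep.disablers)
    assert any("frame-preserving" in w for w in rep.warnings)


def test_insertion_offsets_reported_at_following_codon(rng):
    cds = make_cds(rng)
    aln = AlignmentPair(cds[:31] + "----" + cds[31:], cds[:31] + "TTTT" + cds[31:])
    rep = scan_disablers(cds, aln, normalize=False)
    fs = [d for d in rep.disablers if d.type is DisablerType.FRAMESHIFT_INDEL]
    assert len(fs) == 1 and fs[0].indel_len == 4
    assert fs[0].ref_nt_offset == 30  # codon containing ref offset 31


def test_left_align_gaps_normalizes_repeat_placement():
    #   ref: AAAACG  hom lost one A; any of the four gap placements is
    #   score-equivalent; normalization must choose the leftmost
    for gapped in ("A-AACG", "AA-ACG", "AAA-CG"):
        norm = left_align_gaps(AlignmentPair("AAAACG", gapped))
        assert norm.hom_aln == "-AAACG"
        assert norm.ref_aln == "AAAACG"


def test_frame_bookkeeping_net_offset_invariant(rng):
    # two frameshifts that cancel (net 0 downstream): stops between them are
    # shifted-frame; stops after both are back in frame
    cds = make_cds(rng, n_codons=60)
    # delete 1 nt at 30, insert 1 nt at 90
    ref_aln = cds[:91] + "-" + cds[91:]
    hom_aln = cds[:30] + "-" + cds[31:91] + "T" + cds[91:]
    rep = scan_disablers(cds, AlignmentPair(ref_aln, hom_aln), normalize=False)
    subs_after = [
        d
        for d in rep.disablers
        if d.type is DisablerType.PREMATURE_STOP_SUBSTITUTION
    ]
    for d in subs_after:
        assert d.ref_nt_offset % 3 == 0  # frame-0 calls only at codon starts


def test_scan_enablers_reports_taa_to_tta_substitution(rng):
    cds = make_cds(rng)
    coding = cds[:42] + "TTA" + cds[45:]
    noncoding = cds[:42] + "TAA" + cds[45:]
    rep = scan_enablers(noncoding, coding)
    assert len(rep.enablers) == 1
    d, desc = rep.enablers[0]
    assert d.type is DisablerType.PREMATURE_STOP_SUBSTITUTION
    assert d.ref_nt_offset == 42
    assert "TAA -> TTA" in desc


def test_scan_enablers_identical_sequences_empty(rng):
    cds = make_cds(rng)
    assert scan_enablers(cds, cds).enablers == []


def test_enablers_invert_planted_disablers_one_to_one(rng):
    cfg = SimConfig(seed=int(rng.integers(0, 2**31)), tree="(A:0.0,B:0.0)R;")
    _, _, copy = make_ancestral_locus(cfg)
    ref = copy.cds()
    specs = [
        PlantSpec("R", DisablerType.START_LOSS),
        PlantSpec("R", DisablerType.STOP_LOSS),
        PlantSpec("R", DisablerType.PREMATURE_STOP_SUBSTITUTION, offset=42),
        PlantSpec("R", DisablerType.FRAMESHIFT_INDEL, exon=2, indel_len=2),
    ]
    records = disable_locus(copy, specs, cfg, np.random.default_rng(5), "R")
    truth = {(r.dtype, r.ref_nt_offset) for r in records}
    found = {(d.type, d.ref_nt_offset) for d, _ in scan_enablers(copy.cds(), ref).enablers}
    assert found == truth


def test_render_alignment_marks_each_disabler_once(rng):
    cds = make_cds(rng)
    hom = "ATA" + cds[3:42] + "TAA" + cds[45:]
    rep = scan_disablers(cds, AlignmentPair(cds, hom))
    text = render_alignment(rep, width=60)
    assert text == render_alignment(rep, width=60)  # deterministic
    marks = "".join(
        line[6:] for line in text.splitlines() if line.startswith("disab")
    )
    assert sum(1 for c in marks if c != " ") == len(rep.disablers)
    assert "refnt " in text and "homaa " in text


def test_scan_orf_on_simulated_region_matches_direct_scan(small_locus):
    cfg, model, record, copy = small_locus
    orfs = reconstruct_orfs(model, record, SeqRecord("r", record.seq))
    rep = scan_orf(model.spliced_cds(record), orfs[0])
    assert rep.is_coding and not rep.disablers


def test_partial_alignment_skips_start_check(rng):
    cds = make_cds(rng)
    aln = AlignmentPair(cds[9:], cds[9:])
    rep = scan_disablers(cds, aln, ref_start=9)
    assert rep.is_coding
    assert any("start codon" in w for w in rep.warnings)
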