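"""The scenario generator: locus construction, planting, evolution, emission."""

import numpy as np
import pytest

from orfdecay.core_io import read_fasta, read_gff_exons
from orfdecay.disabler_scan import STOP_CODONS, DisablerType, translate
from orfdecay.phylo import k2p_distance
from orfdecay.synthetic_data import (
    DuplicationEvent,
    PlantSpec,
    SimConfig,
    TranspositionEvent,
    disable_locus,
    emit,
    make_ancestral_locus,
    region_record,
    simulate,
    simulate_k2p_alignment,
)

TWO_TAXON = "(A:0.0,B:0.0)R;"


def test_ancestral_locus_is_clean_cds():
    for seed in range(40):
        cfg = SimConfig(seed=seed, tree=TWO_TAXON)
        model, record, copy = make_ancestral_locus(cfg)
        cds = copy.cds()
        assert cds.startswith("ATG")
        assert cds[-3:] in STOP_CODONS
        aa = translate(cds)
        assert aa.count("*") == 1 and aa.endswith("*")
        assert cds == model.spliced_cds(record)


def test_same_seed_identical_locus():
    cfg = SimConfig(seed=42, tree=TWO_TAXON)
    _, r1, _ = make_ancestral_locus(cfg)
    _, r2, _ = make_ancestral_locus(cfg)
    assert r1.seq == r2.seq


def test_single_exon_locus():
    cfg = SimConfig(seed=1, tree=TWO_TAXON, exon_lengths=(300,), intron_lengths=())
    _, _, copy = make_ancestral_locus(cfg)
    aa = translate(copy.cds())
    assert aa.count("*") == 1 and aa.endswith("*")


def test_plant_start_loss_and_empty_spec(rng):
    cfg = SimConfig(seed=3, tree=TWO_TAXON)
    _, _, copy = make_ancestral_locus(cfg)
    before = copy.seq
    assert disable_locus(copy, [], cfg, rng, "R") == []
    assert copy.seq == before
    recs = disable_locus(copy, [PlantSpec("R", DisablerType.START_LOSS)], cfg, rng, "R")
    assert len(recs) == 1
    assert copy.cds()[:3] != "ATG"
    assert recs[0].ref_nt_offset == 0


def test_plant_collision_raises(rng):
    cfg = SimConfig(seed=3, tree=TWO_TAXON)
    _, _, copy = make_ancestral_locus(cfg)
    with pytest.raises(ValueError, match="collision"):
        disable_locus(
            copy,
            [
                PlantSpec("R", DisablerType.PREMATURE_STOP_SUBSTITUTION, offset=42),
                PlantSpec("R", DisablerType.PREMATURE_STOP_SUBSTITUTION, offset=42),
            ],
            cfg,
            rng,
            "R",
        )


def test_planted_premature_stop_recovered_by_scanner(rng):
    from orfdecay.core_io import AlignmentPair
    from orfdecay.disabler_scan import scan_disablers

    cfg = SimConfig(seed=11, tree=TWO_TAXON)
    _, _, copy = make_ancestral_locus(cfg)
    ref = copy.cds()
    disable_locus(
        copy, [PlantSpec("R", DisablerType.PREMATURE_STOP_SUBSTITUTION, offset=42)], cfg, rng, "R"
    )
    rep = scan_disablers(ref, AlignmentPair(ref, copy.cds()))
    assert [(d.type, d.ref_nt_offset) for d in rep.disablers] == [
        (DisablerType.PREMATURE_STOP_SUBSTITUTION, 42)
    ]


def test_zero_branch_lengths_leaves_identical_to_root():
    cfg = SimConfig(seed=5, tree="(A:0.0,(B:0.0,C:0.0)BC:0.0)R;")
    res = simulate(cfg)
    seqs = {t: res.leaves[t]["autosome"][0].seq for t in ("A", "B", "C")}
    assert seqs["A"] == seqs["B"] == seqs["C"] == res.ancestral_record.seq


def test_k2p_process_calibration():
    # mean pairwise K2P distance at total path 0.2 is close to 0.2
    ds = []
    for seed in range(30):
        recs = dict(simulate_k2p_alignment("(X:0.1,Y:0.1);", 10000, 2.0, seed))
        ds.append(k2p_distance(recs["X"], recs["Y"]))
    assert np.mean(ds) == pytest.approx(0.2, abs=0.005)


def test_fixed_seed_reproducible_files(tmp_path):
    cfg_kwargs = dict(
        seed=9,
        tree="((A:0.02,B:0.02)AB:0.02,C:0.05)R;",
        indel_rate=0.002,
        plants=[PlantSpec("R", DisablerType.START_LOSS)],
    )
    r1 = simulate(SimConfig(**cfg_kwargs))
    r2 = simulate(SimConfig(**cfg_kwargs))
    d1, d2 = tmp_path / "one", tmp_path / "two"
    emit(r1, d1)
    emit(r2, d2)
    for f in sorted(p.name for p in d1.iterdir()):
        assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f


def test_emitted_gff_round_trips_to_gene_models(tmp_path):
    cfg = SimConfig(
        seed=13,
        tree="(A:0.01,B:0.01)R;",
        transpositions=[TranspositionEvent("A", "autosome", "chrY", inverted=True)],
    )
    res = simulate(cfg)
    outdir = tmp_path / "sim"
    emit(res, outdir)
    for taxon in res.leaves:
        for comp, copies in res.leaves[taxon].items():
            rec, models = region_record(taxon, comp, copies)
            fasta = read_fasta(outdir / f"{taxon}.{comp}.fa")
            assert fasta[0].seq == rec.seq
            for model in models:
                back = read_gff_exons(outdir / "annotations.gff3", model.gene_id)
                assert [(e.start, e.end, e.strand) for e in back.exons] == [
                    (e.start, e.end, e.strand) for e in model.exons
                ]
                # spliced CDS from the emitted region equals the copy's CDS
                assert back.spliced_cds(fasta[0]) == model.spliced_cds(rec)


def test_transposition_duplication_and_enable():
    cfg = SimConfig(
        seed=21,
        tree="((A:0.0,B:0.0)AB:0.0,C:0.0)R;",
        plants=[
            PlantSpec("R", DisablerType.START_LOSS),
            PlantSpec("R", DisablerType.FRAMESHIFT_INDEL, exon=1, indel_len=-2),
        ],
        transpositions=[TranspositionEvent("AB", "autosome", "chrY")],
        duplications=[DuplicationEvent("A", "chrY", copies=2)],
        enable_branch="AB",
        enable_compartment="chrY",
    )
    res = simulate(cfg)
    # C never received the transposition
    assert "chrY" not in res.leaves["C"]
    # A's Y compartment holds two tandem copies, both enabled and coding
    a_y = res.leaves["A"]["chrY"]
    assert len(a_y) == 2
    for c in a_y:
        assert c.enabled
        cds = c.cds()
        assert cds == res.ref_cds  # reversion restored the ancestral CDS exactly
    # the autosomal copies keep their disablers
    assert not res.leaves["A"]["autosome"][0].enabled
    truth = res.truth
    auto = truth[(truth.taxon == "A") & (truth.compartment == "autosome")]
    assert (~auto.reverted).all() and auto.intact.all()
    ychr = truth[(truth.taxon == "A") & (truth.compartment == "chrY")]
    assert ychr.reverted.all()


def test_inverted_transposition_emits_minus_strand_copy():
    cfg = SimConfig(
        seed=30,
        tree="(A:0.0,B:0.0)R;",
        transpositions=[TranspositionEvent("A", "autosome", "chrY", inverted=True)],
    )
    res = simulate(cfg)
    rec, models = region_record("A", "chrY", res.leaves["A"]["chrY"])
    assert all(e.strand == "-" for e in models[0].exons)
    assert models[0].spliced_cds(rec) == res.ref_cds


def test_truth_rows_scale_with_copies():
    cfg = SimConfig(
        seed=33,
        tree="(A:0.0,B:0.0)R;",
        plants=[
            PlantSpec("R", DisablerType.START_LOSS),
            PlantSpec("R", DisablerType.STOP_LOSS),
        ],
        duplications=[DuplicationEvent("A", "autosome", copies=3)],
    )
    res = simulate(cfg)
    t = res.truth
    assert len(t[(t.taxon == "A")]) == 2 * 3  # 2 plants x 3 tandem copies
    assert len(t[(t.taxon == "B")]) == 2
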