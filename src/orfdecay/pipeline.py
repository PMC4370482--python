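"""End-to-end orchestration and the packaged demo scenario.

The demo emulates the evolutionary history of a Y-chromosome gene born de
novo from a non-coding autosomal locus: a coding ancestral locus is disabled
at the root (start loss, stop loss, two premature stops at 42 and 81 nt,
and a 4-nt frameshifting deletion), evolves along a five-species primate-like
tree (three apes, one Old World monkey, one outgroup), is transposed from
the autosome to the Y chromosome on the catarrhine stem, duplicated in
tandem on the human/chimpanzee stem, and regains coding ability (every
disabler reverted, integrity enforced) on the ape stem — on the Y copy only.

``run`` executes the stages (simulate, filter, reconstruct, scan, compare,
tree, structure) in dependency order with provenance capture; ``demo`` runs
the packaged scenario and checks its invariants.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from orfdecay import candidate_filter as cf
from orfdecay import comparative, phylo
from orfdecay import genome_structure as gs
from orfdecay.core_io import GenomicInterval, HitRecord, SeqRecord, write_fasta
from orfdecay.disabler_scan import DisablerReport, render_alignment, scan_orf
from orfdecay.orf_reconstruction import AlignParams, reconstruct_orfs
from orfdecay.synthetic_data import (
    DisablerType,
    DuplicationEvent,
    PlantSpec,
    SimConfig,
    SimResult,
    TranspositionEvent,
    emit,
    region_record,
    simulate,
)

DEMO_TAXA = ("Hosa", "Patr", "Gogo", "Mamu", "Caja")


def demo_tree(divergence: float) -> str:
    """Five-species tree with every leaf at root-to-tip distance ``divergence``."""
    a = divergence * 0.25
    g = divergence * 0.50
    m = divergence * 0.75
    c = divergence * 1.00
    return (
        f"((((Hosa:{a},Patr:{a})HP:{a},Gogo:{g})Ape:{a},Mamu:{m})Cat:{a},Caja:{c})Root;"
    )


def demo_config(seed: int, divergence: float = 0.0, indel_rate: float = 0.002) -> SimConfig:
    """The packaged scenario; ``divergence`` is the root-to-leaf substitution load."""
    return SimConfig(
        seed=seed,
        tree=demo_tree(divergence),
        kappa=2.0,
        indel_rate=indel_rate,
        plants=[
            PlantSpec("Root", DisablerType.START_LOSS),
            PlantSpec("Root", DisablerType.STOP_LOSS),
            PlantSpec("Root", DisablerType.PREMATURE_STOP_SUBSTITUTION, exon=0, offset=42),
            PlantSpec("Root", DisablerType.PREMATURE_STOP_SUBSTITUTION, exon=0, offset=81),
            PlantSpec("Root", DisablerType.FRAMESHIFT_INDEL, exon=1, indel_len=-4),
        ],
        enable_branch="Ape",
        enable_compartment="chrY",
        transpositions=[TranspositionEvent("Cat", "autosome", "chrY")],
        duplications=[DuplicationEvent("HP", "chrY", copies=2)],
        root_compartment="autosome",
    )


DEMO_SPLIT_LABELS = {
    "Ape": "after the ape-Old World monkey split",
    "Cat": "after the catarrhine-New World monkey split",
    "HP": "after the human/chimpanzee-gorilla split",
}


def demo_hit_tables(result: SimResult) -> dict[str, list[HitRecord]]:
    """Plausible homology-hit tables for the scenario (hit tables are inputs
    to the filter, not produced by this package, so the demo fabricates the
    numbers a search over the simulated genomes would report)."""
    gene = result.gene_model.gene_id

    def hit(sid, ident, length, ev, s_len=None):
        s_len = s_len or length
        return HitRecord(
            query_id=gene,
            subject_id=sid,
            pct_identity=ident,
            align_length=length,
            e_value=ev,
            bit_score=length * 1.8,
            query=GenomicInterval(gene, 0, length),
            subject=GenomicInterval(sid, 1000, 1000 + s_len),
        )

    return {
        # no qualifying protein homolog outside the lineage
        "outgroup_proteins": [hit("rodent_protein_1", 28.0, 180, 0.5)],
        # within-lineage protein hits only to Y-linked paralogs
        "lineage_proteins": [hit("chrY_paralog_1", 98.0, 119, 1e-60)],
        # long, high-identity non-coding genomic fragments
        "genomes": [
            hit("Hosa_chr7_region", 92.5, 4800, 0.0),
            hit("Patr_chr7_region", 91.0, 4650, 0.0),
            hit("short_fragment", 95.0, 900, 1e-30),
        ],
    }


DEMO_CHROM_MAP = {
    "chrY_paralog_1": "chrY",
    "Hosa_chr7_region": "autosome",
    "Patr_chr7_region": "autosome",
    "short_fragment": "autosome",
}


@dataclass
class RunConfig:
    seed: int
    outdir: str
    divergence: float = 0.0
    indel_rate: float = 0.002
    stages: tuple[str, ...] = (
        "simulate", "filter", "reconstruct", "scan", "compare", "tree", "structure",
    )
    bootstrap_replicates: int = 200
    min_identity: float = 60.0


@dataclass
class StageReport:
    stage: str
    status: str  # ok | failed | skipped
    seconds: float = 0.0
    outputs: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass
class RunReport:
    config: RunConfig
    stages: list[StageReport]
    manifest: list[str]
    # analysis products kept in memory for callers/tests
    sim: SimResult | None = None
    verdict: cf.CandidateVerdict | None = None
    reports: dict[tuple[str, str, str], DisablerReport] = field(default_factory=dict)
    statuses: list[comparative.TaxonStatus] = field(default_factory=list)
    reconstruction: comparative.EventReconstruction | None = None
    tree: object | None = None

    @property
    def ok(self) -> bool:
        return all(s.status != "failed" for s in self.stages)


def reference_anchored_msa(
    reports: dict[str, DisablerReport], ref_cds: str, start: int = 0, end: int | None = None
) -> phylo.MultipleAlignment:
    """Build a reference-anchored multiple alignment from per-taxon scans.

    Column c holds, per taxon, the homolog base aligned to reference CDS
    offset ``start + c`` ('-' when deleted); homolog-only insertions are
    dropped. The reference itself is included as taxon 'reference'."""
    end = end if end is not None else len(ref_cds)
    records = [("reference", ref_cds[start:end])]
    for taxon, rep in sorted(reports.items()):
        aln = rep.alignment
        row = ["-"] * (end - start)
        r = -1
        for a, b in zip(aln.ref_aln, aln.hom_aln):
            if a != "-":
                r += 1
                if start <= r < end:
                    row[r - start] = b if b != "-" else "-"
        records.append((taxon, "".join(row)))
    return phylo.MultipleAlignment(records)


def run(config: RunConfig) -> RunReport:
    """Execute the pipeline stages in dependency order; a stage failure halts
    everything downstream."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config, stages=[], manifest=[])
    halted = False

    def stage(name):
        def deco(fn):
            nonlocal halted
            sr = StageReport(stage=name, status="skipped")
            if name in config.stages and not halted:
                t0 = time.perf_counter()
                try:
                    fn(sr)
                    sr.status = "ok"
                except Exception as exc:  # halt downstream, keep the trace readable
                    sr.status = "failed"
                    sr.warnings.append(f"{type(exc).__name__}: {exc}")
                    halted = True
                sr.seconds = time.perf_counter() - t0
            report.stages.append(sr)
            report.manifest.extend(sr.outputs)
            return fn

        return deco

    @stage("simulate")
    def _simulate(sr):
        sim = simulate(
            demo_config(config.seed, config.divergence, config.indel_rate)
        )
        report.sim = sim
        manifest = emit(sim, outdir / "sim")
        sr.outputs += [f"sim/{f}" for fs in manifest.values() for f in fs]

    @stage("filter")
    def _filter(sr):
        hits = demo_hit_tables(report.sim)
        verdict = cf.evaluate_candidate(
            report.sim.gene_model.gene_id,
            hits["outgroup_proteins"],
            hits["lineage_proteins"],
            hits["genomes"],
            DEMO_CHROM_MAP,
        )
        report.verdict = verdict
        cf.verdict_frame([verdict]).to_csv(outdir / "verdict.tsv", sep="\t", index=False)
        sr.outputs.append("verdict.tsv")

    @stage("reconstruct")
    def _reconstruct(sr):
        sim = report.sim
        params = AlignParams(min_identity=config.min_identity)
        report._orfs = {}
        for taxon in sorted(sim.leaves):
            for comp in sorted(sim.leaves[taxon]):
                rec, _ = region_record(taxon, comp, sim.leaves[taxon][comp])
                orfs = reconstruct_orfs(
                    sim.gene_model, sim.ancestral_record, rec, params
                )
                report._orfs[(taxon, comp)] = orfs
        fa = [
            SeqRecord(id=f"{t}|{c}|orf_{o.orf_id}", seq=o.joined_seq)
            for (t, c), orfs in sorted(report._orfs.items())
            for o in orfs
            if o.joined_seq
        ]
        write_fasta(fa, outdir / "putative_orfs.fa")
        sr.outputs.append("putative_orfs.fa")

    @stage("scan")
    def _scan(sr):
        import pandas as pd

        sim = report.sim
        exon_lengths = [len(e) for e in sim.gene_model.exons]
        frames = []
        renderings = []
        for (taxon, comp), orfs in sorted(report._orfs.items()):
            for orf in orfs:
                if not any(m.found for m in orf.exon_maps):
                    continue
                rep = scan_orf(sim.ref_cds, orf, exon_ref_lengths=exon_lengths)
                report.reports[(taxon, comp, orf.orf_id)] = rep
                frames.append(rep.frame())
                renderings.append(render_alignment(rep))
        report.statuses = _statuses_from_reports(report)
        table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        if not table.empty:
            table = table.astype(
                {"exon": "int64", "ref_nt_offset": "int64", "indel_len": "int64"}
            )
        table.to_csv(outdir / "disablers.tsv", sep="\t", index=False)
        (outdir / "alignments.txt").write_text("\n".join(renderings))
        sr.outputs += ["disablers.tsv", "alignments.txt"]

    @stage("compare")
    def _compare(sr):
        sim = report.sim
        key_reports = {
            f"{t}|{c}|{o}": rep for (t, c, o), rep in report.reports.items()
        }
        matrix = comparative.build_shared_matrix(key_reports)
        matrix.table.to_csv(outdir / "shared_disablers.tsv", sep="\t")
        recon = comparative.infer_ancestral_state(sim.config.tree, report.statuses)
        report.reconstruction = recon
        summary = comparative.summarize_history(recon, DEMO_SPLIT_LABELS)
        (outdir / "history.txt").write_text(summary + "\n")
        sr.outputs += ["shared_disablers.tsv", "history.txt"]

    @stage("tree")
    def _tree(sr):
        sim = report.sim
        per_taxon = {}
        for (taxon, comp, orf_id), rep in sorted(report.reports.items()):
            per_taxon.setdefault(f"{taxon}_{comp}", rep)
        exon1_end = len(sim.gene_model.exons[0])
        msa = reference_anchored_msa(per_taxon, sim.ref_cds, 0, exon1_end)
        try:
            tree = phylo.bootstrap_support(
                msa,
                phylo.k2p_distance,
                phylo.BootstrapConfig(config.bootstrap_replicates, config.seed),
            )
            report.tree = tree
            (outdir / "tree.nwk").write_text(
                tree.as_string(schema="newick", suppress_rooting=True)
            )
            sr.outputs.append("tree.nwk")
        except phylo.SaturationError as exc:
            sr.warnings.append(f"tree skipped: {exc}")

    @stage("structure")
    def _structure(sr):
        sim = report.sim
        taxon = sorted(sim.leaves)[0]
        comp = "chrY" if "chrY" in sim.leaves[taxon] else sorted(sim.leaves[taxon])[0]
        rec, _ = region_record(taxon, comp, sim.leaves[taxon][comp])
        plot = gs.dotplot(rec.seq, rec.seq, gs.DotPlotParams(window=14, max_mismatch=0))
        plot.to_frame().to_csv(outdir / "self_dotplot.tsv", sep="\t", index=False)
        segments = gs.call_repeat_segments(plot, min_segment=200, gap_tolerance=2)
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "a_start": s.interval_a.start,
                    "a_end": s.interval_a.end,
                    "b_start": s.interval_b.start,
                    "b_end": s.interval_b.end,
                    "length": s.length,
                    "strand": s.strand,
                }
                for s in segments
            ]
        ).to_csv(outdir / "repeat_segments.tsv", sep="\t", index=False)
        sr.outputs += ["self_dotplot.tsv", "repeat_segments.tsv"]

    (outdir / "run_report.json").write_text(
        json.dumps(
            {
                "seed": config.seed,
                "divergence": config.divergence,
                "stages": [
                    {
                        "stage": s.stage,
                        "status": s.status,
                        "seconds": round(s.seconds, 3),
                        "outputs": s.outputs,
                        "warnings": s.warnings,
                    }
                    for s in report.stages
                ],
                "manifest": report.manifest,
            },
            indent=2,
        )
        + "\n"
    )
    report.manifest.append("run_report.json")
    return report


def _statuses_from_reports(report: RunReport) -> list[comparative.TaxonStatus]:
    """Per-taxon coding status: the Y-compartment copy where one exists,
    otherwise the autosomal one; coding if any ORF of that compartment is."""
    by_taxon: dict[str, dict[str, list[DisablerReport]]] = {}
    for (taxon, comp, _), rep in report.reports.items():
        by_taxon.setdefault(taxon, {}).setdefault(comp, []).append(rep)
    statuses = []
    for taxon in sorted(by_taxon):
        comp = "chrY" if "chrY" in by_taxon[taxon] else sorted(by_taxon[taxon])[0]
        reps = by_taxon[taxon][comp]
        coding = any(r.is_coding for r in reps)
        statuses.append(
            comparative.TaxonStatus(
                taxon=taxon,
                compartment=comp,
                coding_ability="coding" if coding else "non_coding",
                evidence=f"{len(reps)} scanned ORF(s)",
            )
        )
    return statuses


def demo(outdir: str, seed: int = 0) -> RunReport:
    """Run the packaged scenario (zero post-planting divergence) and verify
    its invariants: full disabler recovery and the gain placed on the ape stem."""
    report = run(RunConfig(seed=seed, outdir=outdir, divergence=0.0))
    if not report.ok:
        raise RuntimeError("demo pipeline failed: " + json.dumps(
            [(s.stage, s.warnings) for s in report.stages if s.status == "failed"],
            default=str,
        ))
    recovered, expected = demo_truth_comparison(report)
    missing = expected - recovered
    extra = recovered - expected
    if missing or extra:
        raise RuntimeError(
            f"disabler recovery mismatch: missing={sorted(missing)} extra={sorted(extra)}"
        )
    gains = [
        ev for ev in report.reconstruction.events if ev.event == "gain_coding"
    ]
    if len(gains) != 1 or gains[0].branch != "Ape" or report.reconstruction.parsimony_score != 1:
        raise RuntimeError("event reconstruction did not place a single gain on the ape stem")
    return report


def demo_truth_comparison(report: RunReport) -> tuple[set, set]:
    """(recovered, expected) disabler key sets for the demo run.

    Keys are (taxon, compartment, copy-rank, type, exon, offset); expected
    keys come from the simulator truth table (intact, unreverted rows),
    recovered keys from the scan reports, with ORF letters mapped to copy
    rank by region coordinate order."""
    sim = report.sim
    truth = sim.truth
    expected = set()
    rank: dict[tuple[str, str, str], int] = {}
    for taxon in sorted(sim.leaves):
        for comp in sorted(sim.leaves[taxon]):
            for i, c in enumerate(sim.leaves[taxon][comp]):
                rank[(taxon, comp, c.copy_id)] = i
    for _, row in truth.iterrows():
        if row["reverted"] or row["destroyed"] or not row["intact"]:
            continue
        expected.add(
            (
                row["taxon"],
                row["compartment"],
                rank[(row["taxon"], row["compartment"], row["copy_id"])],
                row["type"],
                int(row["exon"]),
                int(row["ref_nt_offset"]),
            )
        )
    recovered = set()
    for (taxon, comp, orf_id), rep in report.reports.items():
        orf_rank = ord(orf_id) - ord("a")
        for d in rep.disablers:
            recovered.add(
                (taxon, comp, orf_rank, d.type.value, d.exon_index, d.ref_nt_offset)
            )
    return recovered, expected
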