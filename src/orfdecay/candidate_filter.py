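"""Candidate filtering: orphan classification and genomic-fragment retention.

The decision logic mirrors a two-round homology screen. A gene is a lineage
orphan if no protein-level hit against the out-lineage protein set passes
both an E-value ceiling (default 1e-4) and a strict identity floor (default
35%). An orphan is excluded if a qualifying within-lineage protein hit falls
on an autosome or the X chromosome. Finally, genomic homology fragments are
retained only when strictly longer than 4 kb and strictly above 80%
identity. "Over" / "greater than" are read as strict inequalities
throughout; boundary behaviour is unit-tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from orfdecay.core_io import GenomicInterval, HitRecord


@dataclass(frozen=True)
class OrphanCriteria:
    """Thresholds for the protein-homolog screen."""

    e_max: float = 1e-4
    identity_min: float = 35.0

    def __post_init__(self) -> None:
        if self.e_max <= 0:
            raise ValueError("e_max must be positive")
        if not 0 < self.identity_min < 100:
            raise ValueError("identity_min must be in (0, 100)")

    def qualifies(self, hit: HitRecord) -> bool:
        """A hit counts as evidence of homology: E <= e_max and identity strictly > identity_min."""
        return hit.e_value <= self.e_max and hit.pct_identity > self.identity_min


@dataclass(frozen=True)
class FragmentCriteria:
    """Thresholds for retaining genomic homology fragments."""

    length_min: int = 4000
    identity_min: float = 80.0

    def __post_init__(self) -> None:
        if self.length_min <= 0:
            raise ValueError("length_min must be positive")


@dataclass
class CandidateVerdict:
    gene_id: str
    is_orphan: bool
    has_coding_homolog: bool
    retained_fragments: list[tuple[GenomicInterval, float]] = field(default_factory=list)
    verdict: str = "excluded"
    reason: str = ""

    def __post_init__(self) -> None:
        expected = (
            "candidate"
            if self.is_orphan and not self.has_coding_homolog and self.retained_fragments
            else "excluded"
        )
        if self.verdict != expected:
            raise ValueError(
                f"verdict {self.verdict!r} inconsistent with fields (expected {expected!r})"
            )


def classify_orphan(
    gene_id: str,
    hits_vs_outgroup_proteins: Sequence[HitRecord],
    criteria: OrphanCriteria = OrphanCriteria(),
) -> bool:
    """True iff the gene has no qualifying protein homolog outside the lineage.

    An empty hit list is valid and vacuously classifies the gene as orphan.
    """
    return not any(criteria.qualifies(h) for h in hits_vs_outgroup_proteins)


def exclude_coding_homolog(
    gene_id: str,
    hits_vs_lineage_proteins: Sequence[HitRecord],
    subject_locations: Mapping[str, str],
    criteria: OrphanCriteria = OrphanCriteria(),
) -> bool:
    """True (exclude the gene) iff a qualifying hit's subject lies on an autosome or chrX.

    ``subject_locations`` maps subject ids to a chromosome class in
    {"autosome", "chrX", "chrY"}; subjects absent from the map are ignored
    (their compartment is unknown, so they cannot trigger exclusion).
    """
    for h in hits_vs_lineage_proteins:
        if not criteria.qualifies(h):
            continue
        loc = subject_locations.get(h.subject_id)
        if loc in ("autosome", "chrX"):
            return True
    return False


def filter_genomic_fragments(
    hits_vs_genomes: Sequence[HitRecord],
    criteria: FragmentCriteria = FragmentCriteria(),
) -> list[HitRecord]:
    """Retain fragments strictly longer than length_min and strictly above identity_min.

    The thresholds apply to individual hits, not merged regions. Output is
    sorted by subject location (id, start, end) for determinism.
    """
    kept = [
        h
        for h in hits_vs_genomes
        if h.align_length > criteria.length_min and h.pct_identity > criteria.identity_min
    ]
    kept.sort(key=lambda h: (h.subject.seq_id, h.subject.start, h.subject.end))
    return kept


def evaluate_candidate(
    gene_id: str,
    hits_vs_outgroup_proteins: Sequence[HitRecord],
    hits_vs_lineage_proteins: Sequence[HitRecord],
    hits_vs_genomes: Sequence[HitRecord],
    subject_locations: Mapping[str, str],
    orphan_criteria: OrphanCriteria = OrphanCriteria(),
    fragment_criteria: FragmentCriteria = FragmentCriteria(),
) -> CandidateVerdict:
    """Run the full decision pipeline for one gene and return a verdict."""
    is_orphan = classify_orphan(gene_id, hits_vs_outgroup_proteins, orphan_criteria)
    excluded = exclude_coding_homolog(
        gene_id, hits_vs_lineage_proteins, subject_locations, orphan_criteria
    )
    fragments = filter_genomic_fragments(hits_vs_genomes, fragment_criteria)
    frag_pairs = [(h.subject, h.pct_identity) for h in fragments]
    if not is_orphan:
        reason = "protein homolog found outside the lineage"
    elif excluded:
        reason = "protein-coding homolog on an autosome or chrX"
    elif not frag_pairs:
        reason = "no genomic fragment passed the length/identity thresholds"
    else:
        reason = f"orphan with {len(frag_pairs)} retained non-coding genomic fragment(s)"
    verdict = (
        "candidate" if is_orphan and not excluded and frag_pairs else "excluded"
    )
    return CandidateVerdict(
        gene_id=gene_id,
        is_orphan=is_orphan,
        has_coding_homolog=excluded,
        retained_fragments=frag_pairs,
        verdict=verdict,
        reason=reason,
    )


def read_chrom_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping subject id to chromosome class."""
    df = pd.read_csv(path, sep="\t", names=["subject_id", "chrom_class"], dtype=str, comment="#")
    bad = set(df["chrom_class"]) - {"autosome", "chrX", "chrY"}
    if bad:
        raise ValueError(f"unknown chromosome classes in map: {sorted(bad)}")
    return dict(zip(df["subject_id"], df["chrom_class"]))


def verdict_frame(verdicts: Sequence[CandidateVerdict]) -> pd.DataFrame:
    """Tabulate verdicts for TSV export."""
    return pd.DataFrame(
        {
            "gene_id": [v.gene_id for v in verdicts],
            "is_orphan": [v.is_orphan for v in verdicts],
            "has_coding_homolog": [v.has_coding_homolog for v in verdicts],
            "n_retained_fragments": [len(v.retained_fragments) for v in verdicts],
            "verdict": [v.verdict for v in verdicts],
            "reason": [v.reason for v in verdicts],
        }
    )
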