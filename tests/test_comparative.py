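"""Shared-disabler matrices and parsimony reconstruction of coding ability."""

import itertools

import dendropy
import numpy as np
import pytest

from orfdecay.comparative import (
    TaxonStatus,
    build_shared_matrix,
    infer_ancestral_state,
    summarize_history,
)
from orfdecay.core_io import AlignmentPair
from orfdecay.disabler_scan import Disabler, DisablerReport, DisablerType


def report(taxon, keys):
    return DisablerReport(
        orf_id=taxon,
        disablers=[
            Disabler(DisablerType(t), 0, off) for t, off in keys
        ],
        is_coding=not keys,
        translation="",
        alignment=AlignmentPair("ATG", "ATG"),
    )


def test_shared_matrix_identical_reports():
    keys = [("START_LOSS", 0), ("PREMATURE_STOP_SUBSTITUTION", 42)]
    m = build_shared_matrix({"A": report("A", keys), "B": report("B", keys)})
    assert (m.table == "present").all().all()
    assert set(m.ancestral_candidates) == set(keys)


def test_shared_matrix_present_absent():
    m = build_shared_matrix(
        {"A": report("A", [("START_LOSS", 0)]), "B": report("B", [])}
    )
    assert m.table.loc[("START_LOSS", 0), "A"] == "present"
    assert m.table.loc[("START_LOSS", 0), "B"] == "absent"
    assert m.ancestral_candidates == []


def test_shared_matrix_matches_pairwise_oracle(rng):
    taxa = ["t1", "t2", "t3"]
    reports = {}
    all_keys = set()
    for t in taxa:
        keys = {
            ("PREMATURE_STOP_SUBSTITUTION", int(rng.integers(0, 20)) * 3)
            for _ in range(int(rng.integers(0, 5)))
        }
        all_keys |= keys
        reports[t] = report(t, sorted(keys))
    m = build_shared_matrix(reports)
    # brute force: for every key and taxon, membership decides the cell
    for key in all_keys:
        for t in taxa:
            want = "present" if key in {
                (d.type.value, d.ref_nt_offset) for d in reports[t].disablers
            } else "absent"
            assert m.table.loc[key, t] == want


def test_shared_matrix_tolerance_clusters_nearby_offsets():
    m = build_shared_matrix(
        {
            "A": report("A", [("PREMATURE_STOP_SUBSTITUTION", 42)]),
            "B": report("B", [("PREMATURE_STOP_SUBSTITUTION", 44)]),
        },
        tolerance=3,
    )
    assert len(m.table) == 1
    assert (m.table.loc[("PREMATURE_STOP_SUBSTITUTION", 42)] == "present").all()


PRIMATE_TREE = "((((Hosa,Patr)HP,Gogo)Ape,Mamu)Cat,Caja)Root;"


def test_all_noncoding_means_no_events():
    statuses = [
        TaxonStatus(t, "autosome", "non_coding")
        for t in ("Hosa", "Patr", "Gogo", "Mamu", "Caja")
    ]
    r = infer_ancestral_state(PRIMATE_TREE, statuses)
    assert r.parsimony_score == 0 and r.events == []
    assert summarize_history(r) == "no state changes inferred"


def test_single_gain_on_ape_stem():
    statuses = [TaxonStatus(t, "chrY", "coding") for t in ("Hosa", "Patr", "Gogo")] + [
        TaxonStatus(t, "autosome", "non_coding") for t in ("Mamu", "Caja")
    ]
    r = infer_ancestral_state(PRIMATE_TREE, statuses)
    assert r.parsimony_score == 1
    assert len(r.solutions) == 1
    assert [(e.branch, e.event) for e in r.events] == [("Ape", "gain_coding")]
    text = summarize_history(r, {"Ape": "after the ape-Old World monkey split"})
    assert "gain of coding ability after the ape-Old World monkey split" in text


def test_absent_taxa_are_missing_data():
    statuses = [
        TaxonStatus("Hosa", "chrY", "coding"),
        TaxonStatus("Patr", "chrY", "coding"),
        TaxonStatus("Gogo", "chrY", "absent"),  # missing, not a third state
        TaxonStatus("Mamu", "chrY", "non_coding"),
        TaxonStatus("Caja", "autosome", "non_coding"),
    ]
    r = infer_ancestral_state(PRIMATE_TREE, statuses)
    assert r.parsimony_score == 1


def test_degenerate_input_raises():
    with pytest.raises(ValueError, match="at least 2"):
        infer_ancestral_state(PRIMATE_TREE, [TaxonStatus("Hosa", "chrY", "coding")])


def test_parsimony_score_matches_exhaustive_oracle(rng):
    from oracles import exhaustive_parsimony, random_binary_tree

    for case in range(25):
        n = int(rng.integers(3, 7))
        taxa = [f"L{i}" for i in range(n)]
        newick = random_binary_tree(taxa, rng)
        states = {}
        statuses = []
        for t in taxa:
            s = ["coding", "non_coding", None][int(rng.integers(0, 3))]
            states[t] = s
            statuses.append(TaxonStatus(t, "chrY", s or "unknown"))
        if sum(1 for s in states.values() if s) < 2:
            states[taxa[0]] = "coding"
            states[taxa[1]] = "non_coding"
            statuses[0] = TaxonStatus(taxa[0], "chrY", "coding")
            statuses[1] = TaxonStatus(taxa[1], "chrY", "non_coding")
        r = infer_ancestral_state(newick, statuses)
        # rebuild the tree as child lists for the oracle
        tree = r.tree
        children = {
            node.label: [c.label for c in node.child_nodes()]
            for node in tree.preorder_node_iter()
        }
        want = exhaustive_parsimony(children, tree.seed_node.label, states)
        assert r.parsimony_score == want
        # every enumerated solution realizes the minimum and respects the leaves
        for sol, evs in zip(r.solutions, r.all_events):
            assert len(evs) == r.parsimony_score
            for t, s in states.items():
                if s:
                    assert sol[t] == s


def test_every_event_appears_once_in_summary():
    statuses = [
        TaxonStatus("Hosa", "chrY", "coding"),
        TaxonStatus("Patr", "chrY", "non_coding"),
        TaxonStatus("Gogo", "chrY", "coding"),
        TaxonStatus("Mamu", "chrY", "non_coding"),
        TaxonStatus("Caja", "autosome", "non_coding"),
    ]
    r = infer_ancestral_state(PRIMATE_TREE, statuses)
    text = summarize_history(r)
    for ev in r.events:
        assert sum(ev.branch in line for line in text.splitlines()) >= 1
    assert len([l for l in text.splitlines()[1:] if l]) == len(r.events)
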