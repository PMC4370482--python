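"""K2P/TN93 distances, neighbor joining, bootstrap, Robinson-Foulds."""

import math

import dendropy
import numpy as np
import pytest

from orfdecay.phylo import (
    BootstrapConfig,
    DistanceMatrix,
    MultipleAlignment,
    SaturationError,
    bipartitions,
    bootstrap_support,
    distance_matrix,
    k2p_distance,
    nj_tree,
    robinson_foulds,
    tn93_distance,
)
from orfdecay.synthetic_data import simulate_k2p_alignment


def test_k2p_identical_is_zero():
    assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0


def test_k2p_closed_form_p01_q0():
    # 10 columns, 1 transition (A<->G): P=0.1, Q=0 -> -1/2 ln(0.8)
    a = "AAAAAAAAAA"
    b = "GAAAAAAAAA"
    assert k2p_distance(a, b) == pytest.approx(-0.5 * math.log(0.8))


def test_k2p_hand_computed_20_columns():
    # 20 columns, 2 transitions, 1 transversion: P=0.1, Q=0.05
    a = "A" * 20
    b = "G" + "G" + "C" + "A" * 17
    want = -0.5 * math.log((1 - 0.2 - 0.05) * math.sqrt(1 - 0.1))
    assert k2p_distance(a, b) == pytest.approx(want)


def test_k2p_pairwise_deletion_of_gaps_and_ambiguity():
    # gap and N columns excluded: effective length 10, one transition
    a = "AAAAAAAAAA" + "-N"
    b = "GAAAAAAAAA" + "CC"
    assert k2p_distance(a, b) == pytest.approx(-0.5 * math.log(0.8))


def test_k2p_saturation_raises():
    with pytest.raises(SaturationError):
        k2p_distance("ACACACAC", "CACACACA")


def test_k2p_symmetry(rng):
    recs = dict(simulate_k2p_alignment("(X:0.2,Y:0.2);", 500, 2.0, 3))
    assert k2p_distance(recs["X"], recs["Y"]) == pytest.approx(
        k2p_distance(recs["Y"], recs["X"])
    )


def test_tn93_identical_and_reduces_to_k2p_on_equal_frequencies():
    assert tn93_distance("ACGTACGT", "ACGTACGT") == 0.0
    recs = dict(simulate_k2p_alignment("(X:0.15,Y:0.15);", 20000, 2.0, 5))
    k2p = k2p_distance(recs["X"], recs["Y"])
    tn93 = tn93_distance(recs["X"], recs["Y"])
    assert tn93 == pytest.approx(k2p, rel=0.02)


def test_tn93_saturation_raises():
    with pytest.raises(SaturationError):
        tn93_distance("AGAGAGAGAC", "GAGAGAGACA")


def test_nj_three_taxa_closed_form():
    # d(AB)=0.3, d(AC)=0.5, d(BC)=0.6 -> vA=(0.3+0.5-0.6)/2=0.1, vB=0.2, vC=0.4
    D = DistanceMatrix(["A", "B", "C"], np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]))
    t = nj_tree(D)
    lengths = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
    assert lengths["A"] == pytest.approx(0.1)
    assert lengths["B"] == pytest.approx(0.2)
    assert lengths["C"] == pytest.approx(0.4)


def test_nj_recovers_additive_four_taxon_topology():
    # tree ((A,B),(C,D)) with all branches 1, internal 1
    d = {
        ("A", "B"): 2, ("C", "D"): 2,
        ("A", "C"): 3, ("A", "D"): 3, ("B", "C"): 3, ("B", "D"): 3,
    }
    taxa = ["A", "B", "C", "D"]
    mat = np.zeros((4, 4))
    for i, x in enumerate(taxa):
        for j, y in enumerate(taxa):
            if i != j:
                mat[i, j] = d[tuple(sorted((x, y)))]
    t = nj_tree(DistanceMatrix(taxa, mat))
    assert frozenset({"A", "B"}) in bipartitions(t) or frozenset({"C", "D"}) in bipartitions(t)


def test_nj_consistency_on_random_additive_matrices(rng):
    from oracles import random_binary_tree

    for _ in range(10):
        n = int(rng.integers(4, 9))
        taxa = [f"T{i}" for i in range(n)]
        newick = random_binary_tree(taxa, rng)
        ref = dendropy.Tree.get(data=newick, schema="newick")
        pdm = ref.phylogenetic_distance_matrix()
        tns = ref.taxon_namespace
        mat = np.zeros((n, n))
        for i, x in enumerate(taxa):
            for j, y in enumerate(taxa):
                if i != j:
                    mat[i, j] = pdm.patristic_distance(
                        tns.get_taxon(x), tns.get_taxon(y)
                    )
        t = nj_tree(DistanceMatrix(taxa, mat))
        assert robinson_foulds(t, ref) == 0


def test_nj_label_invariance_under_taxon_permutation(rng):
    recs = simulate_k2p_alignment(
        "((A:0.05,B:0.05):0.05,(C:0.05,D:0.05):0.05,E:0.1);", 2000, 2.0, 9
    )
    aln1 = MultipleAlignment(recs)
    aln2 = MultipleAlignment(list(reversed(recs)))
    t1 = nj_tree(distance_matrix(aln1))
    t2 = nj_tree(distance_matrix(aln2))
    assert robinson_foulds(t1, t2) == 0


def test_rf_identity_and_max_four_taxa():
    t1 = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
    t2 = dendropy.Tree.get(data="((A,C),(B,D));", schema="newick")
    assert robinson_foulds(t1, t1) == 0
    assert robinson_foulds(t1, t2) == 2


def test_rf_matches_dendropy_on_random_trees(rng):
    from oracles import random_binary_tree

    for _ in range(10):
        taxa = [f"T{i}" for i in range(int(rng.integers(4, 8)))]
        tns = dendropy.TaxonNamespace(taxa)
        t1 = dendropy.Tree.get(data=random_binary_tree(taxa, rng), schema="newick", taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=random_binary_tree(taxa, rng), schema="newick", taxon_namespace=tns)
        for t in (t1, t2):
            t.is_rooted = False
            t.update_bipartitions()
        want = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
        assert robinson_foulds(t1, t2) == want


def test_bootstrap_reproducible_and_bounded():
    recs = simulate_k2p_alignment(
        "((A:0.02,B:0.02):0.08,(C:0.02,D:0.02):0.08);", 1000, 2.0, 4
    )
    aln = MultipleAlignment(recs)
    cfg = BootstrapConfig(replicates=50, seed=11)
    t1 = bootstrap_support(aln, k2p_distance, cfg)
    t2 = bootstrap_support(aln, k2p_distance, cfg)
    s1 = sorted(n.label for n in t1.preorder_node_iter() if n.label and not n.is_leaf())
    s2 = sorted(n.label for n in t2.preorder_node_iter() if n.label and not n.is_leaf())
    assert s1 == s2
    assert all(0 <= float(s) <= 100 for s in s1)


def test_alignment_validation():
    with pytest.raises(ValueError, match="length"):
        MultipleAlignment([("a", "ACG"), ("b", "AC")])
    with pytest.raises(ValueError, match="duplicate"):
        MultipleAlignment([("a", "ACG"), ("a", "ACG")])
    with pytest.raises(ValueError, match="at least 3"):
        distance_matrix(MultipleAlignment([("a", "ACG"), ("b", "ACG")]))
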