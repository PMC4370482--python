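"""Distance-based phylogenetics: K2P/TN93 distances, neighbor joining,
nonparametric bootstrap, and Robinson-Foulds tree comparison.

K2P separates the transition proportion P from the transversion proportion Q
over pairwise-included columns:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

TN93 additionally distinguishes purine from pyrimidine transitions and uses
empirical base frequencies; it reduces towards K2P when frequencies are
equal. Columns with a gap or ambiguity in either sequence of a pair are
excluded for that pair (pairwise deletion), which maximizes usable signal on
short alignments. Saturated pairs (log arguments <= 0) raise ``SaturationError``.

Neighbor joining is the canonical agglomerative algorithm with deterministic
tie-breaking by lowest taxon-index pair; negative branch lengths are clamped
to zero (recorded on the tree annotation). Trees are dendropy ``Tree``
objects, so newick I/O comes for free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import dendropy
import numpy as np


class SaturationError(ValueError):
    """Observed divergence too high for the distance formula (log of non-positive)."""


@dataclass
class MultipleAlignment:
    """Aligned nucleotide sequences, one per taxon."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.records}
        if len(lengths) > 1:
            raise ValueError("aligned sequences differ in length")
        names = [t for t, _ in self.records]
        if len(set(names)) != len(names):
            raise ValueError("duplicate taxon names")

    @property
    def taxa(self) -> list[str]:
        return [t for t, _ in self.records]

    @property
    def length(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    def columns(self, idx: np.ndarray) -> "MultipleAlignment":
        return MultipleAlignment(
            [(t, "".join(s[i] for i in idx)) for t, s in self.records]
        )


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise ValueError("distances must be finite and nonnegative")


@dataclass(frozen=True)
class BootstrapConfig:
    replicates: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}
_PURINE = {0, 2}


def _counts(seq_a: str, seq_b: str) -> tuple[int, int, int, int, int, np.ndarray]:
    """Included columns, transitions (purine, pyrimidine split), transversions,
    plus base counts over both sequences on included columns."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    n = ti_ag = ti_ct = tv = 0
    base_counts = np.zeros(4, dtype=float)
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        a = _ENC.get(x)
        b = _ENC.get(y)
        if a is None or b is None:
            continue
        n += 1
        base_counts[a] += 1
        base_counts[b] += 1
        if a == b:
            continue
        if (a in _PURINE) == (b in _PURINE):
            if a in _PURINE:
                ti_ag += 1
            else:
                ti_ct += 1
        else:
            tv += 1
    return n, ti_ag, ti_ct, tv, ti_ag + ti_ct, base_counts


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura two-parameter distance with pairwise deletion of gap/ambiguity columns."""
    n, _, _, tv, ti, _ = _counts(seq_a, seq_b)
    if n == 0:
        raise ValueError("no comparable columns")
    P, Q = ti / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"saturated pair: P={P:.3f}, Q={Q:.3f}")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def tn93_distance(seq_a: str, seq_b: str) -> float:
    """Tamura-Nei (1993) distance with empirical base frequencies."""
    n, ti_ag, ti_ct, tv, _, base_counts = _counts(seq_a, seq_b)
    if n == 0:
        raise ValueError("no comparable columns")
    g = base_counts / base_counts.sum()
    gA, gC, gG, gT = g
    gR, gY = gA + gG, gC + gT
    if min(gA, gC, gG, gT) == 0:
        # degenerate composition: fall back to the K2P special case
        return k2p_distance(seq_a, seq_b)
    P1, P2, Q = ti_ag / n, ti_ct / n, tv / n
    k1 = 2.0 * gA * gG / gR
    k2 = 2.0 * gC * gT / gY
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    w1 = 1.0 - P1 / k1 - Q / (2.0 * gR)
    w2 = 1.0 - P2 / k2 - Q / (2.0 * gY)
    w3 = 1.0 - Q / (2.0 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        raise SaturationError("saturated pair under TN93")
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def distance_matrix(
    aln: MultipleAlignment, distance_fn: Callable[[str, str], float] = k2p_distance
) -> DistanceMatrix:
    n = len(aln.records)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = distance_fn(aln.records[i][1], aln.records[j][1])
    return DistanceMatrix(aln.taxa, d)


def nj_tree(D: DistanceMatrix) -> dendropy.Tree:
    """Canonical neighbor joining, deterministic tie-breaking by lowest taxon-index pair.

    Returns an unrooted dendropy tree (trifurcating seed node). Negative
    branch lengths are clamped to 0; clamped edges are listed in
    ``tree.annotations`` under "clamped_edges".
    """
    taxa = list(D.taxa)
    n = len(taxa)
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes: dict[int, dendropy.Node] = {}
    for i, t in enumerate(taxa):
        node = dendropy.Node(taxon=tns.get_taxon(t))
        nodes[i] = node
    d = {(i, j): float(D.d[i, j]) for i in range(n) for j in range(n)}
    active = list(range(n))
    next_id = n
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        R = {i: sum(d[(i, j)] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (r - 2) * d[(i, j)] - R[i] - R[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        vi = 0.5 * d[(i, j)] + (R[i] - R[j]) / (2.0 * (r - 2))
        vj = d[(i, j)] - vi
        parent = dendropy.Node()
        ni, nj_ = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj_)
        ni.edge.length = clamp(vi)
        nj_.edge.length = clamp(vj)
        nodes[next_id] = parent
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d[(i, k)] + d[(j, k)] - d[(i, j)])
            d[(next_id, k)] = d[(k, next_id)] = dk
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    seed = dendropy.Node()
    if len(active) == 3:
        i, j, k = active
        vi = 0.5 * (d[(i, j)] + d[(i, k)] - d[(j, k)])
        vj = 0.5 * (d[(i, j)] + d[(j, k)] - d[(i, k)])
        vk = 0.5 * (d[(i, k)] + d[(j, k)] - d[(i, j)])
        for idx, v in ((i, vi), (j, vj), (k, vk)):
            seed.add_child(nodes[idx])
            nodes[idx].edge.length = clamp(v)
    elif len(active) == 2:
        i, j = active
        for idx, v in ((i, d[(i, j)] / 2), (j, d[(i, j)] / 2)):
            seed.add_child(nodes[idx])
            nodes[idx].edge.length = clamp(v)
    else:
        seed = nodes[active[0]]
    tree.seed_node = seed
    tree.is_rooted = False
    tree.annotations.add_new("clamped_edges", clamped)
    return tree


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions, each canonicalized to the side not
    containing the lexicographically smallest taxon."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    anchor = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if len(side) < 2 or len(leaves - side) < 2:
            continue
        canon = frozenset(leaves - side) if anchor in side else frozenset(side)
        out.add(canon)
    return out


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Symmetric bipartition (Robinson-Foulds) distance between unrooted trees."""
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    b1, b2 = bipartitions(t1), bipartitions(t2)
    return len(b1 ^ b2)


def bootstrap_support(
    aln: MultipleAlignment,
    distance_fn: Callable[[str, str], float] = k2p_distance,
    config: BootstrapConfig = BootstrapConfig(),
) -> dendropy.Tree:
    """Nonparametric bootstrap: resample columns with replacement, rebuild the
    NJ tree, and attach per-bipartition support (percent of replicates) to the
    internal nodes of the point-estimate tree."""
    tree = nj_tree(distance_matrix(aln, distance_fn))
    counts: dict[frozenset[str], int] = {b: 0 for b in bipartitions(tree)}
    rng = np.random.default_rng(config.seed)
    L = aln.length
    done = 0
    for _ in range(config.replicates):
        idx = rng.integers(0, L, size=L)
        rep = aln.columns(idx)
        try:
            rep_tree = nj_tree(distance_matrix(rep, distance_fn))
        except (SaturationError, ValueError):
            continue
        done += 1
        for b in bipartitions(rep_tree):
            if b in counts:
                counts[b] += 1
    denom = max(done, 1)
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    anchor = min(leaves)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if len(side) < 2 or len(leaves - side) < 2:
            continue
        canon = frozenset(leaves - side) if anchor in side else frozenset(side)
        node.label = f"{100.0 * counts.get(canon, 0) / denom:.0f}"
    tree.annotations.add_new("bootstrap_replicates", done)
    return tree


def read_alignment_fasta(path) -> MultipleAlignment:
    from orfdecay.core_io import read_fasta

    return MultipleAlignment([(r.id, r.seq) for r in read_fasta(path)])
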