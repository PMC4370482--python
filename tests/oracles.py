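"""Independent brute-force oracles used by the test suite.

Each oracle is a deliberately naive re-computation of a quantity the package
computes by a smarter route; none of them share code with the implementation.
"""

from __future__ import annotations

import itertools
from typing import Sequence

NEG_INF = float("-inf")


def semiglobal_score(
    query: str,
    target: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> float:
    """Quadratic Gotoh DP for affine-gap semi-global alignment.

    The query (exon) is aligned end to end; target (region) overhangs at
    either end are free. gap_open is the score of the first gap position.
    """
    m, n = len(query), len(target)

    def s(a: str, b: str) -> float:
        if a not in "ACGT" or b not in "ACGT":
            return 0.0
        return match if a == b else mismatch

    # M: last column aligned pair; X: gap in query (target base internal-skipped);
    # Y: gap in target (query base vs '-')
    M = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    X = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    # leading target overhang is free: "state L" with score 0 at (0, j)
    L0 = [0.0] * (n + 1)
    for i in range(1, m + 1):
        Y[i][0] = gap_open + gap_extend * (i - 1)
        for j in range(0, n + 1):
            if j > 0:
                prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
                if i == 1:
                    prev = max(prev, L0[j - 1])
                if prev > NEG_INF:
                    M[i][j] = prev + s(query[i - 1], target[j - 1])
                X[i][j] = max(
                    M[i][j - 1] + gap_open,
                    X[i][j - 1] + gap_extend,
                    Y[i][j - 1] + gap_open,
                )
            cand = [M[i - 1][j] + gap_open, Y[i - 1][j] + gap_extend]
            if j > 0:
                cand.append(X[i - 1][j] + gap_open)
            if i == 1:
                cand.append(L0[j] + gap_open)
            Y[i][j] = max(Y[i][j], *cand)
    # trailing target overhang is free: best over all j, not ending in X
    return max(max(M[m][j], Y[m][j]) for j in range(n + 1))


def brute_dotplot(
    seq_a: str, seq_b: str, window: int, max_mismatch: int, both_strands: bool = False
) -> set[tuple[int, int, str]]:
    """All window pairs compared directly, one by one."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

    def rc(s: str) -> str:
        return "".join(comp[c] for c in reversed(s))

    def near(wa: str, wb: str) -> bool:
        mm = 0
        for x, y in zip(wa, wb):
            if x != y:
                mm += 1
                if mm > max_mismatch:
                    return False
        return True

    out: set[tuple[int, int, str]] = set()
    wins_a = [seq_a[i : i + window] for i in range(len(seq_a) - window + 1)]
    wins_b = [seq_b[j : j + window] for j in range(len(seq_b) - window + 1)]
    for i, wa in enumerate(wins_a):
        for j, wb in enumerate(wins_b):
            if near(wa, wb):
                out.add((i, j, "+"))
            if both_strands and near(wa, rc(wb)):
                out.add((i, j, "-"))
    return out


def exhaustive_parsimony(
    children: dict[str, list[str]],
    root: str,
    leaf_states: dict[str, str | None],
    states: tuple[str, str] = ("coding", "non_coding"),
) -> int:
    """Minimum number of state changes over all labelings of internal nodes
    and missing-data leaves (tree given as child lists)."""
    nodes = list(children)

    def leaves_below(v: str) -> list[str]:
        if not children[v]:
            return [v]
        return [x for c in children[v] for x in leaves_below(c)]

    free = [v for v in nodes if children[v]] + [
        v for v in nodes if not children[v] and leaf_states.get(v) is None
    ]
    fixed = {v: leaf_states[v] for v in nodes if not children[v] and leaf_states.get(v)}
    best = None
    for combo in itertools.product(states, repeat=len(free)):
        lab = dict(fixed)
        lab.update(dict(zip(free, combo)))
        cost = sum(
            1
            for v in nodes
            for c in children[v]
            if lab[v] != lab[c]
        )
        best = cost if best is None else min(best, cost)
    return best


def refilter(rows: Sequence[dict], length_min: int, identity_min: float) -> list[dict]:
    """Row-by-row re-filter of a hit table (strict inequalities)."""
    kept = [r for r in rows if r["length"] > length_min and r["identity"] > identity_min]
    return sorted(kept, key=lambda r: (r["subject"], r["sstart"], r["send"]))


def random_binary_tree(taxa: list[str], rng) -> str:
    """Random binary newick with branch lengths, by successive random joins."""
    nodes = [(t, f"{t}:{rng.uniform(0.05, 0.3):.4f}") for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (_, a), (_, b) = nodes[i], nodes[j]
        merged = f"({a},{b}):{rng.uniform(0.05, 0.3):.4f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(("", merged))
    return nodes[0][1].rsplit(":", 1)[0] + ";"
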