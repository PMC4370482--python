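"""Cross-taxon shared-disabler analysis and parsimony reconstruction of
coding-ability gains/losses on a species tree.

Disablers shared across taxa at the same projected reference offset argue
for a common non-coding ancestral state; the package operationalizes the
ancestry argument as small parsimony (Fitch/Sankoff with unit costs) on the
binary coding/non-coding character, with "absent" and "unknown" treated as
missing data. All minimum-change labelings are enumerated so ties are
explicit rather than silently resolved.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import pandas as pd

from orfdecay.disabler_scan import Disabler, DisablerReport

CODING, NON_CODING = "coding", "non_coding"
_STATES = (CODING, NON_CODING)


@dataclass
class TaxonStatus:
    taxon: str
    compartment: str  # autosome | chrY | chrX
    coding_ability: str  # coding | non_coding | absent | unknown
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.compartment not in ("autosome", "chrY", "chrX"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.coding_ability not in (CODING, NON_CODING, "absent", "unknown"):
            raise ValueError(f"unknown coding ability {self.coding_ability!r}")


@dataclass
class SharedDisablerMatrix:
    """Rows = disabler keys (type, ref offset), columns = taxa/ORFs;
    cells in {present, absent, unknown}."""

    table: pd.DataFrame  # index: (type, offset) tuples; columns: taxon keys

    @property
    def ancestral_candidates(self) -> list[tuple[str, int]]:
        """Keys present in every column with known state."""
        out = []
        for key, row in self.table.iterrows():
            known = row[row != "unknown"]
            if len(known) and (known == "present").all():
                out.append(key)
        return out


def build_shared_matrix(
    reports: Mapping[str, DisablerReport], tolerance: int = 0
) -> SharedDisablerMatrix:
    """Match disablers across taxa by (type, projected reference offset).

    With a nonzero tolerance, offsets of the same type within ``tolerance``
    nt are clustered (greedily, in offset order) onto the smallest offset of
    the cluster. Rows are ordered by offset then type.
    """
    all_keys: list[tuple[str, int]] = sorted(
        {d.key() for rep in reports.values() for d in rep.disablers},
        key=lambda k: (k[0], k[1]),
    )
    canon: dict[tuple[str, int], tuple[str, int]] = {}
    for typ, group in itertools.groupby(all_keys, key=lambda k: k[0]):
        rep_offset = None
        for _, off in group:
            if rep_offset is None or off - rep_offset > tolerance:
                rep_offset = off
            canon[(typ, off)] = (typ, rep_offset)
    rows = sorted(set(canon.values()), key=lambda k: (k[1], k[0]))
    cols = sorted(reports)
    data = {}
    for col in cols:
        present = {canon[d.key()] for d in reports[col].disablers}
        covered = reports[col].alignment is not None
        data[col] = [
            "present" if key in present else ("absent" if covered else "unknown")
            for key in rows
        ]
    index = (
        pd.MultiIndex.from_tuples(rows, names=["type", "offset"])
        if rows
        else pd.MultiIndex.from_arrays([[], []], names=["type", "offset"])
    )
    table = pd.DataFrame(data, index=index)
    return SharedDisablerMatrix(table)


@dataclass
class BranchEvent:
    branch: str  # label of the child node the branch leads to
    event: str  # gain_coding | loss_coding
    label: str = ""


@dataclass
class EventReconstruction:
    tree: dendropy.Tree
    parsimony_score: int
    solutions: list[dict[str, str]]  # node label -> state, one dict per minimal labeling
    events: list[BranchEvent] = field(default_factory=list)  # events of solutions[0]
    all_events: list[list[BranchEvent]] = field(default_factory=list)


def _label_nodes(tree: dendropy.Tree) -> None:
    """Give every node a unique, deterministic label (leaf taxa keep theirs)."""
    i = 0
    for node in tree.preorder_node_iter():
        if node.taxon is not None:
            node.label = node.taxon.label
        elif not node.label:
            node.label = f"node{i}"
        i += 1


def infer_ancestral_state(
    species_tree: dendropy.Tree | str,
    statuses: Sequence[TaxonStatus],
) -> EventReconstruction:
    """Minimum-change (unit-cost Sankoff) labeling of coding ability.

    Leaves with status absent/unknown are missing data and may take either
    state at no cost. All minimal labelings are enumerated; branch events
    (gain_coding / loss_coding) are read off each labeling. Branches are
    named by the label of the node they lead to.
    """
    if isinstance(species_tree, str):
        tree = dendropy.Tree.get(data=species_tree, schema="newick")
    else:
        tree = species_tree.clone(depth=1)
    _label_nodes(tree)
    leaf_state: dict[str, set[str]] = {}
    for s in statuses:
        if s.coding_ability in _STATES:
            leaf_state.setdefault(s.taxon, set()).add(s.coding_ability)
    known = {t for t, st in leaf_state.items() if st}
    if len(known) < 2:
        raise ValueError("need at least 2 taxa with known coding state")
    tree_leaves = {lf.label for lf in tree.leaf_node_iter()}
    missing = known - tree_leaves
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)}")

    INF = float("inf")
    cost: dict[str, dict[str, float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            allowed = leaf_state.get(node.label) or set(_STATES)
            cost[node.label] = {s: (0.0 if s in allowed else INF) for s in _STATES}
        else:
            cost[node.label] = {
                s: sum(
                    min(cost[c.label][t] + (s != t) for t in _STATES)
                    for c in node.child_nodes()
                )
                for s in _STATES
            }
    root = tree.seed_node
    score = min(cost[root.label].values())

    # enumerate all optimal labelings top-down
    solutions: list[dict[str, str]] = []

    def expand(node, state, assignment):
        assignment = dict(assignment)
        assignment[node.label] = state
        children = node.child_nodes()
        if not children:
            yield assignment
            return
        per_child_options = []
        for c in children:
            best = min(cost[c.label][t] + (state != t) for t in _STATES)
            per_child_options.append(
                [t for t in _STATES if cost[c.label][t] + (state != t) == best]
            )
        for combo in itertools.product(*per_child_options):
            partials = [assignment]
            for c, t in zip(children, combo):
                new_partials = []
                for p in partials:
                    for sub in expand(c, t, p):
                        new_partials.append(sub)
                partials = new_partials
            yield from partials

    for s in _STATES:
        if cost[root.label][s] == score:
            solutions.extend(expand(root, s, {}))
    # deduplicate and order deterministically
    uniq = {tuple(sorted(sol.items())): sol for sol in solutions}
    solutions = [dict(t) for t in sorted(uniq)]

    def events_of(sol: dict[str, str]) -> list[BranchEvent]:
        evs = []
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            ps, cs = sol[node.parent_node.label], sol[node.label]
            if ps != cs:
                evs.append(
                    BranchEvent(
                        branch=node.label,
                        event="gain_coding" if cs == CODING else "loss_coding",
                    )
                )
        return evs

    all_events = [events_of(sol) for sol in solutions]
    return EventReconstruction(
        tree=tree,
        parsimony_score=int(score),
        solutions=solutions,
        events=all_events[0] if all_events else [],
        all_events=all_events,
    )


def summarize_history(
    reconstruction: EventReconstruction,
    named_splits: Mapping[str, str] | None = None,
) -> str:
    """Render each inferred event as text using the supplied branch-label map.

    ``named_splits`` maps a branch (child-node label) to a human-readable
    split description; no dating is computed.
    """
    named_splits = named_splits or {}
    if not reconstruction.events:
        return "no state changes inferred"
    lines = [
        f"parsimony score {reconstruction.parsimony_score}; "
        f"{len(reconstruction.solutions)} minimal labeling(s)"
    ]
    for ev in reconstruction.events:
        what = (
            "gain of coding ability" if ev.event == "gain_coding" else "loss of coding ability"
        )
        where = named_splits.get(ev.branch, f"on the branch to {ev.branch}")
        lines.append(f"{what} {where}")
    return "\n".join(lines)


def read_status_tsv(path) -> list[TaxonStatus]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"taxon", "compartment", "coding_ability"}
    if not required <= set(df.columns):
        raise ValueError(f"status TSV must have columns {sorted(required)}")
    return [
        TaxonStatus(
            taxon=row["taxon"],
            compartment=row["compartment"],
            coding_ability=row["coding_ability"],
            evidence=row.get("evidence", "") or "",
        )
        for _, row in df.iterrows()
    ]
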