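"""Most probable per-column indel scenario under PIP.

Given the gap pattern of one alignment column (presence/absence of a residue
at each leaf), infer where on the tree the character was inserted and on
which branches it was deleted. Under PIP a character is inserted exactly once
(no re-insertion after deletion), so the insertion node must be the MRCA of
the present leaves or one of its ancestors; deletions are permanent, so the
deleted branches form an antichain (none below another) covering exactly the
absent leaves.

The maximization is a two-pass dynamic program over the tree. For each node
``u`` with branch length ``b`` let ``s = exp(-mu*b)`` (character survives the
branch) and ``d = 1 - s`` (character dies on the branch). For a subtree with
no present leaf the best explanation is either deletion on the branch into it
or survival into the node followed by the best explanations below
(``D[u] = max(log d, log s + sum_c D[c])``); for a subtree containing present
leaves the character must survive the branch
(``A[u] = log s + sum_c (A[c] or D[c])``). A candidate insertion node ``v``
scores ``log iota(v) + log beta(v) + sum over v's children of A/D``; the
scenario is the argmax over candidates with deletions read off the
maximizing backtrack.

Character states never enter: the scenario depends on the gap pattern only,
so neighbouring columns with identical patterns receive identical histories
— this is what lets single-character inference preserve long indels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .pip_model import PIPParams, branch_survival, insertion_intensity, survival_factor
from .tree import PhyloTree, TreeNode

__all__ = [
    "GapPattern",
    "IndelScenario",
    "candidate_insertion_nodes",
    "most_probable_scenario",
    "scenario_log_prob",
]


@dataclass(frozen=True)
class GapPattern:
    """Presence/absence of a residue over the leaves for one column."""

    column_index: int
    presence: dict[str, int]

    def present_leaves(self) -> frozenset[str]:
        return frozenset(l for l, p in self.presence.items() if p)

    def validate(self) -> None:
        if not any(self.presence.values()):
            raise ValueError(
                f"column {self.column_index}: all-gap pattern is invalid")

    def __hash__(self):  # patterns are cache keys; dict is not hashable
        return hash((self.column_index, tuple(sorted(self.presence.items()))))


@dataclass
class IndelScenario:
    """One column's inferred indel history.

    ``insertion_node`` is where the character first existed;
    ``deletion_branches`` names child nodes of branches on which it was
    deleted; ``alive_nodes`` is the connected set of nodes carrying the
    character; ``log_prob`` is the achieved log score.
    """

    column_index: int
    insertion_node: str
    deletion_branches: frozenset[str]
    alive_nodes: frozenset[str]
    log_prob: float


def candidate_insertion_nodes(tree: PhyloTree, pattern: GapPattern) -> list[TreeNode]:
    """Nodes at which the column's character may have been inserted.

    Returns the path from the MRCA of the present leaves up to the root,
    ordered from the MRCA upward.
    """
    pattern.validate()
    node = tree.mrca(pattern.present_leaves())
    path = [node]
    while not node.is_root:
        node = node.parent
        path.append(node)
    return path


def _log(x: float) -> float:
    return math.log(x) if x > 0 else -math.inf


def _subtree_tables(tree: PhyloTree, params: PIPParams, present: frozenset[str]):
    """Postorder A/D score tables and per-node bookkeeping.

    Returns (has_present, A, D, del_here) keyed by node id, where
    ``del_here[u]`` records whether the deletion option won D[u]
    (ties prefer the deletion, i.e. the single higher event).
    """
    has_present: dict[str, bool] = {}
    A: dict[str, float] = {}
    D: dict[str, float] = {}
    del_here: dict[str, bool] = {}
    for node in tree.postorder():
        if node.is_leaf:
            has_present[node.id] = node.id in present
        else:
            has_present[node.id] = any(has_present[c.id] for c in node.children)
        if node.is_root:
            continue
        s = branch_survival(params, node.branch_length)
        log_s, log_d = _log(s), _log(1.0 - s)
        if has_present[node.id]:
            total = log_s
            for c in node.children:
                total += A[c.id] if has_present[c.id] else D[c.id]
            A[node.id] = total
        else:
            survive = log_s + sum(D[c.id] for c in node.children)
            if node.is_leaf:
                D[node.id] = log_d
                del_here[node.id] = True
            elif log_d >= survive:
                D[node.id] = log_d
                del_here[node.id] = True
            else:
                D[node.id] = survive
                del_here[node.id] = False
    return has_present, A, D, del_here


def most_probable_scenario(tree: PhyloTree, params: PIPParams,
                           pattern: GapPattern) -> IndelScenario:
    """Maximum-probability (insertion node, deletion branches) explanation.

    Ties between candidate insertion nodes are broken towards the node
    closest to the MRCA of the present leaves; ties inside an absent
    subtree are broken towards the single higher deletion. Both rules favor
    the most parsimonious of the equally likely scenarios and make the
    result deterministic.
    """
    pattern.validate()
    present = pattern.present_leaves()
    has_present, A, D, del_here = _subtree_tables(tree, params, present)

    best_v, best_score = None, -math.inf
    for v in candidate_insertion_nodes(tree, pattern):
        score = (_log(insertion_intensity(tree, params, v))
                 + _log(survival_factor(params, v)))
        for c in v.children:
            score += A[c.id] if has_present[c.id] else D[c.id]
        if score > best_score:
            best_v, best_score = v, score

    alive = {best_v.id}
    deletions: set[str] = set()

    def walk(node: TreeNode) -> None:
        for c in node.children:
            if has_present[c.id]:
                alive.add(c.id)
                walk(c)
            elif del_here[c.id]:
                deletions.add(c.id)
            else:
                alive.add(c.id)
                walk(c)

    walk(best_v)
    return IndelScenario(
        column_index=pattern.column_index,
        insertion_node=best_v.id,
        deletion_branches=frozenset(deletions),
        alive_nodes=frozenset(alive),
        log_prob=best_score,
    )


def scenario_log_prob(tree: PhyloTree, params: PIPParams,
                      scenario: IndelScenario) -> float:
    """Re-score a scenario; raises if it is internally inconsistent.

    The score is ``log iota(v) + log beta(v)`` for the insertion node plus
    ``log s(b)`` for every surviving branch below it and ``log d(b)`` for
    every deletion branch; branches below a deletion contribute nothing.
    """
    v = tree.by_id[scenario.insertion_node]
    deletions = set(scenario.deletion_branches)
    score = (_log(insertion_intensity(tree, params, v))
             + _log(survival_factor(params, v)))
    alive = {v.id}

    def walk(node: TreeNode) -> float:
        total = 0.0
        for c in node.children:
            s = branch_survival(params, c.branch_length)
            if c.id in deletions:
                below = _collect_below(c)
                if below & deletions:
                    raise ValueError(
                        f"deletion branch below deletion branch: {sorted(below & deletions)}")
                total += _log(1.0 - s)
            else:
                alive.add(c.id)
                total += _log(s) + walk(c)
        return total

    score += walk(v)
    unreachable = deletions - {c.id for n in map(tree.by_id.get, alive)
                               for c in n.children}
    if unreachable:
        raise ValueError(f"deletion branches not below the alive set: {sorted(unreachable)}")
    if frozenset(alive) != scenario.alive_nodes:
        raise ValueError("alive_nodes inconsistent with insertion node and deletions")
    return score


def _collect_below(node: TreeNode) -> set[str]:
    out = set()
    stack = list(node.children)
    while stack:
        n = stack.pop()
        out.add(n.id)
        stack.extend(n.children)
    return out
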