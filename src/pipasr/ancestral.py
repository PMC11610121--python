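"""Joint maximum-likelihood ancestral residues on the scenario-pruned tree.

For each alignment column the inferred indel scenario fixes the set of nodes
that carry a character; the character's substitution history is then confined
to the subtree induced by those nodes, rooted at the insertion node. Within
that subtree the jointly most likely assignment of residues to the internal
nodes is found with the classic max-product dynamic program (Pupko-style):
a bottom-up pass propagates, for every possible parent state, the best state
and score of each subtree, and a top-down pass reads off the argmax. The
insertion node takes the model equilibrium ``pi`` as its prior.

Ambiguity codes at leaves (X, B, Z) are treated as the set of compatible
residues, maximized over in the bottom-up pass. Ties are broken by alphabet
order for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .history import GapPattern, IndelScenario, most_probable_scenario
from .pip_model import PIPParams
from .substitution import AMBIGUITY_CODES, SubstitutionModel, wag_model
from .tree import PhyloTree, TreeNode

__all__ = [
    "AncestralReconstruction",
    "prune_to_alive",
    "joint_ml_characters",
    "reconstruct_alignment",
]

GAP = "-"


@dataclass
class AncestralReconstruction:
    """Inferred ancestral rows plus the per-column indel scenarios."""

    msa_columns: int
    ancestral_rows: dict[str, str]
    scenarios: list[IndelScenario]


def prune_to_alive(tree: PhyloTree, scenario: IndelScenario) -> PhyloTree:
    """Subtree induced by the scenario's alive nodes, rooted at the
    insertion node, with branch lengths preserved."""
    alive = scenario.alive_nodes

    def build(node: TreeNode) -> TreeNode:
        clone = TreeNode(node.id, node.branch_length)
        for c in node.children:
            if c.id in alive:
                clone.add_child(build(c))
        return clone

    root = build(tree.by_id[scenario.insertion_node])
    root.branch_length = 0.0
    return PhyloTree(root)


def _leaf_state_scores(model: SubstitutionModel, residue: str) -> np.ndarray:
    """Log-indicator vector over states compatible with a leaf symbol."""
    k = len(model.alphabet)
    out = np.full(k, -np.inf)
    if residue in AMBIGUITY_CODES:
        for r in AMBIGUITY_CODES[residue]:
            out[model.state_index(r)] = 0.0
    else:
        out[model.state_index(residue)] = 0.0
    return out


def joint_ml_characters(pruned: PhyloTree, model: SubstitutionModel,
                        leaf_states: dict[str, str]) -> dict[str, str]:
    """Jointly most likely residues at the internal nodes of ``pruned``.

    ``leaf_states`` maps observed leaf labels to a residue (or ambiguity
    code). Pruned-tree leaves absent from ``leaf_states`` are unobserved
    ancestors (their descendants were all deleted); they are assigned a
    residue like any other ancestral node. Returns a map from every
    unobserved node label to its residue. Unknown symbols raise ``KeyError``.
    """
    k = len(model.alphabet)
    observed = set(leaf_states)
    if len(pruned.nodes) == 1:
        node = pruned.root
        if node.id in observed:
            return {}
        # lone unobserved node: maximize the prior
        return {node.id: model.alphabet[int(np.argmax(model.equilibrium))]}

    # bottom-up: best[u][i] = best log-lik of u's subtree given parent state i
    best_score: dict[str, np.ndarray] = {}
    best_state: dict[str, np.ndarray] = {}
    for node in pruned.postorder():
        if node.is_root:
            continue
        logp = model.log_transition_matrix(node.branch_length)
        if node.id in observed:
            msg = _leaf_state_scores(model, leaf_states[node.id])
        else:
            msg = np.zeros(k)
            for c in node.children:
                msg = msg + best_score[c.id]
        scores = logp + msg[None, :]
        best_state[node.id] = np.argmax(scores, axis=1)
        best_score[node.id] = scores[np.arange(k), best_state[node.id]]

    root = pruned.root
    assignment: dict[str, str] = {}
    states: dict[str, int] = {}
    if root.id in observed:
        scores = _leaf_state_scores(model, leaf_states[root.id])
        states[root.id] = int(np.argmax(np.log(model.equilibrium) + scores))
    else:
        root_msg = np.log(model.equilibrium)
        for c in root.children:
            root_msg = root_msg + best_score[c.id]
        states[root.id] = int(np.argmax(root_msg))
        assignment[root.id] = model.alphabet[states[root.id]]
    for node in pruned.preorder():
        if node.is_root:
            continue
        s = int(best_state[node.id][states[node.parent.id]])
        states[node.id] = s
        if node.id not in observed:
            assignment[node.id] = model.alphabet[s]
    return assignment


def reconstruct_alignment(tree: PhyloTree, params: PIPParams,
                          model: SubstitutionModel | None,
                          leaf_msa: dict[str, str]) -> AncestralReconstruction:
    """Two-stage ancestral reconstruction of a leaf alignment.

    Per column: infer the most probable indel scenario from the gap pattern,
    prune the tree to the scenario's alive nodes, and assign joint-ML
    residues to the internal alive nodes; non-alive ancestral cells become
    gaps. Columns are independent; identical leaf columns yield identical
    ancestral cells.
    """
    model = model or wag_model()
    leaf_names = set(leaf_msa)
    if leaf_names != tree.leaf_names:
        raise ValueError(
            "leaf names do not match the tree: "
            f"missing={sorted(tree.leaf_names - leaf_names)} "
            f"extra={sorted(leaf_names - tree.leaf_names)}")
    lengths = {len(s) for s in leaf_msa.values()}
    if len(lengths) > 1:
        raise ValueError("alignment rows have unequal lengths")
    ncol = lengths.pop() if lengths else 0

    internal = [n.id for n in tree.internal_nodes()]
    rows = {v: [] for v in internal}
    scenarios: list[IndelScenario] = []
    order = sorted(leaf_names)

    scenario_cache: dict[frozenset, tuple[IndelScenario, PhyloTree]] = {}
    column_cache: dict[tuple, dict[str, str]] = {}

    for col in range(ncol):
        residues = {l: leaf_msa[l][col] for l in order}
        presence = frozenset(l for l, r in residues.items() if r != GAP)
        if not presence:
            raise ValueError(f"column {col} is all-gap")

        cached = scenario_cache.get(presence)
        if cached is None:
            pattern = GapPattern(column_index=col,
                                 presence={l: int(r != GAP) for l, r in residues.items()})
            scenario = most_probable_scenario(tree, params, pattern)
            pruned = prune_to_alive(tree, scenario)
            scenario_cache[presence] = (scenario, pruned)
        else:
            scenario, pruned = cached
        scenario = IndelScenario(col, scenario.insertion_node,
                                 scenario.deletion_branches,
                                 scenario.alive_nodes, scenario.log_prob)
        scenarios.append(scenario)

        key = tuple(residues[l] for l in order)
        cells = column_cache.get(key)
        if cells is None:
            leaf_states = {l: residues[l] for l in presence}
            assignment = joint_ml_characters(pruned, model, leaf_states)
            cells = {}
            for v in internal:
                cells[v] = assignment[v] if v in scenario.alive_nodes else GAP
            column_cache[key] = cells
        for v in internal:
            rows[v].append(cells[v])

    ancestral_rows = {v: "".join(r) for v, r in rows.items()}
    return AncestralReconstruction(msa_columns=ncol,
                                   ancestral_rows=ancestral_rows,
                                   scenarios=scenarios)
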