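import itertools

import numpy as np
import pytest

import pipasr as p
from pipasr.history import GapPattern, IndelScenario
from test_history import brute_force_scenario


def joint_log_likelihood(tree, model, states):
    """Log-likelihood of a full assignment (states: label -> state index)."""
    ll = np.log(model.equilibrium[states[tree.root.id]])
    for n in tree.nodes:
        if n.is_root:
            continue
        P = model.transition_matrix(n.branch_length)
        ll += np.log(P[states[n.parent.id], states[n.id]])
    return ll


def brute_force_joint_ml(tree, model, leaf_states):
    unknown = [n.id for n in tree.nodes if n.id not in leaf_states]
    fixed = {l: model.state_index(r) for l, r in leaf_states.items()}
    best = (-np.inf, None)
    for combo in itertools.product(range(20), repeat=len(unknown)):
        states = {**fixed, **dict(zip(unknown, combo))}
        ll = joint_log_likelihood(tree, model, states)
        if ll > best[0] + 1e-12:
            best = (ll, {u: model.alphabet[states[u]] for u in unknown})
    return best


class TestPruneToAlive:
    def test_all_present_returns_full_tree(self, fixture_tree, pip_params):
        pat = GapPattern(0, {l: 1 for l in fixture_tree.leaf_names})
        sc = p.most_probable_scenario(fixture_tree, pip_params, pat)
        pruned = p.prune_to_alive(fixture_tree, sc)
        assert {n.id for n in pruned.nodes} == {n.id for n in fixture_tree.nodes}
        assert pruned.tau == pytest.approx(fixture_tree.tau)

    def test_single_leaf_scenario(self, fixture_tree, pip_params):
        sc = IndelScenario(0, "Human", frozenset(), frozenset({"Human"}), 0.0)
        pruned = p.prune_to_alive(fixture_tree, sc)
        assert len(pruned.nodes) == 1
        assert pruned.root.id == "Human"

    def test_one_deletion_removes_clade_only(self, fixture_tree, pip_params):
        pres = {l: int(l not in {"Mouse", "Rat"})
                for l in fixture_tree.leaf_names}
        sc = p.most_probable_scenario(fixture_tree, pip_params,
                                      GapPattern(0, pres))
        if sc.insertion_node == "root" and sc.deletion_branches == {"Murinae"}:
            pruned = p.prune_to_alive(fixture_tree, sc)
            assert "Murinae" not in {n.id for n in pruned.nodes}
            for n in pruned.nodes:
                if not n.is_root:
                    assert n.branch_length == \
                        fixture_tree.by_id[n.id].branch_length
        else:
            pruned = p.prune_to_alive(fixture_tree, sc)
            assert {l for l in pruned.leaf_names} >= {
                "Human", "Chimp", "Gorilla", "Macaque"}


class TestJointMLCharacters:
    def test_single_node_tree_empty_map(self, wag):
        t = p.PhyloTree(p.TreeNode("X"))
        assert p.joint_ml_characters(t, wag, {"X": "A"}) == {}

    def test_identity_dominates_on_short_branches(self, wag):
        t = p.parse_newick("((A:0.01,B:0.02)ab:0.05,C:0.03)r;")
        got = p.joint_ml_characters(t, wag, {"A": "A", "B": "A", "C": "A"})
        assert got == {"ab": "A", "r": "A"}

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_three_leaves(self, wag, seed):
        rng = np.random.default_rng(seed)
        bl = rng.uniform(0.02, 0.8, size=5)
        t = p.parse_newick(
            f"((A:{bl[0]:.3f},B:{bl[1]:.3f})ab:{bl[2]:.3f},C:{bl[3]:.3f})r;")
        leaf_states = {l: wag.alphabet[rng.integers(20)] for l in "ABC"}
        ll_bf, _ = brute_force_joint_ml(t, wag, leaf_states)
        got = p.joint_ml_characters(t, wag, leaf_states)
        states = {**{l: wag.state_index(r) for l, r in leaf_states.items()},
                  **{k: wag.state_index(v) for k, v in got.items()}}
        assert joint_log_likelihood(t, wag, states) == pytest.approx(
            ll_bf, abs=1e-9)

    def test_unobserved_pruned_leaf_gets_residue(self, wag):
        # an ancestor whose descendants were all deleted is a pruned-tree
        # leaf without observation; it must still receive a residue
        t = p.parse_newick("((A:0.1,B:0.1)ab:0.2,cd:0.4)r;")
        got = p.joint_ml_characters(t, wag, {"A": "W", "B": "W"})
        assert set(got) == {"ab", "cd", "r"}
        assert got["ab"] == "W"

    def test_ambiguity_code_treated_as_set(self, wag):
        t = p.parse_newick("((A:0.01,B:0.01)ab:0.05,C:0.02)r;")
        got = p.joint_ml_characters(t, wag, {"A": "B", "B": "D", "C": "D"})
        assert got["ab"] == "D"  # B = {D,N}; D is consistent everywhere

    def test_unknown_symbol_raises(self, wag):
        t = p.parse_newick("(A:0.1,B:0.1)r;")
        with pytest.raises(KeyError):
            p.joint_ml_characters(t, wag, {"A": "J", "B": "A"})


class TestReconstructAlignment:
    def test_gapless_msa_gapless_ancestors(self, fixture_tree, pip_params, wag):
        cfg = p.SimulationConfig(root_length=60, indel_rate=0.0, seed=2,
                                 model=wag)
        ds = p.evolve_sequences(fixture_tree, cfg)
        rec = p.reconstruct_alignment(fixture_tree, pip_params, wag, ds.leaf_msa)
        for row in rec.ancestral_rows.values():
            assert "-" not in row
        for sc in rec.scenarios:
            assert sc.insertion_node == "root"
            assert not sc.deletion_branches

    def test_identical_columns_identical_cells(self, fixture_tree, pip_params,
                                               wag, small_replicate):
        rec = p.reconstruct_alignment(fixture_tree, pip_params, wag,
                                      small_replicate.leaf_msa)
        order = sorted(small_replicate.leaf_msa)
        seen = {}
        anc = sorted(rec.ancestral_rows)
        for c in range(rec.msa_columns):
            key = tuple(small_replicate.leaf_msa[l][c] for l in order)
            cells = tuple(rec.ancestral_rows[v][c] for v in anc)
            if key in seen:
                assert seen[key] == cells
            else:
                seen[key] = cells

    def test_gap_placement_matches_scenarios(self, fixture_tree, pip_params,
                                             wag, small_replicate):
        rec = p.reconstruct_alignment(fixture_tree, pip_params, wag,
                                      small_replicate.leaf_msa)
        for sc in rec.scenarios:
            for v, row in rec.ancestral_rows.items():
                assert (row[sc.column_index] == "-") == (v not in sc.alive_nodes)

    def test_column_permutation_equivariance(self, fixture_tree, pip_params, wag):
        cfg = p.SimulationConfig(root_length=40, seed=9, model=wag)
        ds = p.evolve_sequences(fixture_tree, cfg)
        rec = p.reconstruct_alignment(fixture_tree, pip_params, wag, ds.leaf_msa)
        rng = np.random.default_rng(0)
        perm = rng.permutation(rec.msa_columns)
        shuffled = {l: "".join(s[c] for c in perm) for l, s in ds.leaf_msa.items()}
        rec2 = p.reconstruct_alignment(fixture_tree, pip_params, wag, shuffled)
        for v in rec.ancestral_rows:
            expected = "".join(rec.ancestral_rows[v][c] for c in perm)
            assert rec2.ancestral_rows[v] == expected

    def test_four_leaf_toy_matches_composed_oracles(self, wag):
        """End to end on a hand-made alignment: stage 1 (exhaustive scenario
        search) composed with stage 2 (exhaustive joint ML) per column."""
        t = p.parse_newick("((A:0.05,B:0.07)ab:0.1,(C:0.06,D:0.04)cd:0.12)r;")
        msa = {"A": "ACD-", "B": "ACDE", "C": "AC-E", "D": "ACDE"}
        params = p.PIPParams(lambda_ins=0.4, mu_del=0.1)
        rec = p.reconstruct_alignment(t, params, wag, msa)
        for col in range(4):
            presence = {l: int(msa[l][col] != "-") for l in msa}
            _, sc_bf = brute_force_scenario(t, params, GapPattern(col, presence))
            pruned = p.prune_to_alive(t, sc_bf)
            leaf_states = {l: msa[l][col] for l in msa if msa[l][col] != "-"}
            _, assign_bf = brute_force_joint_ml(pruned, wag, leaf_states)
            for v in ("ab", "cd", "r"):
                expected = assign_bf.get(v, "-") if v in sc_bf.alive_nodes else "-"
                assert rec.ancestral_rows[v][col] == expected, (col, v)

    def test_leaf_name_mismatch_raises(self, fixture_tree, pip_params, wag):
        with pytest.raises(ValueError, match="Human"):
            p.reconstruct_alignment(fixture_tree, pip_params, wag,
                                    {"NotHuman": "AA"})

    def test_all_gap_column_raises(self, fixture_tree, pip_params, wag):
        msa = {l: "A-" for l in fixture_tree.leaf_names}
        with pytest.raises(ValueError, match="1"):
            p.reconstruct_alignment(fixture_tree, pip_params, wag, msa)
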