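import numpy as np
import pytest
from scipy import stats as sps

import pipasr as p
from pipasr.history import IndelScenario
from pipasr.stats import correlation_cohort_tally


def scen(col, ins, dels=()):
    return IndelScenario(col, ins, frozenset(dels), frozenset({ins}), 0.0)


class TestGapSegments:
    def test_two_runs(self):
        segs = p.extract_gap_segments({"x": "AA--A-"})
        assert [(s.start_column, s.length) for s in segs] == [(2, 2), (5, 1)]

    def test_gapless_row(self):
        assert p.extract_gap_segments({"x": "ACDEF"}) == []

    def test_all_gap_row(self):
        segs = p.extract_gap_segments({"x": "----"})
        assert [(s.start_column, s.length) for s in segs] == [(0, 4)]

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError):
            p.extract_gap_segments({"x": "AA", "y": "AAA"})


class TestEventSegments:
    def test_contiguous_insertions_merge(self):
        scenarios = [scen(c, "X") for c in range(5, 10)]
        segs = p.group_event_segments(scenarios)
        assert segs == [p.EventSegment("insertion", "X", 5, 5)]

    def test_alternating_nodes_split(self):
        scenarios = [scen(0, "X"), scen(1, "Y"), scen(2, "X")]
        segs = p.group_event_segments(scenarios)
        assert [(s.node_id, s.length) for s in segs] == [
            ("X", 1), ("Y", 1), ("X", 1)]

    def test_deletion_runs_merge_and_conserve_characters(self):
        scenarios = [scen(c, "root", {"B"}) for c in range(4)]
        scenarios += [scen(4, "root")]
        segs = p.group_event_segments(scenarios)
        del_segs = [s for s in segs if s.kind == "deletion"]
        assert del_segs == [p.EventSegment("deletion", "B", 0, 4)]
        ins_total = sum(s.length for s in segs if s.kind == "insertion")
        assert ins_total == 5

    def test_column_gap_breaks_runs(self):
        scenarios = [scen(0, "X"), scen(2, "X")]  # column 1 missing
        segs = p.group_event_segments(scenarios)
        assert [(s.start_column, s.length) for s in segs] == [(0, 1), (2, 1)]

    def test_single_simulated_event_recovered_end_to_end(self, fixture_tree,
                                                         pip_params, wag):
        """A replicate engineered to contain one indel event should yield
        one inferred event segment of the true length."""
        rng = np.random.default_rng(0)
        for attempt in range(200):
            cfg = p.SimulationConfig(root_length=120, indel_rate=0.02,
                                     seed=int(rng.integers(2**31)), model=wag)
            ds = p.evolve_sequences(fixture_tree, cfg)
            if len(ds.events) == 1 and ds.events[0].kind == "insertion" \
                    and len(ds.events[0].column_span) >= 2:
                break
        else:
            pytest.fail("no single-insertion replicate found")
        event = ds.events[0]
        rec = p.reconstruct_alignment(fixture_tree, pip_params, wag, ds.leaf_msa)
        segs = [s for s in p.group_event_segments(rec.scenarios)
                if s.kind == "insertion" and s.node_id != "root"]
        assert len(segs) == 1
        assert segs[0].length == event.length


class TestLineageSummary:
    def test_gapless_alignment_all_root_insertions(self, fixture_tree,
                                                   pip_params, wag):
        cfg = p.SimulationConfig(root_length=50, indel_rate=0.0, seed=4,
                                 model=wag)
        ds = p.evolve_sequences(fixture_tree, cfg)
        rec = p.reconstruct_alignment(fixture_tree, pip_params, wag, ds.leaf_msa)
        summaries = {s.node_id: s for s in p.lineage_summary(rec, ds.leaf_msa)}
        for label, s in summaries.items():
            assert s.deleted_chars == 0
            if label == "root":
                assert s.inserted_chars == 50
            else:
                assert s.inserted_chars == 0
            assert s.ins_del_bias is None

    def test_insertion_counts_sum_to_columns(self, fixture_tree, pip_params,
                                             wag, small_replicate):
        rec = p.reconstruct_alignment(fixture_tree, pip_params, wag,
                                      small_replicate.leaf_msa)
        summaries = p.lineage_summary(rec, small_replicate.leaf_msa)
        assert sum(s.inserted_chars for s in summaries) == rec.msa_columns
        total_dels = sum(len(sc.deletion_branches) for sc in rec.scenarios)
        assert sum(s.deleted_chars for s in summaries) == total_dels

    def test_segment_character_consistency(self, fixture_tree, pip_params,
                                           wag, small_replicate):
        rec = p.reconstruct_alignment(fixture_tree, pip_params, wag,
                                      small_replicate.leaf_msa)
        segs = p.group_event_segments(rec.scenarios)
        seg_ins = sum(s.length for s in segs if s.kind == "insertion")
        seg_del = sum(s.length for s in segs if s.kind == "deletion")
        assert seg_ins == rec.msa_columns
        assert seg_del == sum(len(sc.deletion_branches) for sc in rec.scenarios)


class TestKSTwoSample:
    def test_identical_samples(self):
        cmp = p.ks_two_sample([1, 2, 3, 4], [1, 2, 3, 4])
        assert cmp.ks_statistic == 0.0
        assert cmp.p_value == 1.0

    def test_disjoint_supports(self):
        cmp = p.ks_two_sample([1], [2])
        assert cmp.ks_statistic == 1.0

    def test_statistic_matches_ecdf_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=80)
        b = rng.normal(0.5, 1.0, size=60)
        cmp = p.ks_two_sample(a, b)
        grid = np.sort(np.concatenate([a, b]))
        ecdf_a = np.searchsorted(np.sort(a), grid, side="right") / len(a)
        ecdf_b = np.searchsorted(np.sort(b), grid, side="right") / len(b)
        assert cmp.ks_statistic == pytest.approx(
            np.abs(ecdf_a - ecdf_b).max(), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            p.ks_two_sample([], [1, 2])


class TestMeanGapDifference:
    def test_identical_pairs_zero_differences(self):
        diffs, mw_p, tt_p = p.mean_gap_difference([(3.0, 3.0)] * 10)
        assert np.all(diffs == 0)
        assert mw_p == 1.0 and tt_p == 1.0

    def test_constant_shift_detected_in_mean(self):
        rng = np.random.default_rng(1)
        roots = rng.uniform(2, 8, size=50)
        pairs = [(r + 3.0, r) for r in roots]
        diffs, _, _ = p.mean_gap_difference(pairs)
        assert np.mean(diffs) == pytest.approx(3.0)

    def test_null_rarely_rejects(self):
        """Symmetric differences around zero: both tests should fail to
        reject in the vast majority of seeded trials."""
        rng = np.random.default_rng(7)
        ok_mw = ok_tt = 0
        trials = 40
        for _ in range(trials):
            roots = rng.uniform(2, 8, size=200)
            tips = roots + rng.normal(0, 1.0, size=200)
            _, mw_p, tt_p = p.mean_gap_difference(list(zip(tips, roots)))
            ok_mw += mw_p > 0.05
            ok_tt += tt_p > 0.05
        assert ok_mw >= 0.9 * trials
        assert ok_tt >= 0.9 * trials


class TestLengthDistanceCorrelation:
    def _toy_tree(self):
        return p.parse_newick("((A:0.1,B:0.2)ab:0.1,(C:0.3,D:0.4)cd:0.2)r;")

    def test_monotone_lengths_give_rho_one(self):
        t = self._toy_tree()
        dists = {l: t.path_length_to_root(t.by_id[l]) for l in "ABCD"}
        order = sorted("ABCD", key=lambda l: dists[l])
        lens = {l: 10 + 5 * order.index(l) for l in "ABCD"}
        msa = {l: "A" * (lens[l] + 5) for l in "ABCD"}
        msa = {l: s[:lens[l]] + "-" * (25 - lens[l]) for l, s in
               ((l, "A" * 25) for l in "ABCD")}
        rho, pval = p.length_vs_distance_correlation(
            None, msa, t, root_row="A" * 5 + "-" * 20)
        assert rho == pytest.approx(1.0)

    def test_constant_lengths_flagged_degenerate(self):
        t = self._toy_tree()
        msa = {l: "AAAA" for l in "ABCD"}
        with pytest.warns(UserWarning):
            rho, pval = p.length_vs_distance_correlation(
                None, msa, t, root_row="AAAA")
        assert rho == 0.0 and pval == 1.0

    def test_matches_rank_pearson_oracle(self):
        t = p.parse_newick(
            "((A:0.11,B:0.23)ab:0.05,(C:0.31,D:0.47)cd:0.19)r;")
        lens = {"A": 12, "B": 17, "C": 11, "D": 20}
        msa = {l: "A" * n + "-" * (25 - n) for l, n in lens.items()}
        root_row = "A" * 15 + "-" * 10
        rho, _ = p.length_vs_distance_correlation(None, msa, t, root_row=root_row)
        dists = [0.0] + [t.path_length_to_root(t.by_id[l]) for l in
                         [lf.id for lf in t.leaves]]
        ls = [15] + [lens[lf.id] for lf in t.leaves]
        manual = sps.pearsonr(sps.rankdata(dists), sps.rankdata(ls))
        assert rho == pytest.approx(manual.statistic, abs=1e-12)

    def test_cohort_tally(self):
        results = [(0.9, 0.01), (-0.8, 0.02), (0.1, 0.9), None]
        tally = correlation_cohort_tally(results, alpha=0.05)
        assert tally["n_groups"] == 3
        assert tally["significant_positive"] == 1
        assert tally["significant_negative"] == 1
        assert tally["bonferroni_alpha"] == pytest.approx(0.05 / 3)


class TestGapLengthHistogram:
    def test_all_above_cutoff_empty_histogram(self):
        counts, edges = p.gap_length_histogram([31, 40, 100])
        assert counts.sum() == 0

    def test_counts(self):
        counts, edges = p.gap_length_histogram([1, 1, 2])
        idx = np.searchsorted(edges, 1.0, side="left") - 1
        assert counts[idx] == 2

    def test_bin_edges_cover_cutoff_range(self):
        counts, edges = p.gap_length_histogram([1, 2, 3], bins=100, cutoff=30)
        assert len(counts) == 100
        assert edges[0] == 0.0
        assert edges[-1] == 30.0


def test_plot_gap_length_histogram_writes_png(tmp_path):
    from pipasr.stats import plot_gap_length_histogram
    out = tmp_path / "hist.png"
    plot_gap_length_histogram({"tips": [1, 2, 2, 5], "root": [1, 3]}, out)
    assert out.stat().st_size > 0
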