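"""Descriptive and inferential statistics over gaps and indel histories.

Covers gap-segment extraction from alignment rows, grouping per-column
scenarios into multi-character event segments, per-lineage indel summaries
(the machine-readable analogue of a gaps-and-indels summary table),
distribution comparisons (two-sample Kolmogorov-Smirnov), mean gap-length
differences (Mann-Whitney and t tests), and sequence-length versus
evolutionary-distance correlations (Spearman).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .ancestral import AncestralReconstruction
from .history import IndelScenario
from .tree import PhyloTree

__all__ = [
    "GapSegment",
    "EventSegment",
    "LineageIndelSummary",
    "DistributionComparison",
    "extract_gap_segments",
    "group_event_segments",
    "lineage_summary",
    "ks_two_sample",
    "mean_gap_difference",
    "length_vs_distance_correlation",
    "correlation_cohort_tally",
    "gap_length_histogram",
]

GAP = "-"


@dataclass(frozen=True)
class GapSegment:
    """A maximal run of gap characters in one alignment row."""

    row_label: str
    start_column: int
    length: int


@dataclass(frozen=True)
class EventSegment:
    """Adjacent columns sharing one indel event (same kind and node),
    interpreted as a single multi-character indel."""

    kind: str  # "insertion" | "deletion"
    node_id: str
    start_column: int
    length: int


@dataclass
class LineageIndelSummary:
    """Per-lineage indel and gap counts (one row of the summary table)."""

    node_id: str
    inserted_chars: int
    deleted_chars: int
    ins_del_bias: float | None  # None when deleted_chars == 0
    gap_chars: int
    total_gaps: int
    avg_gap_length: float
    pct_gap_chars: float


@dataclass
class DistributionComparison:
    sample_a_name: str
    sample_b_name: str
    n_a: int
    n_b: int
    ks_statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    histogram_spec: tuple[int, int] = (100, 30)  # (bins, cutoff)


def extract_gap_segments(msa_rows: dict[str, str]) -> list[GapSegment]:
    """Maximal '-' runs of every row, in row-then-column order."""
    lengths = {len(s) for s in msa_rows.values()}
    if len(lengths) > 1:
        raise ValueError("alignment rows have unequal lengths")
    out = []
    for label in msa_rows:
        row = msa_rows[label]
        start = None
        for i, ch in enumerate(row):
            if ch == GAP:
                if start is None:
                    start = i
            elif start is not None:
                out.append(GapSegment(label, start, i - start))
                start = None
        if start is not None:
            out.append(GapSegment(label, start, len(row) - start))
    return out


def group_event_segments(scenarios: list[IndelScenario]) -> list[EventSegment]:
    """Merge per-column single-character events into multi-character segments.

    Adjacent columns inserted at the same node form one insertion segment;
    adjacent columns deleted on the same branch form one deletion segment.
    Character counts are conserved: segment lengths per (kind, node) sum to
    the per-column event counts.
    """
    scenarios = sorted(scenarios, key=lambda s: s.column_index)
    segments: list[EventSegment] = []
    open_runs: dict[tuple[str, str], tuple[int, int]] = {}  # key -> (start, len)

    for i, sc in enumerate(scenarios):
        contiguous = i > 0 and scenarios[i - 1].column_index == sc.column_index - 1
        keys = {("insertion", sc.insertion_node)}
        keys.update(("deletion", b) for b in sc.deletion_branches)
        if not contiguous:
            for key, (start, ln) in open_runs.items():
                segments.append(EventSegment(key[0], key[1], start, ln))
            open_runs = {}
        for key in list(open_runs):
            if key not in keys:
                start, ln = open_runs.pop(key)
                segments.append(EventSegment(key[0], key[1], start, ln))
        for key in keys:
            if key in open_runs:
                start, ln = open_runs[key]
                open_runs[key] = (start, ln + 1)
            else:
                open_runs[key] = (sc.column_index, 1)
    for key, (start, ln) in open_runs.items():
        segments.append(EventSegment(key[0], key[1], start, ln))
    segments.sort(key=lambda s: (s.start_column, s.kind, s.node_id))
    return segments


def lineage_summary(reconstruction: AncestralReconstruction,
                    leaf_msa: dict[str, str]) -> list[LineageIndelSummary]:
    """Per-node inserted/deleted residue counts and gap statistics.

    Insertions are attributed to the insertion node of each column's
    scenario; deletions to the child node of the branch they occurred on.
    Gap statistics are computed from the node's own row (leaves from the
    input alignment, ancestors from the reconstruction).
    """
    ins_counts: dict[str, int] = {}
    del_counts: dict[str, int] = {}
    for sc in reconstruction.scenarios:
        ins_counts[sc.insertion_node] = ins_counts.get(sc.insertion_node, 0) + 1
        for b in sc.deletion_branches:
            del_counts[b] = del_counts.get(b, 0) + 1

    rows = dict(leaf_msa)
    rows.update(reconstruction.ancestral_rows)
    segs_by_row: dict[str, list[GapSegment]] = {label: [] for label in rows}
    for seg in extract_gap_segments(rows):
        segs_by_row[seg.row_label].append(seg)

    out = []
    for label in sorted(rows):
        segs = segs_by_row[label]
        gap_chars = sum(s.length for s in segs)
        ncol = len(rows[label])
        ins = ins_counts.get(label, 0)
        dele = del_counts.get(label, 0)
        out.append(LineageIndelSummary(
            node_id=label,
            inserted_chars=ins,
            deleted_chars=dele,
            ins_del_bias=(ins / dele) if dele > 0 else None,
            gap_chars=gap_chars,
            total_gaps=len(segs),
            avg_gap_length=(gap_chars / len(segs)) if segs else 0.0,
            pct_gap_chars=100.0 * gap_chars / ncol if ncol else 0.0,
        ))
    return out


def ks_two_sample(sample_a, sample_b,
                  name_a: str = "a", name_b: str = "b") -> DistributionComparison:
    """Two-sided two-sample Kolmogorov-Smirnov comparison of length samples."""
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test requires two non-empty samples")
    res = sps.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return DistributionComparison(
        sample_a_name=name_a, sample_b_name=name_b,
        n_a=int(a.size), n_b=int(b.size),
        ks_statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
    )


def mean_gap_difference(per_group: list[tuple[float, float]]):
    """Paired (tips mean - root mean) gap-length differences with tests.

    Returns ``(differences, mannwhitney_p, ttest_p)`` where the Mann-Whitney
    test compares the two mean samples and the two-sample t test does the
    same parametrically.
    """
    if len(per_group) < 2:
        raise ValueError("need at least two groups")
    tips = np.array([t for t, _ in per_group], dtype=float)
    roots = np.array([r for _, r in per_group], dtype=float)
    diffs = tips - roots
    if np.all(tips == tips[0]) and np.all(roots == roots[0]) and tips[0] == roots[0]:
        return diffs, 1.0, 1.0
    mw = sps.mannwhitneyu(tips, roots, alternative="two-sided")
    tt = sps.ttest_ind(tips, roots)
    return diffs, float(mw.pvalue), float(tt.pvalue)


def length_vs_distance_correlation(reconstruction: AncestralReconstruction | None,
                                   leaf_msa: dict[str, str],
                                   tree: PhyloTree,
                                   root_row: str | None = None):
    """Spearman correlation of ungapped sequence length vs root-to-node
    distance, over the tips and the root (root at distance 0).

    Returns ``(rho, p_value)`` for the group, or ``(0.0, 1.0)`` flagged with
    a warning when ranks are degenerate (constant lengths). Groups with
    fewer than 3 points are skipped with a warning (returns None).
    """
    points = []
    if root_row is None and reconstruction is not None:
        root_row = reconstruction.ancestral_rows[tree.root.id]
    if root_row is not None:
        points.append((0.0, len(root_row.replace(GAP, ""))))
    for leaf in tree.leaves:
        points.append((tree.path_length_to_root(leaf),
                       len(leaf_msa[leaf.id].replace(GAP, ""))))
    if len(points) < 3:
        warnings.warn("fewer than 3 points; correlation skipped")
        return None
    dist, lens = zip(*points)
    if len(set(lens)) == 1 or len(set(dist)) == 1:
        warnings.warn("degenerate ranks; correlation undefined, reported as 0")
        return 0.0, 1.0
    res = sps.spearmanr(dist, lens)
    return float(res.statistic), float(res.pvalue)


def correlation_cohort_tally(results, alpha: float = 0.05):
    """Count significant positive/negative correlations in a cohort.

    ``results`` is an iterable of (rho, p) pairs (None entries ignored).
    Returns a dict with counts at ``alpha`` split by sign and at the
    Bonferroni-style threshold ``alpha / n_groups``.
    """
    results = [r for r in results if r is not None]
    n = len(results)
    bonf = alpha / n if n else alpha
    tally = {
        "n_groups": n,
        "significant_positive": sum(1 for rho, p in results if p < alpha and rho > 0),
        "significant_negative": sum(1 for rho, p in results if p < alpha and rho < 0),
        "significant_bonferroni": sum(1 for _, p in results if p < bonf),
        "alpha": alpha,
        "bonferroni_alpha": bonf,
    }
    return tally


def gap_length_histogram(lengths, bins: int = 100, cutoff: int = 30):
    """Histogram of gap lengths over (0, cutoff] with the given bin count.

    Lengths above the cutoff are excluded from the histogram (uninformative
    tail) but the full sample should be retained by the caller for tests.
    Returns ``(counts, bin_edges)``.
    """
    arr = np.asarray(list(lengths), dtype=float)
    kept = arr[arr <= cutoff]
    edges = np.linspace(0.0, float(cutoff), bins + 1)
    counts, edges = np.histogram(kept, bins=edges)
    return counts, edges


def plot_gap_length_histogram(samples: dict[str, list[int]], path,
                              bins: int = 100, cutoff: int = 30) -> None:
    """Overlayed gap-length histograms (PNG); requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for name, lengths in samples.items():
        arr = np.asarray(list(lengths), dtype=float)
        ax.hist(arr[arr <= cutoff], bins=np.linspace(0, cutoff, bins + 1),
                alpha=0.5, label=f"{name} (n={arr.size})", density=True)
    ax.set_xlabel("gap length (residues)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
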