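"""Scoring inferred ancestral alignments against simulator truth.

All metrics are computed over the *ancestral cells*: the (internal node,
column) entries of the alignment. Residue accuracy counts cells whose true
state is a residue and whose inferred symbol equals it exactly (an inferred
gap counts as wrong). Column accuracy requires every ancestral cell of a
column to match truth, gaps included. Gap metrics treat the gap as the
positive class: precision = TP/(TP+FP), recall = TP/(TP+FN), F-score their
harmonic mean, with zero-denominator cases reported as 1 when the paired
error count is also 0 (perfect) and 0 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ancestral import AncestralReconstruction
from .simulate import EvolvedDataset

__all__ = ["ReconstructionScores", "score_reconstruction",
           "classify_by_fscore", "roc_points"]

GAP = "-"


@dataclass
class ReconstructionScores:
    replicate_id: str
    residue_accuracy: float
    column_accuracy: float
    gap_tp: int
    gap_fp: int
    gap_fn: int
    gap_tn: int
    precision: float
    recall: float
    f_score: float
    class_label: str = ""


def _safe_ratio(num: int, denom: int, errors: int) -> float:
    if denom == 0:
        return 1.0 if errors == 0 else 0.0
    return num / denom


def score_reconstruction(truth: EvolvedDataset,
                         inferred: AncestralReconstruction) -> ReconstructionScores:
    """Score one replicate's reconstruction against the simulated truth.

    Requires that the reconstruction was run on the true alignment (same
    column set) of the same tree (same internal-node labels).
    """
    internal = sorted(inferred.ancestral_rows)
    missing = [v for v in internal if v not in truth.true_msa]
    if missing:
        raise ValueError(f"truth lacks ancestral rows for: {missing}")
    ncol = len(truth.leaf_columns)
    if inferred.msa_columns != ncol:
        raise ValueError(
            f"column-set mismatch: truth (observed alignment) has {ncol} "
            f"columns, inference has {inferred.msa_columns}")

    tp = fp = fn = tn = 0
    res_total = res_correct = 0
    col_ok = [True] * ncol
    for v in internal:
        t_row = truth.true_row_on_leaf_columns(v)
        i_row = inferred.ancestral_rows[v]
        for c in range(ncol):
            t, i = t_row[c], i_row[c]
            if t == GAP:
                if i == GAP:
                    tp += 1
                else:
                    fn += 1
                    col_ok[c] = False
            else:
                res_total += 1
                if i == GAP:
                    fp += 1
                    col_ok[c] = False
                else:
                    tn += 1
                    if i == t:
                        res_correct += 1
                    else:
                        col_ok[c] = False

    precision = _safe_ratio(tp, tp + fp, fp)
    recall = _safe_ratio(tp, tp + fn, fn)
    if precision + recall > 0:
        f_score = 2 * precision * recall / (precision + recall)
    else:
        f_score = 0.0
    return ReconstructionScores(
        replicate_id=truth.replicate_id,
        residue_accuracy=_safe_ratio(res_correct, res_total, res_total - res_correct),
        column_accuracy=sum(col_ok) / ncol if ncol else 1.0,
        gap_tp=tp, gap_fp=fp, gap_fn=fn, gap_tn=tn,
        precision=precision, recall=recall, f_score=f_score,
    )


def classify_by_fscore(scores: list[ReconstructionScores], tree=None):
    """Label replicates by gap-retrieval F-score.

    ``optimal``: F >= 0.99; ``sub_optimal``: 0.70 <= F < 0.99; ``poor``:
    F < 0.70. Mutates ``class_label`` in place and returns
    ``(labels, class_counts, class_branch_lengths)`` where the last maps a
    class to the pooled ancestral (internal, non-root) branch lengths of its
    replicates' trees when ``tree`` is given (one shared tree) — the basis
    of a branch-length-by-performance comparison.
    """
    labels = []
    for sc in scores:
        if sc.f_score >= 0.99:
            sc.class_label = "optimal"
        elif sc.f_score >= 0.70:
            sc.class_label = "sub_optimal"
        else:
            sc.class_label = "poor"
        labels.append(sc.class_label)
    counts = {c: labels.count(c) for c in ("optimal", "sub_optimal", "poor")}
    branch_lengths: dict[str, list[float]] = {c: [] for c in counts}
    if tree is not None:
        ancestral_bl = [n.branch_length for n in tree.internal_nodes()
                        if not n.is_root]
        for lab in labels:
            branch_lengths[lab].extend(ancestral_bl)
    return labels, counts, branch_lengths


def roc_points(scores: list[ReconstructionScores]) -> list[tuple[float, float]]:
    """Per-replicate (false positive rate, true positive rate) points for
    gap inference; gap is the positive class."""
    points = []
    for sc in scores:
        tpr = _safe_ratio(sc.gap_tp, sc.gap_tp + sc.gap_fn, sc.gap_fn)
        fpr = (sc.gap_fp / (sc.gap_fp + sc.gap_tn)
               if (sc.gap_fp + sc.gap_tn) > 0 else 0.0)
        points.append((fpr, tpr))
    return points
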