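"""Reproducible experiment driver: simulate -> reconstruct -> score -> stats.

`run_full_experiment` strings the whole simulation study together: it
simulates a cohort of replicates on one tree, removes unusable replicates
(gapless or with unrealistically long gaps), reconstructs ancestral
sequences from the *true* alignment and the *true* tree, scores every
replicate against the simulator truth, and accumulates the cohort-level
statistics: mean accuracies, pooled gap-length distribution comparisons,
mean-gap-difference tests, and the sequence-length/distance correlation
tally.

PIP reconstruction parameters default to ``mu = deletion rate`` and
``lambda = mu * root_length`` so that PIP's expected stationary sequence
length ``lambda/mu`` equals the simulated root length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ancestral import reconstruct_alignment
from .evaluation import ReconstructionScores, classify_by_fscore, score_reconstruction
from .io import run_header, write_fasta_msa, write_lineage_tsv, write_scenario_tsv
from .pip_model import PIPParams
from .simulate import SimulationConfig, apply_replicate_filters, evolve_sequences
from .stats import (correlation_cohort_tally, extract_gap_segments, ks_two_sample,
                    length_vs_distance_correlation, lineage_summary,
                    mean_gap_difference)
from .substitution import wag_model
from .tree import PhyloTree, mammal_fixture_tree, parse_newick

__all__ = ["ExperimentConfig", "ExperimentReport", "run_full_experiment"]

#: Leaf gaps longer than this many residues mark a replicate as
#: biologically unrealistic (the simulation-cohort exclusion rule).
DEFAULT_MAX_GAP = 250


@dataclass
class ExperimentConfig:
    """Configuration of one end-to-end simulation experiment."""

    tree_source: str = "mammal_fixture"  # Newick path or the built-in fixture
    n_replicates: int = 100
    root_length: int = 1000
    indel_rate: float = 0.1
    zipf_alpha: float = 1.7
    max_indel_length: int = 50
    max_gap_filter: int = DEFAULT_MAX_GAP
    lambda_ins: float | None = None  # default: mu * root_length
    mu_del: float | None = None      # default: indel_rate
    seed: int = 0
    output_dir: str | None = None

    def resolve_tree(self) -> PhyloTree:
        if self.tree_source == "mammal_fixture":
            return mammal_fixture_tree()
        path = Path(self.tree_source)
        if not path.exists():
            raise FileNotFoundError(f"no such tree file: {path}")
        return parse_newick(path.read_text())

    def pip_params(self) -> PIPParams:
        mu = self.mu_del if self.mu_del is not None else self.indel_rate
        if mu <= 0:
            mu = 0.1
        lam = self.lambda_ins if self.lambda_ins is not None else mu * self.root_length
        return PIPParams(lambda_ins=lam, mu_del=mu)


@dataclass
class ExperimentReport:
    """Cohort-level results of one experiment run."""

    config: ExperimentConfig
    n_simulated: int
    n_analyzed: int
    filtered: list[tuple[str, str]]
    failed: list[tuple[str, str]]
    scores: list[ReconstructionScores]
    class_counts: dict[str, int]
    mean_residue_accuracy: float
    mean_column_accuracy: float
    mean_precision: float
    mean_recall: float
    ks_tips_vs_root: dict
    ks_inferred_vs_true: dict
    gap_diff_tests: dict
    correlation_tally: dict
    lineage_totals: dict[str, dict[str, int]] = field(default_factory=dict)

    def summary_dict(self) -> dict:
        return {
            "n_simulated": self.n_simulated,
            "n_analyzed": self.n_analyzed,
            "n_filtered": len(self.filtered),
            "n_failed": len(self.failed),
            "mean_residue_accuracy": self.mean_residue_accuracy,
            "mean_column_accuracy": self.mean_column_accuracy,
            "mean_gap_precision": self.mean_precision,
            "mean_gap_recall": self.mean_recall,
            "class_counts": self.class_counts,
            "ks_tips_vs_root": self.ks_tips_vs_root,
            "ks_inferred_vs_true": self.ks_inferred_vs_true,
            "gap_diff_tests": self.gap_diff_tests,
            "correlation_tally": self.correlation_tally,
        }


def run_full_experiment(config: ExperimentConfig,
                        progress: bool = False) -> ExperimentReport:
    """Run the full simulation study described by ``config``.

    Replicate failures are recorded and skipped; the run raises only if
    more than 10% of analyzed replicates fail.
    """
    tree = config.resolve_tree()
    model = wag_model()
    params = config.pip_params()
    master = np.random.default_rng(config.seed)
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    hashed = {k: v for k, v in vars(config).items() if k != "output_dir"}
    header = run_header(config.seed, hashed)

    datasets = []
    for i in range(config.n_replicates):
        sim = SimulationConfig(
            root_length=config.root_length, indel_rate=config.indel_rate,
            zipf_alpha=config.zipf_alpha,
            max_indel_length=config.max_indel_length,
            seed=int(master.integers(2**31)), model=model)
        ds = evolve_sequences(tree, sim)
        ds.replicate_id = f"rep{i:04d}"
        datasets.append(ds)

    kept, filtered = apply_replicate_filters(datasets, config.max_gap_filter)

    scores: list[ReconstructionScores] = []
    failed: list[tuple[str, str]] = []
    tip_gap_lengths: list[int] = []
    root_gap_lengths: list[int] = []
    inferred_anc_gaps: list[int] = []
    true_anc_gaps: list[int] = []
    gap_means: list[tuple[float, float]] = []
    correlations = []
    lineage_totals: dict[str, dict[str, int]] = {}

    for ds in kept:
        try:
            rec = reconstruct_alignment(tree, params, model, ds.leaf_msa)
            sc = score_reconstruction(ds, rec)
        except Exception as exc:  # noqa: BLE001 - replicate-level isolation
            failed.append((ds.replicate_id, f"{type(exc).__name__}: {exc}"))
            continue
        scores.append(sc)

        tip_segs = extract_gap_segments(ds.leaf_msa)
        root_row = rec.ancestral_rows[tree.root.id]
        root_segs = extract_gap_segments({tree.root.id: root_row})
        tip_gap_lengths.extend(s.length for s in tip_segs)
        root_gap_lengths.extend(s.length for s in root_segs)
        inferred_anc_gaps.extend(
            s.length for s in extract_gap_segments(rec.ancestral_rows))
        true_anc_gaps.extend(
            s.length for s in extract_gap_segments(
                {v: ds.true_row_on_leaf_columns(v) for v in rec.ancestral_rows}))
        if tip_segs and root_segs:
            gap_means.append((
                float(np.mean([s.length for s in tip_segs])),
                float(np.mean([s.length for s in root_segs]))))
        correlations.append(
            length_vs_distance_correlation(rec, ds.leaf_msa, tree))
        for summ in lineage_summary(rec, ds.leaf_msa):
            agg = lineage_totals.setdefault(
                summ.node_id, {"inserted_chars": 0, "deleted_chars": 0,
                               "gap_chars": 0, "total_gaps": 0})
            agg["inserted_chars"] += summ.inserted_chars
            agg["deleted_chars"] += summ.deleted_chars
            agg["gap_chars"] += summ.gap_chars
            agg["total_gaps"] += summ.total_gaps

        if out_dir:
            rep_dir = out_dir / ds.replicate_id
            rep_dir.mkdir(exist_ok=True)
            write_fasta_msa(ds.leaf_msa, rep_dir / "leaf_msa.fasta")
            write_fasta_msa({**ds.leaf_msa, **rec.ancestral_rows},
                            rep_dir / "reconstructed_msa.fasta")
            write_scenario_tsv(rec.scenarios, rep_dir / "scenarios.tsv", header)
            write_lineage_tsv(lineage_summary(rec, ds.leaf_msa),
                              rep_dir / "lineage_summary.tsv", header)
        if progress:
            print(f"{ds.replicate_id}: residue_acc={sc.residue_accuracy:.4f} "
                  f"col_acc={sc.column_accuracy:.4f}")

    _, class_counts, _ = classify_by_fscore(scores, tree)

    def _mean(attr):
        return float(np.mean([getattr(s, attr) for s in scores])) if scores else float("nan")

    def _ks(a, b, na, nb):
        if not a or not b:
            return {"error": "empty sample"}
        cmp = ks_two_sample(a, b, na, nb)
        return {"statistic": cmp.ks_statistic, "p_value": cmp.p_value,
                "n_a": cmp.n_a, "n_b": cmp.n_b,
                "mean_a": cmp.mean_a, "mean_b": cmp.mean_b}

    if gap_means and len(gap_means) >= 2:
        diffs, mw_p, tt_p = mean_gap_difference(gap_means)
        gap_diff = {"mean_difference": float(np.mean(diffs)),
                    "mannwhitney_p": mw_p, "ttest_p": tt_p,
                    "n_groups": len(gap_means)}
    else:
        gap_diff = {"error": "fewer than two groups with gaps"}

    report = ExperimentReport(
        config=config,
        n_simulated=config.n_replicates,
        n_analyzed=len(scores),
        filtered=filtered,
        failed=failed,
        scores=scores,
        class_counts=class_counts,
        mean_residue_accuracy=_mean("residue_accuracy"),
        mean_column_accuracy=_mean("column_accuracy"),
        mean_precision=_mean("precision"),
        mean_recall=_mean("recall"),
        ks_tips_vs_root=_ks(tip_gap_lengths, root_gap_lengths, "tips", "root"),
        ks_inferred_vs_true=_ks(inferred_anc_gaps, true_anc_gaps,
                                "inferred_ancestral", "true_ancestral"),
        gap_diff_tests=gap_diff,
        correlation_tally=correlation_cohort_tally(correlations),
        lineage_totals=lineage_totals,
    )

    if out_dir:
        with open(out_dir / "cohort_report.json", "w") as fh:
            json.dump({"header": header.strip(),
                       **report.summary_dict(),
                       "filtered": report.filtered,
                       "failed": report.failed,
                       "lineage_totals": report.lineage_totals}, fh, indent=2)

    if scores and len(failed) > 0.1 * (len(scores) + len(failed)):
        raise RuntimeError(
            f"{len(failed)} of {len(scores) + len(failed)} replicates failed")
    return report
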