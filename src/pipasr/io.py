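"""File I/O: FASTA alignments, scenario/summary tables, run headers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .history import IndelScenario

__all__ = [
    "read_fasta_msa",
    "write_fasta_msa",
    "write_scenario_tsv",
    "write_lineage_tsv",
    "run_header",
]


def read_fasta_msa(path) -> dict[str, str]:
    """Read an aligned FASTA file into an ordered label -> row mapping."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such alignment file: {path}")
    rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not rows:
        raise ValueError(f"no FASTA records in {path}")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise ValueError(f"rows of {path} have unequal lengths {sorted(lengths)}")
    return rows


def write_fasta_msa(rows: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=label, description="")
               for label, seq in rows.items()]
    SeqIO.write(records, str(path), "fasta")


def run_header(seed, config: dict) -> str:
    """Comment header carrying version, seed, and a config hash."""
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]
    return f"# pipasr {__version__} seed={seed} config_sha={digest}\n"


def write_scenario_tsv(scenarios: list[IndelScenario], path,
                       header: str = "") -> None:
    """Per-column scenario table: column, insertion node, deletion branches,
    log-probability."""
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("column\tinsertion_node\tdeletion_branches\tlog_prob\n")
        for sc in sorted(scenarios, key=lambda s: s.column_index):
            dels = ",".join(sorted(sc.deletion_branches))
            fh.write(f"{sc.column_index}\t{sc.insertion_node}\t{dels}\t"
                     f"{sc.log_prob:.6f}\n")


def write_lineage_tsv(summaries, path, header: str = "") -> None:
    """Lineage summary table mirroring the gaps-and-indels statistics."""
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("lineage\tgap_chars\tavg_gap_length\ttotal_gaps\t"
                 "pct_gap_chars\tinsertions\tdeletions\tins_del_bias\n")
        for s in summaries:
            bias = f"{s.ins_del_bias:.4f}" if s.ins_del_bias is not None else "NA"
            fh.write(f"{s.node_id}\t{s.gap_chars}\t{s.avg_gap_length:.2f}\t"
                     f"{s.total_gaps}\t{s.pct_gap_chars:.2f}\t"
                     f"{s.inserted_chars}\t{s.deleted_chars}\t{bias}\n")
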