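"""Sequence evolution simulator with multi-character indels and true histories.

Sequences of amino acids evolve down a phylogeny under three processes:

* substitutions (rate 1 per site in expectation, WAG by default),
* insertions at rate ``indel_rate`` per site (with ``L + 1`` insertion slots
  for a sequence of length ``L``, ends included),
* deletions at rate ``indel_rate`` per site.

Indel lengths follow a Zipf law ``P(l) ~ l^-alpha`` truncated at
``max_indel_length``; deletions running past the end of the sequence are
clipped and logged with their realized length. Indel events are generated by
an exact Gillespie algorithm per branch (their rates depend only on the
current length); substitutions are then applied to each residue over the time
interval it is alive on the branch via the model's transition matrices, which
is distributionally exact because substitutions do not alter indel rates.

The output tracks the *true* alignment: every surviving residue opens one
global alignment column, and all node rows (ancestors included) are emitted
over the common column set, so reconstruction accuracy can be scored directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .substitution import SubstitutionModel, wag_model
from .tree import PhyloTree

__all__ = [
    "IndelEvent",
    "EvolvedDataset",
    "SimulationConfig",
    "sample_zipf_length",
    "zipf_pmf",
    "evolve_sequences",
    "apply_replicate_filters",
]


@dataclass
class IndelEvent:
    """One insertion or deletion on a branch.

    ``node_id`` names the child end of the branch on which the event
    happened; ``length`` is the realized length (after end clipping for
    deletions); ``column_span`` holds the global alignment columns of the
    affected residues (empty if none of them survived in any node row);
    ``time_offset`` is the event time in [0, b] from the top of the branch.
    """

    node_id: str
    kind: str  # "insertion" | "deletion"
    length: int
    column_span: tuple[int, ...]
    time_offset: float


@dataclass
class EvolvedDataset:
    """Simulator output: true alignment over leaves and ancestors.

    ``true_msa`` rows span every column carried by at least one node
    (ancestors included). ``leaf_msa`` is the alignment of the observed
    sequences: it spans only the columns carried by at least one *leaf*
    (``leaf_columns`` gives their indices within the true column set);
    ancestral residues in leaf-invisible columns are unobservable to any
    reconstruction method.
    """

    tree: PhyloTree
    true_msa: dict[str, str]
    leaf_msa: dict[str, str]
    events: list[IndelEvent]
    root_length: int
    leaf_columns: list[int] | None = None
    replicate_id: str = "rep0"

    def __post_init__(self):
        if self.leaf_columns is None:
            self.leaf_columns = list(range(
                len(next(iter(self.leaf_msa.values()))) if self.leaf_msa else 0))

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.true_msa.values()))) if self.true_msa else 0

    def ungapped_length(self, node_id: str) -> int:
        return len(self.true_msa[node_id].replace("-", ""))

    def true_row_on_leaf_columns(self, node_id: str) -> str:
        """True row of a node restricted to the leaf-visible columns."""
        row = self.true_msa[node_id]
        return "".join(row[c] for c in self.leaf_columns)


@dataclass
class SimulationConfig:
    """Simulation parameters.

    Defaults emulate the mammalian ortholog study conditions: 1000-residue
    root sequences, insertion and deletion rates of 0.1 each relative to a
    substitution rate of 1, Zipfian indel lengths with exponent 1.7 capped
    at 50 residues.
    """

    root_length: int = 1000
    indel_rate: float = 0.1
    zipf_alpha: float = 1.7
    max_indel_length: int = 50
    seed: int = 0
    model: SubstitutionModel | None = None

    def __post_init__(self):
        if self.root_length <= 0:
            raise ValueError("root_length must be > 0")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")
        if not self.zipf_alpha > 1:
            raise ValueError("zipf_alpha must be > 1")
        if self.max_indel_length < 1:
            raise ValueError("max_indel_length must be >= 1")


@lru_cache(maxsize=64)
def zipf_pmf(alpha: float, max_len: int) -> np.ndarray:
    """Truncated Zipf pmf over lengths 1..max_len, ``P(l) ~ l^-alpha``."""
    lengths = np.arange(1, max_len + 1, dtype=float)
    w = lengths ** (-alpha)
    return w / w.sum()


def sample_zipf_length(alpha: float, max_len: int, rng: np.random.Generator) -> int:
    """Draw one indel length from the truncated Zipf distribution."""
    if not alpha > 1:
        raise ValueError("alpha must be > 1")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if max_len == 1:
        return 1
    return int(rng.choice(max_len, p=zipf_pmf(alpha, max_len))) + 1


class _Residue:
    """A residue on a branch: global column id, current state index, and the
    time (from the top of the branch) since when it has existed there."""

    __slots__ = ("col", "state", "t0")

    def __init__(self, col, state, t0):
        self.col = col
        self.state = state
        self.t0 = t0


def evolve_sequences(tree: PhyloTree, config: SimulationConfig) -> EvolvedDataset:
    """Evolve sequences down ``tree`` and return the true alignment.

    The root sequence has exactly ``config.root_length`` residues drawn
    i.i.d. from the model equilibrium. Determinism: the same config (seed
    included) yields a byte-identical dataset.
    """
    model = config.model or wag_model()
    rng = np.random.default_rng(config.seed)
    pi = model.equilibrium
    k = len(model.alphabet)
    r = config.indel_rate

    # master column order; column ids index into this list's ordering
    col_order: list[int] = list(range(config.root_length))
    next_col = [config.root_length]

    root_states = rng.choice(k, size=config.root_length, p=pi)
    root_seq = [_Residue(c, int(s), 0.0) for c, s in zip(col_order, root_states)]

    node_seqs: dict[str, list[tuple[int, int]]] = {}  # id -> [(col, state)]
    events: list[IndelEvent] = []

    def run_branch(parent_seq, node):
        b = node.branch_length
        seq = [_Residue(res.col, res.state, 0.0) for res in parent_seq]
        t = 0.0
        if r > 0 and b > 0:
            while True:
                L = len(seq)
                ins_rate = r * (L + 1)
                del_rate = r * L
                total = ins_rate + del_rate
                if total <= 0:
                    break
                t += rng.exponential(1.0 / total)
                if t >= b:
                    break
                length = sample_zipf_length(
                    config.zipf_alpha, config.max_indel_length, rng)
                if rng.random() < ins_rate / total:
                    slot = int(rng.integers(L + 1))
                    # anchor new columns in the master order
                    if slot == 0 and L > 0:
                        pos = col_order.index(seq[0].col)
                    elif L == 0:
                        pos = len(col_order)
                    else:
                        pos = col_order.index(seq[slot - 1].col) + 1
                    new = []
                    for j in range(length):
                        cid = next_col[0]
                        next_col[0] += 1
                        col_order.insert(pos + j, cid)
                        state = int(rng.choice(k, p=pi))
                        new.append(_Residue(cid, state, t))
                    seq[slot:slot] = new
                    events.append(IndelEvent(
                        node.id, "insertion", length,
                        tuple(res.col for res in new), t))
                else:
                    start = int(rng.integers(L))
                    realized = min(length, L - start)
                    removed = seq[start:start + realized]
                    del seq[start:start + realized]
                    events.append(IndelEvent(
                        node.id, "deletion", realized,
                        tuple(res.col for res in removed), t))

        # substitutions: each surviving residue evolves over [t0, b]
        inherited = [res for res in seq if res.t0 == 0.0]
        if inherited and b > 0:
            p_full = model.transition_matrix(b)
            states = np.array([res.state for res in inherited])
            u = rng.random(len(states))
            cdf = np.cumsum(p_full[states, :], axis=1)
            new_states = np.minimum((u[:, None] > cdf).sum(axis=1), k - 1)
            for res, s in zip(inherited, new_states):
                res.state = int(s)
        for res in seq:
            if res.t0 > 0.0:
                p = model.transition_matrix(b - res.t0)
                res.state = int(rng.choice(k, p=p[res.state]))
        return seq

    # preorder walk
    seqs_by_node = {id(tree.root): root_seq}
    node_seqs[tree.root.id] = [(res.col, res.state) for res in root_seq]
    for node in tree.preorder():
        if node.is_root:
            continue
        parent_seq = seqs_by_node[id(node.parent)]
        seq = run_branch(parent_seq, node)
        seqs_by_node[id(node)] = seq
        node_seqs[node.id] = [(res.col, res.state) for res in seq]
    # free intermediate per-node residue lists of pruned lineages lazily
    del seqs_by_node

    # surviving columns: present in at least one node row
    alive_cols = set()
    for pairs in node_seqs.values():
        alive_cols.update(c for c, _ in pairs)
    ordered = [c for c in col_order if c in alive_cols]
    col_index = {c: i for i, c in enumerate(ordered)}
    ncol = len(ordered)

    alphabet = model.alphabet
    true_msa = {}
    for label, pairs in node_seqs.items():
        row = ["-"] * ncol
        for c, s in pairs:
            row[col_index[c]] = alphabet[s]
        true_msa[label] = "".join(row)

    # observed alignment: columns carried by at least one leaf
    leaf_columns = sorted({
        i for l in tree.leaf_names for i, ch in enumerate(true_msa[l])
        if ch != "-"})
    leaf_msa = {l: "".join(true_msa[l][c] for c in leaf_columns)
                for l in tree.leaf_names}

    remapped = [
        IndelEvent(e.node_id, e.kind, e.length,
                   tuple(col_index[c] for c in e.column_span if c in col_index),
                   e.time_offset)
        for e in events
    ]
    return EvolvedDataset(tree=tree, true_msa=true_msa, leaf_msa=leaf_msa,
                          events=remapped, root_length=config.root_length,
                          leaf_columns=leaf_columns)


def apply_replicate_filters(datasets, max_gap: int):
    """Remove unusable replicates, mirroring the cohort exclusions.

    Replicates whose leaf alignment contains no gap at all carry no indel
    signal; replicates whose longest leaf gap exceeds ``max_gap`` are
    treated as biologically unrealistic. Returns ``(kept, report)`` where
    the report lists ``(replicate_id, reason)`` pairs.
    """
    from .stats import extract_gap_segments

    kept, report = [], []
    for ds in datasets:
        segments = extract_gap_segments(ds.leaf_msa)
        if not segments:
            report.append((ds.replicate_id, "no_gaps"))
            continue
        longest = max(s.length for s in segments)
        if longest > max_gap:
            report.append((ds.replicate_id, f"max_gap_exceeded:{longest}"))
            continue
        kept.append(ds)
    return kept, report
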