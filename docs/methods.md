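# Methods

## Model and procedure

`pipasr` implements ancestral sequence reconstruction under the Poisson
Indel Process (PIP). PIP couples a Poisson insertion process over the tree
(a character can be inserted on any branch, or at the root representing the
infinite past) with a per-character continuous-time Markov substitution
model augmented by an absorbing deletion state of rate μ. The key
quantities, for a node *v* with branch length *b(v)* on a tree of total
length τ:

| quantity | definition | meaning |
|---|---|---|
| ι(v) | b(v)/(τ + 1/μ), root: (1/μ)/(τ + 1/μ) | probability the character entered on the branch above v |
| β(v) | (1 − e^{−μb})/(μb), root: 1 | survival from a uniform insertion point to v |
| s(b), d(b) | e^{−μb}, 1 − e^{−μb} | survival/death over a full branch |

Reconstruction is per column and has two stages.

**Stage 1 — indel scenario.** Only the column's gap pattern enters. Because
a character is inserted exactly once and deletions are permanent, the
insertion node must lie on the path from the MRCA of the present leaves to
the root, and the deletion branches form an antichain. A postorder pass
computes, per subtree, the best log-score of "all leaves below are absent"
(either delete on the branch into the subtree, or survive and delete
further down) and of "the present leaves below are alive"; a candidate scan
over the MRCA→root path then maximizes
log ι(v) + log β(v) + Σ children terms. Ties are broken toward the
insertion node nearest the MRCA and toward the single higher deletion —
the most parsimonious of the equally probable scenarios, and deterministic.
The test suite proves the DP equal to exhaustive search over all
(insertion node × deletion antichain) pairs on 6-leaf trees for every gap
pattern and many random branch-length/μ draws.

**Stage 2 — ancestral characters.** The tree is pruned to the scenario's
alive nodes (rooted at the insertion node) and residues are assigned to all
unobserved alive nodes by joint maximum likelihood (max-product dynamic
program, root prior π). Joint rather than marginal reconstruction was
chosen because it returns the single best explanation of the column — the
natural partner of the stage-1 maximum-probability scenario — and because
it is directly checkable against brute-force enumeration (the suite does,
on random ≤3-internal-node trees). Leaf ambiguity codes (X, B, Z) act as
compatible-residue sets; DP ties break by alphabet order. An alive internal
node whose descendants were all deleted is a leaf of the pruned tree with
no observation; it is assigned a residue like any other ancestral node.

The substitution model is WAG, with exchangeabilities and frequencies
embedded as constants; the generator is scaled to one expected substitution
per site per unit time, and transition matrices come from the symmetric
eigendecomposition available for reversible models (cross-checked against
scipy's matrix exponential to 1e−10 in the tests).

## Parameters

* **μ (deletion rate)** — per character per unit time. In the simulation
  study μ = 0.1, matching the simulator's deletion rate relative to a unit
  substitution rate.
* **λ (insertion intensity)** — per unit tree length. Defaults tie it to
  μ via λ/μ = expected stationary sequence length; the experiment driver
  uses λ = μ × root length (λ = 100 for 1000-residue roots), so PIP's
  equilibrium length matches the simulated root length. λ only shifts all
  candidate scores equally within a column, so the inferred scenarios are
  insensitive to it; it is exposed for completeness and log-probability
  reporting.
* Branch lengths of exactly 0 are clamped to 1e−9 inside β to avoid 0/0
  (continuity gives β → 1).

## Simulator

The simulator defines the package's simulation-study conditions: root
sequences of 1000 residues drawn from π; substitutions under WAG;
insertions and deletions each at rate 0.1 per site (insertions have L + 1
slots, ends included; deletions start uniformly on sites and are clipped at
the sequence end, logging the realized length); indel lengths Zipfian,
P(ℓ) ∝ ℓ^−1.7 on 1..50. On real datasets the natural cap would be
data-driven (for instance the longest gap observed in the alignment at
hand); a self-contained simulation has no such anchor, so a fixed
50-residue cap is used.

Indel events are generated by an exact Gillespie algorithm per branch;
substitutions are then applied to each residue over the time interval it is
alive on the branch via transition matrices. This is distributionally exact
because indel rates depend only on the current sequence length, never on
residue states. Every surviving residue opens one global alignment column;
rows for all nodes (ancestors included) are emitted over the common column
set, and the complete event log (node, kind, realized length, columns,
time offset) is retained, so evaluation needs no re-derivation.

One subtlety: a residue can survive in ancestors yet be deleted in every
extant lineage. Such columns exist in the full true alignment but cannot
appear in the alignment of the observed sequences, which is what the
reconstruction receives. `EvolvedDataset` therefore records the leaf-visible
column subset, and all truth-vs-inference comparisons are made on it
(roughly one column per replicate at study conditions).

Replicate filters remove unusable cohort members: replicates with no gaps at
all carry no indel signal and are removed, as are replicates whose longest
leaf gap exceeds 250 residues (5× the indel cap — a "biologically
unrealistic" outlier guard that almost never triggers at these settings).

What the simulator does *not* model: rate heterogeneity across sites,
indel-rate variation across branches, codon/DNA state spaces, alignment
error (the reconstruction sees the true alignment). Passing tests therefore
demonstrate correctness of the method under its own model class and
alignment-error-free inputs; they do not quantify robustness to misaligned
real data.

## Experiment driver and cohort statistics

`run_full_experiment` simulates a cohort (per-replicate seeds drawn from
one master generator), filters, reconstructs each replicate from the true
alignment and true tree, scores it, and accumulates: mean residue/column
accuracy and gap precision/recall (gap as positive class; zero-denominator
conventions keep perfect replicates at F = 1); pooled two-sample KS
comparisons (tip vs root gap lengths, inferred vs true ancestral gap
lengths; asymptotic p-values); the per-replicate mean-gap-length difference
with Mann–Whitney and t tests; Spearman correlations of ungapped sequence
length against root-to-node distance (tips and root; root at distance 0;
cumulative path length rather than the node's own branch length, since the
root has no branch) with a cohort tally at 0.05 and at the Bonferroni-style
0.05/#groups threshold; and per-lineage insertion/deletion totals.

The default cohort size is 100 replicates; at this size the cohort means
carry standard errors of a few tenths of a percentage point and the whole
experiment runs in well under a minute on one CPU.

## Numerical and design notes

* Scenario and pruned-tree computations are cached per gap pattern, and
  ancestral columns per full leaf column, within one alignment — identical
  columns provably yield identical results, so this is a pure speedup.
* The F-score classes use fixed thresholds: optimal F ≥ 0.99,
  sub-optimal 0.70 ≤ F < 0.99, with the remainder labelled poor.
* Midpoint rooting places the root halfway along the branch joining two
  named sister clades (for the mammal fixture: primates vs rodents,
  0.1005 each side), conserving total tree length; re-rooting an already
  midpoint-rooted tree is a fixed point.
* On a symmetric midpoint-rooted tree, PIP's identity
  ι(v)β(v) = ι(root)·d(b(v)) makes "insert at the MRCA" and "insert above
  and delete the sibling" nearly equiprobable; the MRCA wins by the
  residual survival factor. A consequence worth knowing when interpreting
  results on such trees: characters are never placed above the MRCA of the
  present leaves, so ancestral gap recall is maximal while precision
  absorbs all placement error. On asymmetric trees both directions occur.

## Known limitations

* λ and μ are taken as given, not estimated from the data.
* Only the single maximum-probability scenario per column is reported; no
  posterior over scenarios or suboptimal alternatives.
* Real protein data requires externally produced alignments and trees
  (any aligner/tree-inference tool works; the reconstruction CLI accepts
  plain FASTA + Newick); the package itself only simulates.
* Gap metrics on the fixture tree inherit the symmetric-root degeneracy
  described above; accuracy summaries on a single fixed tree are not
  directly comparable to cohort averages over heterogeneous trees.
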