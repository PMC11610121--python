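"""Poisson Indel Process intensities and survival probabilities.

Under PIP, single characters are inserted by a Poisson process over the tree
(including the root, which represents the infinite past) and, once inserted,
evolve by a substitution CTMC augmented with an absorbing deletion state of
rate ``mu``. The quantities here are the standard per-node building blocks:

* ``iota(v)`` — probability that a character present somewhere in the history
  was inserted on the branch above ``v`` (or at the root),
* ``beta(v)`` — probability that a character inserted at a uniform point on
  the branch above ``v`` survives until ``v``,
* ``survival(b) = exp(-mu*b)`` — probability a character present at the top
  of a branch of length ``b`` survives to its bottom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .tree import PhyloTree, TreeNode

__all__ = ["PIPParams", "insertion_intensity", "survival_factor", "branch_survival"]

# branch lengths of exactly 0 are clamped here to avoid 0/0 in beta
_MIN_BRANCH = 1e-9


@dataclass(frozen=True)
class PIPParams:
    """PIP indel parameters.

    Parameters
    ----------
    lambda_ins : float
        Insertion intensity per unit of tree length (lambda > 0). The
        expected sequence length at stationarity is ``lambda/mu``.
    mu_del : float
        Deletion rate per character per unit time (mu > 0).
    """

    lambda_ins: float
    mu_del: float

    def __post_init__(self):
        if not self.lambda_ins > 0:
            raise ValueError("lambda_ins must be > 0")
        if not self.mu_del > 0:
            raise ValueError("mu_del must be > 0")


def insertion_intensity(tree: PhyloTree, params: PIPParams, node: TreeNode) -> float:
    """Normalized insertion intensity iota(v).

    ``iota(v) = b(v) / (tau + 1/mu)`` for non-root nodes and
    ``iota(root) = (1/mu) / (tau + 1/mu)``; the intensities sum to 1 over
    the whole tree.
    """
    norm = tree.tau + 1.0 / params.mu_del
    if node.is_root:
        return (1.0 / params.mu_del) / norm
    return node.branch_length / norm


def survival_factor(params: PIPParams, node: TreeNode) -> float:
    """Insertion-branch survival beta(v).

    For a non-root node, a character inserted at a uniformly distributed
    point on the branch survives to the node with probability
    ``(1 - exp(-mu*b)) / (mu*b)``; at the root beta = 1. Continuous at
    b = 0 with limit 1.
    """
    if node.is_root:
        return 1.0
    b = max(node.branch_length, _MIN_BRANCH)
    x = params.mu_del * b
    return -math.expm1(-x) / x


def branch_survival(params: PIPParams, branch_length: float) -> float:
    """Probability ``exp(-mu*b)`` that a character survives a whole branch."""
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    return math.exp(-params.mu_del * branch_length)
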