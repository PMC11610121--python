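"""Amino-acid substitution model (WAG) and transition probabilities.

The generator is assembled from exchangeabilities ``s_ij`` and equilibrium
frequencies ``pi`` as ``Q_ij = s_ij * pi_j`` (i != j), with the diagonal set
so rows sum to zero, then scaled so the expected rate at equilibrium,
``-sum_i pi_i Q_ii``, equals one substitution per site per unit time.

Transition matrices ``P(b) = expm(Q b)`` are computed through the symmetric
eigendecomposition available for reversible models and cached per branch
length.
"""

from __future__ import annotations

import numpy as np

from ._wag_data import WAG_ALPHABET, WAG_EXCHANGEABILITIES, WAG_FREQUENCIES

__all__ = ["SubstitutionModel", "wag_model", "transition_matrix"]

#: Ambiguity codes accepted at leaves, mapped to compatible residue sets.
AMBIGUITY_CODES = {
    "X": set(WAG_ALPHABET),
    "B": {"D", "N"},
    "Z": {"E", "Q"},
}


class SubstitutionModel:
    """Reversible amino-acid substitution model with unit expected rate.

    Parameters
    ----------
    exchangeabilities : array-like
        Symmetric (20, 20) matrix of exchangeabilities ``s_ij`` (diagonal
        ignored), or the flat lower triangle in column-major order.
    frequencies : array-like
        Equilibrium frequencies ``pi`` (length 20, positive, summing to 1).
    alphabet : str
        Residue order of the matrices.
    """

    def __init__(self, exchangeabilities, frequencies, alphabet=WAG_ALPHABET):
        self.alphabet = alphabet
        k = len(alphabet)
        self.equilibrium = np.asarray(frequencies, dtype=float)
        if self.equilibrium.shape != (k,) or np.any(self.equilibrium <= 0):
            raise ValueError("frequencies must be positive, one per residue")
        self.equilibrium = self.equilibrium / self.equilibrium.sum()

        ex = np.asarray(exchangeabilities, dtype=float)
        if ex.ndim == 1:
            s = np.zeros((k, k))
            s[np.tril_indices(k, -1)] = ex  # column-major lower triangle
            s = s + s.T
        else:
            s = (ex + ex.T) / 2.0
            np.fill_diagonal(s, 0.0)
        q = s * self.equilibrium[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        rate = -np.dot(self.equilibrium, np.diag(q))
        self.rate_matrix = q / rate

        # symmetric eigendecomposition of D^{1/2} Q D^{-1/2} (reversibility)
        d = np.sqrt(self.equilibrium)
        sym = self.rate_matrix * d[:, None] / d[None, :]
        w, u = np.linalg.eigh((sym + sym.T) / 2.0)
        self._eigvals = w
        self._u = u
        self._d = d
        self._index = {a: i for i, a in enumerate(alphabet)}
        self._pcache: dict[float, np.ndarray] = {}

    def state_index(self, residue: str) -> int:
        try:
            return self._index[residue]
        except KeyError:
            raise KeyError(f"unknown residue {residue!r}") from None

    def transition_matrix(self, branch_length: float) -> np.ndarray:
        """Stochastic matrix ``P(b)``; cached per branch length."""
        if branch_length < 0:
            raise ValueError("branch_length must be >= 0")
        p = self._pcache.get(branch_length)
        if p is None:
            e = np.exp(self._eigvals * branch_length)
            sym_p = (self._u * e[None, :]) @ self._u.T
            p = sym_p / self._d[:, None] * self._d[None, :]
            np.clip(p, 0.0, None, out=p)
            p /= p.sum(axis=1, keepdims=True)
            p.setflags(write=False)
            self._pcache[branch_length] = p
        return p

    def log_transition_matrix(self, branch_length: float) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.transition_matrix(branch_length))


def wag_model() -> SubstitutionModel:
    """The WAG model with its published frequencies."""
    return SubstitutionModel(WAG_EXCHANGEABILITIES, WAG_FREQUENCIES)


def transition_matrix(model: SubstitutionModel, branch_length: float) -> np.ndarray:
    """Functional wrapper around :meth:`SubstitutionModel.transition_matrix`."""
    return model.transition_matrix(branch_length)
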