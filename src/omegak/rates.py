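"""MG94xHKY codon rate matrices and transition probabilities.

The instantaneous rate of a single-nucleotide codon change i -> j is

    q_ij = kappa^[transition] * omega^[nonsynonymous] * pi_j

where pi_j is the equilibrium frequency of the *target codon* (the
Goldman–Yang frequency treatment within the MG94 single-step structure;
the choice is documented in docs/methods.md).  Multi-nucleotide changes
have rate zero.  The chain is time-reversible by construction:
pi_i q_ij = pi_j q_ji.

Codon frequencies come from F1x4 or F3x4 products of (positional)
nucleotide frequencies, or directly from observed codon counts.
"""

from __future__ import annotations

import numpy as np

from .genetic_code import (
    IS_NONSYN,
    IS_TRANSITION,
    N_CODONS,
    SENSE_CODONS,
    SINGLE_CHANGE,
    NUCLEOTIDES,
)

_FREQ_TOL = 1e-6


def validate_freqs(codon_freqs: np.ndarray) -> np.ndarray:
    """Validate and return a 61-vector of codon frequencies."""
    pi = np.asarray(codon_freqs, dtype=float)
    if pi.shape != (N_CODONS,):
        raise ValueError(f"codon_freqs must have shape ({N_CODONS},), got {pi.shape}")
    if np.any(pi < 0):
        raise ValueError("codon frequencies must be non-negative")
    total = pi.sum()
    if abs(total - 1.0) > _FREQ_TOL:
        raise ValueError(f"codon frequencies must sum to 1 (got {total:.8f})")
    return pi / total


def f1x4_frequencies(nt_freqs) -> np.ndarray:
    """Codon frequencies from a single nucleotide frequency vector (ACGT
    order), renormalised over the 61 sense codons."""
    f = np.asarray(nt_freqs, dtype=float)
    if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1.0) > _FREQ_TOL:
        raise ValueError("nt_freqs must be 4 non-negative values summing to 1")
    idx = {n: i for i, n in enumerate(NUCLEOTIDES)}
    pi = np.array([f[idx[c[0]]] * f[idx[c[1]]] * f[idx[c[2]]] for c in SENSE_CODONS])
    return pi / pi.sum()


def f3x4_frequencies(pos_nt_freqs) -> np.ndarray:
    """Codon frequencies from per-codon-position nucleotide frequencies
    (3x4 array, ACGT order), renormalised over the sense codons."""
    f = np.asarray(pos_nt_freqs, dtype=float)
    if f.shape != (3, 4):
        raise ValueError("pos_nt_freqs must have shape (3, 4)")
    idx = {n: i for i, n in enumerate(NUCLEOTIDES)}
    pi = np.array(
        [f[0, idx[c[0]]] * f[1, idx[c[1]]] * f[2, idx[c[2]]] for c in SENSE_CODONS]
    )
    total = pi.sum()
    if total <= 0:
        raise ValueError("positional nucleotide frequencies leave no sense codon possible")
    return pi / total


def build_rate_matrix(
    kappa: float,
    omega: float,
    codon_freqs,
    *,
    normalise: bool = True,
) -> np.ndarray:
    """61x61 MG94xHKY instantaneous rate matrix.

    With ``normalise=True`` (default) the matrix is scaled so the expected
    number of substitutions per unit time at equilibrium is 1; the model
    engine instead normalises whole category mixtures with
    :func:`expected_rate` so that branch lengths are expected
    substitutions/site under the *reference* process.
    """
    if not kappa > 0:
        raise ValueError(f"kappa must be > 0, got {kappa}")
    if omega < 0:
        raise ValueError(f"omega must be >= 0, got {omega}")
    pi = validate_freqs(codon_freqs)

    q = np.where(SINGLE_CHANGE, 1.0, 0.0)
    q = q * np.where(IS_TRANSITION, kappa, 1.0)
    q = q * np.where(IS_NONSYN, omega, 1.0)
    q = q * pi[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if normalise:
        rate = expected_rate(q, pi)
        if rate <= 0:
            raise ValueError("degenerate rate matrix (zero total rate)")
        q = q / rate
    return q


def expected_rate(q: np.ndarray, pi: np.ndarray) -> float:
    """Expected substitutions per unit time: -sum_i pi_i q_ii."""
    return float(-(pi * np.diag(q)).sum())


class SpectralQ:
    """Eigendecomposition of a reversible rate matrix for fast P(t).

    Uses the symmetrising similarity transform B = D^{1/2} Q D^{-1/2}
    (D = diag(pi)), so a real symmetric eigenproblem suffices.
    """

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        pi = np.asarray(pi, dtype=float)
        if np.any(pi <= 0):
            raise ValueError("spectral decomposition requires strictly positive pi")
        sq = np.sqrt(pi)
        b = (sq[:, None] * q) / sq[None, :]
        b = 0.5 * (b + b.T)  # symmetrise against round-off
        lam, v = np.linalg.eigh(b)
        # a rate matrix has no positive eigenvalues; clamp roundoff
        self.lam = np.minimum(lam, 0.0)
        # P(t) = L exp(lam t) R with L = D^{-1/2} V, R = V^T D^{1/2}
        self.left = v / sq[:, None]
        self.right = v.T * sq[None, :]

    def transition(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) for a single time t >= 0."""
        if t < 0:
            raise ValueError(f"time must be >= 0, got {t}")
        p = (self.left * np.exp(self.lam * t)[None, :]) @ self.right
        np.clip(p, 0.0, None, out=p)
        return p

    def transitions(self, ts: np.ndarray) -> np.ndarray:
        """Stacked P(t) for an array of times; shape (len(ts), 61, 61)."""
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ValueError("times must be >= 0")
        e = np.exp(np.multiply.outer(ts, self.lam))  # (m, 61)
        p = np.einsum("ik,mk,kj->mij", self.left, e, self.right, optimize=True)
        np.clip(p, 0.0, None, out=p)
        return p


def transition_probabilities(q: np.ndarray, t: float, pi=None) -> np.ndarray:
    """P = exp(Qt).  If ``pi`` is given the reversible spectral route is
    used; otherwise scipy's expm."""
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    if pi is not None:
        return SpectralQ(q, np.asarray(pi, dtype=float)).transition(t)
    from scipy.linalg import expm

    p = expm(q * t)
    np.clip(p, 0.0, None, out=p)
    return p
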