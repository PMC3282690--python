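"""Discrete-time Markov chain utilities shared by the simulator and fitter."""

from __future__ import annotations

import numpy as np

__all__ = ["stationary_distribution"]


def stationary_distribution(A: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Unique stationary distribution pi of a row-stochastic matrix A.

    Solves ``pi A = pi`` via the eigenvector of A^T at eigenvalue 1.  Raises
    ``ValueError`` if A is not row-stochastic (within ``tol``) or the chain has
    no unique stationary distribution (reducible chains, the identity matrix).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    K = A.shape[0]
    if np.any(A < -tol) or np.max(np.abs(A.sum(axis=1) - 1.0)) > max(tol, 1e-10):
        raise ValueError("A must be row-stochastic")
    if K == 1:
        return np.array([1.0])
    eigvals, eigvecs = np.linalg.eig(A.T)
    close = np.abs(eigvals - 1.0) < 1e-9
    if np.count_nonzero(close) != 1:
        raise ValueError("no unique stationary distribution (chain reducible or degenerate)")
    v = np.real(eigvecs[:, np.argmax(close)])
    v = np.clip(v * np.sign(v.sum()), 0.0, None)
    pi = v / v.sum()
    if np.max(np.abs(pi @ A - pi)) > 1e-8:
        raise ValueError("stationary solve failed to converge")
    return pi
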