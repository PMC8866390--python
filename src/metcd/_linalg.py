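"""Shared dense linear algebra with a graded jitter policy.

Kinship matrices estimated from markers are frequently rank-deficient
(duplicated lines, small marker panels), so every symmetric factorization in
the package goes through :func:`chol_psd` / :func:`solve_psd`, which add an
escalating diagonal ridge (relative to the mean diagonal) before declaring
failure.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg as sla

# relative jitter ladder applied to the mean diagonal
_JITTERS = (0.0, 1e-10, 1e-8, 1e-6)


class SingularMatrixError(np.linalg.LinAlgError):
    """Raised when a matrix stays non-positive-definite after the jitter ladder."""


def _scale(a: np.ndarray) -> float:
    d = float(np.mean(np.abs(np.diag(a))))
    return d if d > 0 else 1.0


def chol_psd(a: np.ndarray, lower: bool = True) -> np.ndarray:
    """Cholesky factor of a (possibly semi-definite) symmetric matrix.

    Tries an exact factorization first, then adds ``eps * mean(diag)`` for
    eps in 1e-10 ... 1e-6.
    """
    a = np.asarray(a, dtype=float)
    s = _scale(a)
    for eps in _JITTERS:
        try:
            return sla.cholesky(a + eps * s * np.eye(a.shape[0]), lower=lower)
        except sla.LinAlgError:
            continue
    raise SingularMatrixError(
        f"matrix of dimension {a.shape[0]} is not positive definite "
        f"even after diagonal jitter up to {_JITTERS[-1]:.0e} * mean(diag)"
    )


def solve_psd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve ``a x = b`` for symmetric positive (semi-)definite ``a``."""
    c = chol_psd(a)
    return sla.cho_solve((c, True), np.asarray(b, dtype=float))


def inv_psd(a: np.ndarray) -> np.ndarray:
    """Inverse of a symmetric positive (semi-)definite matrix (jittered)."""
    return solve_psd(a, np.eye(np.asarray(a).shape[0]))


def project_psd(a: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Nearest (in Frobenius sense) symmetric matrix with eigenvalues >= floor."""
    a = 0.5 * (a + a.T)
    w, v = np.linalg.eigh(a)
    if w.min() >= floor:
        return a
    w = np.clip(w, floor, None)
    return (v * w) @ v.T
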