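"""Functional PCA in basis-coefficient space under the W inner product.

For images represented by centred basis coefficients ``C`` (N x K) and basis
Gram matrix ``W`` (inner products of basis functions), the covariance
operator's eigenfunctions have coefficient vectors ``xi`` solving the
unsymmetric problem ``(N-1)^{-1} C'C W xi = lambda xi`` subject to
``xi' W xi = I``.  This is solved stably via the Cholesky factor ``W = LL'``:
with ``A = (N-1)^{-1/2} C L``, the squared singular values of ``A`` are the
eigenvalues and ``xi = (L')^{-1} u`` for the right singular vectors ``u``.
When the plain factorisation fails numerically, a pivoted Cholesky with rank
truncation is used instead.

Per-subject scores are ``nu = C W xi`` — inner products of the centred image
with the eigenfunctions — and can be computed for held-out images with the
training-set mean and eigenfunctions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy.linalg import lapack

__all__ = [
    "GramMatrix",
    "EigenSystem",
    "compute_gram_matrix",
    "fit_fpca",
    "select_truncation",
    "compute_scores",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GramMatrix:
    """Symmetric PSD matrix of basis inner products w_kl = <phi_k, phi_l>."""

    W: np.ndarray
    integration_rule: str = "unit-weight cross product over masked voxels"

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=np.float64)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if not np.allclose(W, W.T, atol=1e-10 * max(1.0, np.abs(W).max())):
            raise ValueError("W must be symmetric")
        object.__setattr__(self, "W", W)


def compute_gram_matrix(basis, mask=None) -> GramMatrix:
    """Gram matrix of the mask-restricted basis (cross product over voxels).

    This is exactly ``D'D`` for the masked design ``D`` — the same matrix the
    projection's normal equations use — computed with unit voxel weight (any
    positive scaling of W is absorbed by the downstream regression).
    """
    return GramMatrix(W=basis.gram.copy())


@dataclass
class EigenSystem:
    """Eigenfunctions (as basis-coefficient columns), eigenvalues, and PVE.

    ``xi`` has one column per retained component, W-orthonormal
    (``xi' W xi = I``); ``eigenvalues`` are decreasing and nonnegative;
    ``pve`` is the cumulative proportion of variance explained; ``M`` is the
    selected truncation (None until :func:`select_truncation` is applied).
    """

    xi: np.ndarray
    eigenvalues: np.ndarray
    pve: np.ndarray
    cholesky_mode: str
    M: int | None = None

    @property
    def M_max(self) -> int:
        return int(self.eigenvalues.size)


def _pivoted_cholesky(W: np.ndarray, tol: float) -> tuple[np.ndarray, np.ndarray, int]:
    c, piv, rank, info = lapack.dpstrf(W, lower=1)
    if info < 0:
        raise np.linalg.LinAlgError("pivoted Cholesky factorisation failed")
    L = np.tril(c)[:, :rank]
    perm = np.asarray(piv[: W.shape[0]], dtype=int) - 1
    return L, perm, int(rank)


def fit_fpca(
    C: np.ndarray,
    W: GramMatrix | np.ndarray,
    rank_tol: float = 1e-10,
    cholesky_mode: str = "auto",
) -> EigenSystem:
    """Eigendecompose the sample covariance operator from centred coefficients.

    Parameters
    ----------
    C : ndarray (N, K)
        Coefficient matrix centred column-wise over the training sample.
    W : GramMatrix or ndarray (K, K)
        Basis inner-product matrix.
    rank_tol : float
        Singular values below ``rank_tol * s_max`` are discarded.
    cholesky_mode : {"auto", "plain", "pivoted"}
        "auto" tries the plain factorisation first and falls back to the
        pivoted one on failure.
    """
    C = np.asarray(C, dtype=np.float64)
    Wm = W.W if isinstance(W, GramMatrix) else np.asarray(W, dtype=np.float64)
    N, K = C.shape
    if N < 2:
        raise ValueError("FPCA requires at least 2 observations")
    if Wm.shape != (K, K):
        raise ValueError("W dimension does not match coefficient columns")

    mode = "plain"
    perm = None
    if cholesky_mode not in ("auto", "plain", "pivoted"):
        raise ValueError(f"unknown cholesky_mode {cholesky_mode!r}")
    if cholesky_mode in ("auto", "plain"):
        try:
            L = sla.cholesky(Wm, lower=True)
        except np.linalg.LinAlgError:
            if cholesky_mode == "plain":
                raise
            mode = "pivoted"
    else:
        mode = "pivoted"
    if mode == "pivoted":
        logger.warning(
            "plain Cholesky of W failed or pivoted mode requested; "
            "using pivoted factorisation with rank truncation"
        )
        L, perm, rank = _pivoted_cholesky(Wm, rank_tol)
        Cp = C[:, perm]
        A = Cp @ L / np.sqrt(N - 1)
    else:
        A = C @ L / np.sqrt(N - 1)

    _, s, Vt = sla.svd(A, full_matrices=False)
    keep = s > rank_tol * (s[0] if s.size else 0.0)
    s = s[keep]
    U = Vt[keep].T  # right singular vectors as columns
    eigenvalues = s**2

    if mode == "plain":
        xi = sla.solve_triangular(L, U, lower=True, trans="T")
    else:
        r = L.shape[1]
        xi_p = np.zeros((K, U.shape[1]))
        xi_p[:r] = sla.solve_triangular(L[:r, :r], U, lower=True, trans="T")
        xi = np.zeros_like(xi_p)
        xi[perm] = xi_p

    # deterministic sign: largest-|coefficient| entry of each column positive
    if xi.size:
        idx = np.argmax(np.abs(xi), axis=0)
        signs = np.sign(xi[idx, np.arange(xi.shape[1])])
        signs[signs == 0] = 1.0
        xi = xi * signs

    total = eigenvalues.sum()
    pve = np.cumsum(eigenvalues) / total if total > 0 else np.zeros_like(eigenvalues)
    return EigenSystem(
        xi=xi, eigenvalues=eigenvalues, pve=pve, cholesky_mode=mode
    )


def select_truncation(eigen: EigenSystem, pve_threshold: float) -> int:
    """Smallest M whose leading eigenvalues explain >= pve_threshold variance.

    Sets ``eigen.M`` as a side effect and returns it.
    """
    if not 0.0 < pve_threshold <= 1.0:
        raise ValueError("pve_threshold must lie in (0, 1]")
    if eigen.eigenvalues.size == 0 or eigen.eigenvalues.sum() <= 0:
        raise ValueError("all eigenvalues are zero: degenerate data")
    M = int(np.searchsorted(eigen.pve, pve_threshold - 1e-12) + 1)
    M = min(M, eigen.M_max)
    eigen.M = M
    return M


def compute_scores(
    centered_coeffs: np.ndarray,
    W: GramMatrix | np.ndarray,
    eigen: EigenSystem,
    M: int | None = None,
) -> np.ndarray:
    """Scores nu = C W xi[:, :M] for training or held-out images.

    ``centered_coeffs`` must be centred with the TRAINING mean.  Training
    scores have zero mean and variance ``lambda_m`` (denominator N-1);
    held-out scores need not be mean-zero.
    """
    if M is None:
        M = eigen.M if eigen.M is not None else eigen.M_max
    if M > eigen.M_max:
        raise ValueError(f"truncation M={M} exceeds M_max={eigen.M_max}")
    Wm = W.W if isinstance(W, GramMatrix) else np.asarray(W)
    C = np.atleast_2d(np.asarray(centered_coeffs, dtype=np.float64))
    return C @ (Wm @ eigen.xi[:, :M])
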