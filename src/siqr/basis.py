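"""Tensor-product B-spline basis expansion of 3D volumes.

Each image is represented as a linear combination of a 3D tensor product of
univariate B-splines of degree ``r`` (quadratic by default) with equidistant
distinct knots spanning each axis.  With ``l_j`` distinct knots per axis and
clamped (fully repeated) boundary knots, the univariate basis count is
``Q_j = l_j + r - 1`` and the full tensor design has ``Q1*Q2*Q3`` columns.
The design is restricted to the analysis mask: rows to masked voxels, columns
to basis functions with support inside the mask.  Projection of an image is
ordinary least squares on the masked voxels, sharing one factorisation of the
normal-equations matrix across all images of a cohort.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import linalg as sla
from scipy import sparse
from scipy.interpolate import BSpline

from .volumes import SmoothMask, Volume3D, mask_vectorize

__all__ = [
    "BasisSystem",
    "ProjectedDataset",
    "DegenerateBasisError",
    "build_basis_system",
    "project_image",
    "project_cohort",
    "center_new",
]

logger = logging.getLogger(__name__)


class DegenerateBasisError(ValueError):
    """Knot configuration that cannot produce a valid basis."""


def _axis_knots(n_points: int, voxel_size: float, spacing: float) -> np.ndarray:
    """Equidistant distinct knots covering [0, (P-1)*voxel_size].

    The final spacing is clipped so the last knot lands exactly on the axis
    boundary.
    """
    extent = (n_points - 1) * voxel_size
    if extent <= 0:
        raise DegenerateBasisError("axis needs at least 2 voxels")
    if spacing <= 0:
        raise DegenerateBasisError("knot spacing must be positive")
    if spacing > extent:
        raise DegenerateBasisError(
            f"knot spacing {spacing} exceeds axis extent {extent}"
        )
    knots = np.arange(0.0, extent, spacing)
    return np.append(knots, extent)


def _axis_design(
    n_points: int, voxel_size: float, knots: np.ndarray, degree: int
) -> sparse.csr_matrix:
    """Evaluate the clamped univariate B-spline basis at the voxel centres."""
    t = np.concatenate([[knots[0]] * degree, knots, [knots[-1]] * degree])
    x = np.arange(n_points) * voxel_size
    return BSpline.design_matrix(x, t, degree).tocsr()


@dataclass
class BasisSystem:
    """Mask-restricted tensor-product B-spline design for one cohort grid.

    Attributes
    ----------
    design : scipy.sparse.csr_matrix, shape (n_active, K_active)
        Rows are masked voxels in raster order, columns the active tensor
        basis functions.
    gram : ndarray, shape (K_active, K_active)
        ``design.T @ design`` — the basis product (Gram) matrix under the
        unit-weight cross-product rule over masked voxels, shared with FPCA.
    active_columns : ndarray of int
        Indices into the full ``Q1*Q2*Q3`` tensor basis of the columns with
        support inside the mask.
    """

    degree: int
    knot_spacing_mm: float
    grid_shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    knots: tuple[np.ndarray, np.ndarray, np.ndarray]
    axis_designs: tuple[sparse.csr_matrix, sparse.csr_matrix, sparse.csr_matrix]
    Q: tuple[int, int, int]
    active_columns: np.ndarray
    design: sparse.csr_matrix
    gram: np.ndarray
    _solve: Callable[[np.ndarray], np.ndarray] = field(repr=False, default=None)
    solver_mode: str = "cholesky"

    @property
    def K_full(self) -> int:
        return int(np.prod(self.Q))

    @property
    def K_active(self) -> int:
        return int(self.active_columns.size)

    @property
    def ref(self) -> str:
        """Compact identifier used to tag projected datasets."""
        return (
            f"bspline(degree={self.degree},spacing={self.knot_spacing_mm}mm,"
            f"grid={self.grid_shape},Q={self.Q},K_active={self.K_active})"
        )

    def solve_normal(self, rhs: np.ndarray) -> np.ndarray:
        """Solve gram @ c = rhs with the shared factorisation."""
        return self._solve(rhs)


def _make_normal_solver(
    gram: np.ndarray, rank_tol: float = 1e-10
) -> tuple[Callable[[np.ndarray], np.ndarray], str]:
    try:
        c_and_low = sla.cho_factor(gram)
    except np.linalg.LinAlgError:
        evals, evecs = sla.eigh(gram)
        keep = evals > rank_tol * evals.max()
        warnings.warn(
            "masked design is rank-deficient; using minimum-norm projection",
            RuntimeWarning,
            stacklevel=3,
        )
        inv = evecs[:, keep] / evals[keep]

        def solve(rhs: np.ndarray, _inv=inv, _vecs=evecs[:, keep]) -> np.ndarray:
            return _inv @ (_vecs.T @ rhs)

        return solve, "eigh-pinv"

    def solve(rhs: np.ndarray, _f=c_and_low) -> np.ndarray:
        return sla.cho_solve(_f, rhs)

    return solve, "cholesky"


def build_basis_system(
    grid_shape: Sequence[int],
    voxel_size_mm: float | Sequence[float],
    knot_spacing_mm: float,
    degree: int = 2,
    mask: SmoothMask | None = None,
) -> BasisSystem:
    """Build the mask-restricted tensor-product B-spline design.

    Parameters
    ----------
    grid_shape : (P1, P2, P3)
    voxel_size_mm : scalar or triple
    knot_spacing_mm : distance between distinct knots (the last interval is
        clipped to end exactly at the axis boundary)
    degree : spline degree (2 = quadratic, the default)
    mask : analysis mask; if None, the full grid is used
    """
    grid_shape = tuple(int(p) for p in grid_shape)
    vs = np.atleast_1d(np.asarray(voxel_size_mm, dtype=float))
    if vs.size == 1:
        vs = np.repeat(vs, 3)
    if degree < 1:
        raise DegenerateBasisError("degree must be >= 1")

    knots = tuple(
        _axis_knots(grid_shape[j], vs[j], knot_spacing_mm) for j in range(3)
    )
    S = tuple(
        _axis_design(grid_shape[j], vs[j], knots[j], degree) for j in range(3)
    )
    Q = tuple(s.shape[1] for s in S)
    for j in range(3):
        assert Q[j] == len(knots[j]) + degree - 1

    phi = sparse.kron(S[2], sparse.kron(S[1], S[0], format="csr"), format="csr")

    if mask is None:
        ind = np.ones(grid_shape, dtype=bool)
        mask = SmoothMask(
            indicator=ind, sigma_voxels=0.0, threshold=0.5,
            voxel_size_mm=tuple(vs),
        )
    if mask.shape != grid_shape:
        raise ValueError("mask shape does not match grid shape")

    rows = phi[mask.flat]
    col_mass = np.asarray(abs(rows).sum(axis=0)).ravel()
    active = np.flatnonzero(col_mass > 0)
    design = rows[:, active].tocsr()
    gram = (design.T @ design).toarray()
    gram = 0.5 * (gram + gram.T)
    solve, mode = _make_normal_solver(gram)

    return BasisSystem(
        degree=degree,
        knot_spacing_mm=float(knot_spacing_mm),
        grid_shape=grid_shape,
        voxel_size_mm=tuple(float(v) for v in vs),
        knots=knots,
        axis_designs=S,
        Q=Q,
        active_columns=active,
        design=design,
        gram=gram,
        _solve=solve,
        solver_mode=mode,
    )


def _fit_stats(
    X: np.ndarray, coeffs: np.ndarray, design: sparse.csr_matrix
) -> np.ndarray:
    """Per-image R^2 about the masked-voxel mean (columns of X are images)."""
    fitted = design @ coeffs
    ssr = np.sum((X - fitted) ** 2, axis=0)
    centered = X - X.mean(axis=0, keepdims=True)
    sst = np.sum(centered**2, axis=0)
    scale = np.maximum(np.sum(X**2, axis=0), 1.0)
    r2 = np.empty_like(ssr)
    constant = sst <= 1e-12 * scale
    if constant.any():
        logger.info(
            "%d constant image(s): R^2 reported as 1 by convention",
            int(constant.sum()),
        )
    r2[constant] = 1.0
    nz = ~constant
    r2[nz] = 1.0 - ssr[nz] / sst[nz]
    return np.clip(r2, 0.0, 1.0)


def project_image(
    volume: Volume3D, basis: BasisSystem, mask: SmoothMask
) -> tuple[np.ndarray, float]:
    """Least-squares projection of one image onto the masked basis.

    Returns the coefficient vector (length ``K_active``) and the R^2 of the
    fit about the image's masked-voxel mean.  Constant images get R^2 = 1 by
    convention.
    """
    x = mask_vectorize(volume, mask)
    if not np.all(np.isfinite(x)):
        raise ValueError("volume contains non-finite values inside the mask")
    X = x[:, None]
    coeffs = basis.solve_normal(basis.design.T @ X)
    r2 = _fit_stats(X, coeffs, basis.design)
    return coeffs[:, 0], float(r2[0])


@dataclass
class ProjectedDataset:
    """Basis coefficients for a cohort, centred with a training-set mean.

    ``coeffs_centered = coeffs_raw - mean_coeffs`` row-wise, where
    ``mean_coeffs`` is the mean over the designated training subset only, so
    held-out rows need not have zero mean.
    """

    coeffs_raw: np.ndarray
    mean_coeffs: np.ndarray
    coeffs_centered: np.ndarray
    r_squared: np.ndarray
    basis_ref: str
    training_index: np.ndarray


def project_cohort(
    volumes: Sequence[Volume3D],
    basis: BasisSystem,
    mask: SmoothMask,
    training_index: Sequence[int] | None = None,
) -> ProjectedDataset:
    """Project every image of a cohort and centre with the training mean.

    Per-image projections are independent (one shared factorisation), so the
    raw coefficients do not depend on which subjects form the training
    subset; only the mean used for centring does.
    """
    if len(volumes) == 0:
        raise ValueError("empty cohort")
    X = np.column_stack([mask_vectorize(v, mask) for v in volumes])
    if not np.all(np.isfinite(X)):
        raise ValueError("cohort contains non-finite voxel values in the mask")
    coeffs = basis.solve_normal(basis.design.T @ X).T  # N x K_active
    r2 = _fit_stats(X, coeffs.T, basis.design)
    if training_index is None:
        training_index = np.arange(len(volumes))
    training_index = np.asarray(training_index, dtype=int)
    if training_index.size == 0:
        raise ValueError("training subset is empty")
    mean = coeffs[training_index].mean(axis=0)
    return ProjectedDataset(
        coeffs_raw=coeffs,
        mean_coeffs=mean,
        coeffs_centered=coeffs - mean,
        r_squared=r2,
        basis_ref=basis.ref,
        training_index=training_index,
    )


def center_new(coeffs: np.ndarray, mean_coeffs: np.ndarray) -> np.ndarray:
    """Centre held-out/new coefficient rows with the TRAINING mean."""
    coeffs = np.atleast_2d(np.asarray(coeffs, dtype=np.float64))
    if coeffs.shape[1] != mean_coeffs.shape[0]:
        raise ValueError("coefficient length does not match training mean")
    return coeffs - mean_coeffs
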