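"""Independent brute-force oracles used by the tests.

Everything here is deliberately written without reusing the package's own
computational paths: dense per-basis-function spline evaluation, explicit
tensor products, dense least squares, a free-variable LP formulation of
quantile regression, and grid searches.
"""

import numpy as np
from scipy import sparse
from scipy.interpolate import BSpline
from scipy.optimize import linprog


def clamped_knot_vector(distinct_knots, degree):
    k = np.asarray(distinct_knots, dtype=float)
    return np.concatenate([[k[0]] * degree, k, [k[-1]] * degree])


def dense_axis_design(n_points, voxel_size, distinct_knots, degree):
    """Evaluate each univariate clamped B-spline basis function separately."""
    t = clamped_knot_vector(distinct_knots, degree)
    n_basis = len(t) - degree - 1
    x = np.arange(n_points) * voxel_size
    cols = []
    for q in range(n_basis):
        c = np.zeros(n_basis)
        c[q] = 1.0
        cols.append(BSpline(t, c, degree, extrapolate=True)(x))
    return np.column_stack(cols)


def dense_tensor_design(grid_shape, voxel_size, distinct_knots_per_axis, degree):
    """Full dense tensor-product design, voxels in x-fastest raster order."""
    S = [
        dense_axis_design(grid_shape[j], voxel_size, distinct_knots_per_axis[j], degree)
        for j in range(3)
    ]
    Q = [s.shape[1] for s in S]
    P = grid_shape
    D = np.empty((P[0] * P[1] * P[2], Q[0] * Q[1] * Q[2]))
    for q3 in range(Q[2]):
        for q2 in range(Q[1]):
            for q1 in range(Q[0]):
                col = np.einsum(
                    "x,y,z->xyz", S[0][:, q1], S[1][:, q2], S[2][:, q3]
                )
                D[:, q3 * Q[1] * Q[0] + q2 * Q[0] + q1] = col.ravel(order="F")
    return D


def lp_quantile_regression(y, X, tau):
    """Unpenalised quantile regression via a free-variable LP formulation.

    Variables: alpha, b (free), u+, u- (nonnegative);
    constraints alpha + X b + u+ - u- = y;
    objective tau * sum(u+) + (1 - tau) * sum(u-).
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    N, M = X.shape
    cost = np.concatenate([[0.0], np.zeros(M), np.full(N, tau), np.full(N, 1 - tau)])
    A_eq = sparse.hstack(
        [
            sparse.csc_matrix(np.ones((N, 1))),
            sparse.csc_matrix(X),
            sparse.identity(N, format="csc"),
            -sparse.identity(N, format="csc"),
        ],
        format="csc",
    )
    bounds = [(None, None)] * (1 + M) + [(0, None)] * (2 * N)
    res = linprog(cost, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    assert res.success, res.message
    return res.x[0], res.x[1 : 1 + M], res.fun


def check_loss_sum(u, tau):
    u = np.asarray(u, float)
    return float(np.sum((tau - (u <= 0)) * u))
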