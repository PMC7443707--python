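"""Interval-coverage simulation for quantile-regression prediction intervals.

A prediction interval built from two quantile fits at tau = delta/2 and
1 - delta/2 should contain a new response (1 - delta)*100% of the time when
the conditional-quantile model is correctly specified; the error vanishes at
rate O(n^{-1/2}) in the training size.  This module checks the claim on a
heteroskedastic linear benchmark where least-squares intervals would fail:

    y = 1 + 2 z + (0.5 + 0.5 |z|) * eps,   z ~ Uniform(0, 1),  eps ~ N(0, 1).

Because z is positive, the noise scale is linear in z on its support and the
true conditional quantiles are exactly linear in z — within the fitted
family at every level.
"""

from __future__ import annotations

import numpy as np

from .quantreg import fit_quantile_lasso

__all__ = ["simulate_heteroskedastic", "interval_coverage_simulation"]


def simulate_heteroskedastic(n: int, rng: np.random.Generator):
    """One draw of the benchmark location-scale model."""
    z = rng.uniform(0.0, 1.0, size=n)
    eps = rng.standard_normal(n)
    y = 1.0 + 2.0 * z + (0.5 + 0.5 * np.abs(z)) * eps
    return z[:, None], y


def interval_coverage_simulation(
    tau_lower: float,
    tau_upper: float,
    n_train: int = 1000,
    n_test: int = 5000,
    n_replicates: int = 20,
    seed: int = 0,
) -> float:
    """Mean out-of-sample interval coverage, in percent.

    Per replicate: fit unpenalised quantile regressions of y on z at the two
    levels on the training draw, then record the fraction of an independent
    test draw falling strictly inside the per-subject interval.
    """
    ss = np.random.SeedSequence(seed)
    covered = []
    for child in ss.spawn(n_replicates):
        rng = np.random.default_rng(child)
        z_tr, y_tr = simulate_heteroskedastic(n_train, rng)
        z_te, y_te = simulate_heteroskedastic(n_test, rng)
        lo = fit_quantile_lasso(y_tr, z_tr, tau_lower, h_lasso=0.0)
        hi = fit_quantile_lasso(y_tr, z_tr, tau_upper, h_lasso=0.0)
        q_lo = lo.predict(z_te)
        q_hi = hi.predict(z_te)
        covered.append(np.mean((y_te > q_lo) & (y_te < q_hi)))
    return 100.0 * float(np.mean(covered))
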