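import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import siqr

settings.register_profile(
    "siqr",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("siqr")


@pytest.fixture(scope="session")
def small_cohort():
    """Synthetic 16^3 cohort used across modules (fast, full pipeline-able)."""
    cfg = siqr.SyntheticConfig(
        n_subjects=60, grid_shape=(16, 16, 16), knot_spacing_mm=4.0, seed=7
    )
    return siqr.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """Unpenalised full-data fit of the small cohort (shared, read-only)."""
    c = small_cohort
    model = siqr.BrainAgeQuantileModel(
        c.volumes, c.table, c.mask,
        knot_spacing_mm=4.0, h=0.0, pve=0.95, basis=c.basis,
    )
    return model, model.fit(seed=0)


@pytest.fixture(scope="session")
def n500_study():
    """Twenty replicate N=500 cohorts: CV interval records and median-slope
    recovery, computed once and shared.

    Per replicate: (a) the normative 10-fold CV with unpenalised quantile
    fits at tau = 0.05/0.5/0.95 under homoskedastic noise, keeping the
    out-of-sample records; (b) a full-data median fit with CV-tuned LASSO
    and post-l1 refit at PVE 0.95, mapped back onto the generating
    components for slope recovery.
    """
    import pandas as pd

    records = []
    slopes = []
    for rep in range(20):
        cfg = siqr.SyntheticConfig(n_subjects=500, seed=1000 + rep)
        cohort = siqr.generate_cohort(cfg)
        model = siqr.BrainAgeQuantileModel(
            cohort.volumes, cohort.table, cohort.mask,
            h=0.0, pve=0.8, basis=cohort.basis,
        )
        cv = model.fit_cv(n_folds=10, seed=rep)
        rec = cv.records.copy()
        rec["rep"] = rep
        records.append(rec)

        model_r = siqr.BrainAgeQuantileModel(
            cohort.volumes, cohort.table, cohort.mask,
            h="cv", pve=0.95, post_l1=True, basis=cohort.basis,
        )
        res = model_r.fit(seed=rep)
        med = res.quantile_models[0.5]
        implied = siqr.implied_true_slopes(
            res.eigen.xi, model_r.gram.W, cohort.xi_star, med.b_hat
        )
        slopes.append(implied)
    return {
        "records": pd.concat(records, ignore_index=True),
        "implied_slopes": np.array(slopes),
        "true_b": np.array(siqr.SyntheticConfig().true_b),
        "n_reps": 20,
    }
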