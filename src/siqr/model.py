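"""Normative brain-age model: the end-to-end scalar-on-image workflow.

``BrainAgeQuantileModel`` bundles a cohort of registered volumes, the
subject table and the analysis mask with the modelling configuration.  Its
``fit()`` trains the full pipeline (projection -> FPCA -> truncation ->
quantile regressions at tau = delta/2, 0.5, 1 - delta/2) on all subjects and
returns a :class:`BrainAgeResults`; ``fit_cv()`` runs the normative K-fold
protocol in which every control's prediction is out of sample — the
training mean, eigenfunctions, truncation and regression coefficients for a
subject never see that subject's own image or age.

Per subject the model emits the three predicted ages, the prediction
interval (q_lower, q_upper), brainPAD (median-predicted minus chronological
age), the coverage flag, and the *-positive / *-negative flags (chronological
age below the lower / above the upper interval limit).  Crossed intervals
(upper below lower) are counted and used as the ordered pair (min, max).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import basis as _basis
from . import fpca as _fpca
from . import quantreg as _qr
from .maps import CoefficientMap, reconstruct_beta
from .volumes import SmoothMask, Volume3D

__all__ = [
    "IntervalSpec",
    "MetricsSummary",
    "BrainAgeQuantileModel",
    "BrainAgeResults",
    "CrossValidationResults",
    "fisher_z_ci",
    "build_records",
    "compute_metrics",
    "detect_crossings",
    "sensitivity_grid",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntervalSpec:
    """Nominal (1 - delta) prediction interval from two quantile fits."""

    delta: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must lie in (0, 1)")

    @property
    def tau_lower(self) -> float:
        return self.delta / 2.0

    @property
    def tau_mid(self) -> float:
        return 0.5

    @property
    def tau_upper(self) -> float:
        return 1.0 - self.delta / 2.0

    @property
    def taus(self) -> tuple[float, float, float]:
        return (self.tau_lower, self.tau_mid, self.tau_upper)

    @property
    def nominal_coverage(self) -> float:
        return 1.0 - self.delta


def fisher_z_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if n < 4:
        raise ValueError("Fisher-z interval needs n >= 4")
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + level / 2.0) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def build_records(
    ids: Sequence[str],
    ages: np.ndarray | None,
    q_lower: np.ndarray,
    q_median: np.ndarray,
    q_upper: np.ndarray,
) -> pd.DataFrame:
    """Assemble per-subject prediction records.

    With chronological ages supplied, brainPAD and the coverage/star flags
    are derived; crossed intervals contribute as the ordered pair (min, max).
    """
    rec = pd.DataFrame(
        {
            "id": list(ids),
            "q_lower": np.asarray(q_lower, float),
            "q_median": np.asarray(q_median, float),
            "q_upper": np.asarray(q_upper, float),
        }
    )
    rec["crossed"] = rec["q_upper"] < rec["q_lower"]
    if ages is not None:
        age = np.asarray(ages, float)
        lo = np.minimum(rec["q_lower"], rec["q_upper"])
        hi = np.maximum(rec["q_lower"], rec["q_upper"])
        rec.insert(1, "age", age)
        rec["brainpad"] = rec["q_median"] - age
        rec["star_pos"] = age < lo
        rec["star_neg"] = age > hi
        rec["covered"] = ~(rec["star_pos"] | rec["star_neg"])
    return rec


@dataclass(frozen=True)
class MetricsSummary:
    """Prediction metrics over a record set (Table-style summary).

    ``coverage`` is the sample proportion of subjects whose chronological
    age lies inside their interval; ``cor_ci_95`` is the Fisher-z interval
    for the correlation between median-predicted and chronological age
    (None when n < 4).
    """

    n: int
    mae: float
    rmse: float
    cor: float
    cor_ci_95: tuple[float, float] | None
    coverage: float
    star_pos_rate: float
    star_neg_rate: float
    crossing_count: int

    def round(self, ndigits: int = 2) -> dict:
        d = {
            "n": self.n,
            "mae": round(self.mae, ndigits),
            "rmse": round(self.rmse, ndigits),
            "cor": round(self.cor, ndigits),
            "coverage": round(self.coverage, ndigits),
            "star_pos_rate": round(self.star_pos_rate, ndigits),
            "star_neg_rate": round(self.star_neg_rate, ndigits),
            "crossing_count": self.crossing_count,
        }
        if self.cor_ci_95 is not None:
            d["cor_ci_95"] = tuple(round(v, ndigits) for v in self.cor_ci_95)
        return d


def compute_metrics(records: pd.DataFrame) -> MetricsSummary:
    """MAE/RMSE/correlation (with Fisher-z CI), coverage and star rates."""
    if "age" not in records:
        raise ValueError("records lack chronological ages")
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records for metrics")
    pad = records["brainpad"].to_numpy()
    mae = float(np.mean(np.abs(pad)))
    rmse = float(np.sqrt(np.mean(pad**2)))
    cor = float(
        np.corrcoef(records["q_median"], records["age"])[0, 1]
    )
    ci = fisher_z_ci(cor, n) if n >= 4 and abs(cor) < 1 else None
    return MetricsSummary(
        n=n,
        mae=mae,
        rmse=rmse,
        cor=cor,
        cor_ci_95=ci,
        coverage=float(records["covered"].mean()),
        star_pos_rate=float(records["star_pos"].mean()),
        star_neg_rate=float(records["star_neg"].mean()),
        crossing_count=int(records["crossed"].sum()),
    )


def detect_crossings(records: pd.DataFrame) -> pd.DataFrame:
    """Subjects whose upper quantile prediction falls below the lower one.

    Reported for sanity checking only; no monotonisation is applied.
    """
    return records.loc[records["crossed"], ["id", "q_lower", "q_upper"]].copy()


@dataclass
class _PipelineState:
    """Everything needed to predict for new images: training-set quantities."""

    mean_coeffs: np.ndarray
    eigen: _fpca.EigenSystem
    M: int
    models: dict[float, _qr.QuantileModel]
    tuning: dict[float, _qr.TuningResult | None]
    seed: int


class BrainAgeQuantileModel:
    """Scalar-on-image quantile regression of age on registered volumes.

    Parameters
    ----------
    volumes, table : the cohort — one volume per table row (columns
        ``id, age, group``), all on one grid
    mask : smooth analysis mask
    knot_spacing_mm : distinct-knot spacing of the quadratic B-spline basis
        (default 12 mm; sensitivity values 6/9/15 are supported)
    degree : spline degree (default 2)
    pve : proportion-of-variance threshold selecting the number of FPC
        scores entering the regressions (default 0.8)
    delta : interval miscoverage; quantile fits at delta/2, 0.5, 1-delta/2
    h : "cv" to tune the LASSO penalty by 5-fold check-loss CV, or a fixed
        nonnegative float (0 = unpenalised)
    h_grid_size : points in the geometric penalty grid when tuning
    tune_folds : folds for penalty tuning
    post_l1 : refit unpenalised on the selected support (default False)
    cholesky_mode : passed to FPCA ("auto" = pivoted fallback on failure)

    The constructor projects every image onto the masked basis once (shared
    factorisation); per-subject projections are independent so this never
    leaks information across CV folds.
    """

    def __init__(
        self,
        volumes: Sequence[Volume3D],
        table: pd.DataFrame,
        mask: SmoothMask,
        *,
        knot_spacing_mm: float = 12.0,
        degree: int = 2,
        pve: float = 0.8,
        delta: float = 0.1,
        h: str | float = "cv",
        h_grid_size: int = 25,
        tune_folds: int = 5,
        post_l1: bool = False,
        cholesky_mode: str = "auto",
        basis: _basis.BasisSystem | None = None,
    ) -> None:
        if len(volumes) != len(table):
            raise ValueError("one volume per table row required")
        self.table = table.reset_index(drop=True)
        self.mask = mask
        self.spec = IntervalSpec(delta)
        self.pve = float(pve)
        self.h = h
        self.h_grid_size = int(h_grid_size)
        self.tune_folds = int(tune_folds)
        self.post_l1 = bool(post_l1)
        self.cholesky_mode = cholesky_mode
        ref = volumes[0]
        if basis is None:
            basis = _basis.build_basis_system(
                ref.shape, ref.voxel_size_mm, knot_spacing_mm, degree, mask
            )
        self.basis = basis
        self.gram = _fpca.compute_gram_matrix(basis)
        proj = _basis.project_cohort(volumes, basis, mask)
        self.coeffs_raw = proj.coeffs_raw
        self.r_squared = proj.r_squared
        self.ages = self.table["age"].to_numpy(dtype=float)
        self.ids = self.table["id"].astype(str).tolist()

    @classmethod
    def from_files(
        cls, volume_paths, table_path, raw_mask_path, *,
        mask_sigma_voxels: float = 2.0, mask_threshold: float = 0.5, **kwargs
    ) -> "BrainAgeQuantileModel":
        from .volumes import build_smooth_mask, read_cohort, read_volume

        volumes, table = read_cohort(volume_paths, table_path)
        mask = build_smooth_mask(
            read_volume(raw_mask_path), mask_sigma_voxels, mask_threshold
        )
        return cls(volumes, table, mask, **kwargs)

    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    # -- internal fitting -------------------------------------------------

    def _tune_seed(self, seed: int, fold: int, tau_index: int) -> int:
        return int((seed * 1000003 + fold * 101 + tau_index) % (2**31 - 1))

    def _fit_state(self, train_idx: np.ndarray, seed: int, fold: int = -1) -> _PipelineState:
        raw_tr = self.coeffs_raw[train_idx]
        mean = raw_tr.mean(axis=0)
        C_tr = raw_tr - mean
        eigen = _fpca.fit_fpca(
            C_tr, self.gram, cholesky_mode=self.cholesky_mode
        )
        M = _fpca.select_truncation(eigen, self.pve)
        nu_tr = _fpca.compute_scores(C_tr, self.gram, eigen, M)
        y_tr = self.ages[train_idx]
        models: dict[float, _qr.QuantileModel] = {}
        tuning: dict[float, _qr.TuningResult | None] = {}
        for k, tau in enumerate(self.spec.taus):
            if self.h == "cv":
                tr = _qr.tune_h(
                    y_tr,
                    nu_tr,
                    tau,
                    h_grid=_qr.default_h_grid(
                        y_tr, nu_tr, tau, n_points=self.h_grid_size
                    ),
                    n_folds=self.tune_folds,
                    seed=self._tune_seed(seed, fold, k),
                )
                h_val = tr.chosen_h
            else:
                tr = None
                h_val = float(self.h)
            m = _qr.fit_quantile_lasso(y_tr, nu_tr, tau, h_lasso=h_val)
            if self.post_l1:
                m = _qr.post_l1_refit(m, y_tr, nu_tr)
            models[tau] = m
            tuning[tau] = tr
        return _PipelineState(
            mean_coeffs=mean, eigen=eigen, M=M, models=models,
            tuning=tuning, seed=seed,
        )

    def _predict_state(
        self, state: _PipelineState, index: np.ndarray
    ) -> pd.DataFrame:
        C = self.coeffs_raw[index] - state.mean_coeffs
        nu = _fpca.compute_scores(C, self.gram, state.eigen, state.M)
        tl, tm, tu = self.spec.taus
        return build_records(
            [self.ids[i] for i in index],
            self.ages[index],
            state.models[tl].predict(nu),
            state.models[tm].predict(nu),
            state.models[tu].predict(nu),
        )

    # -- public API --------------------------------------------------------

    def fit(self, seed: int = 0) -> "BrainAgeResults":
        """Train on ALL subjects (the normative full-data fit)."""
        state = self._fit_state(np.arange(self.n_subjects), seed)
        return BrainAgeResults(self, state)

    def fit_cv(self, n_folds: int = 10, seed: int = 0) -> "CrossValidationResults":
        """Normative K-fold CV: every subject's prediction is out of sample.

        Fold assignment is a seeded uniform shuffle (no stratification).
        With fewer than 2 subjects per fold the fold count is reduced with a
        warning.
        """
        n = self.n_subjects
        if n < 2 * n_folds:
            new_folds = max(2, n // 2)
            warnings.warn(
                f"only {n} subjects: reducing folds {n_folds} -> {new_folds}",
                RuntimeWarning,
            )
            n_folds = new_folds
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        for f, chunk in enumerate(np.array_split(order, n_folds)):
            fold_of[chunk] = f
        records = []
        train_indices: list[np.ndarray] = []
        cholesky_modes: list[str] = []
        for f in range(n_folds):
            test_idx = np.flatnonzero(fold_of == f)
            train_idx = np.flatnonzero(fold_of != f)
            state = self._fit_state(train_idx, seed, fold=f)
            records.append(self._predict_state(state, test_idx))
            train_indices.append(train_idx)
            cholesky_modes.append(state.eigen.cholesky_mode)
        rec = (
            pd.concat(records, ignore_index=True)
            .set_index("id")
            .loc[self.ids]
            .reset_index()
        )
        return CrossValidationResults(
            model=self,
            records=rec,
            fold_of=fold_of,
            train_indices=train_indices,
            n_folds=n_folds,
            seed=seed,
            cholesky_modes=cholesky_modes,
        )


class _LoadedModelStub:
    """Geometry/config carrier for results deserialised from disk."""

    def __init__(self, basis, mask, spec, pve):
        self.basis = basis
        self.mask = mask
        self.spec = spec
        self.pve = pve
        self.gram = _fpca.compute_gram_matrix(basis)
        self.n_subjects = 0
        self.r_squared = np.array([np.nan])


class BrainAgeResults:
    """Full-data fit: per-tau quantile models plus the FPCA state.

    Exposes prediction for new cohorts (centred with the training mean and
    scored against the training eigenfunctions), coefficient-map
    reconstruction, and a text summary.
    """

    def __init__(self, model: BrainAgeQuantileModel, state: _PipelineState):
        self.model = model
        self.state = state

    @property
    def eigen(self) -> _fpca.EigenSystem:
        return self.state.eigen

    @property
    def M(self) -> int:
        return self.state.M

    @property
    def quantile_models(self) -> dict[float, _qr.QuantileModel]:
        return self.state.models

    def params(self) -> pd.DataFrame:
        """Intercepts and slopes per quantile level (original score scale)."""
        rows = []
        for tau, m in self.state.models.items():
            rows.append(
                {
                    "tau": tau,
                    "alpha": m.alpha_hat,
                    "h_lasso": m.h_lasso,
                    "n_selected": len(m.support),
                    **{f"b{j + 1}": v for j, v in enumerate(m.b_hat)},
                }
            )
        return pd.DataFrame(rows)

    def predict(
        self,
        volumes: Sequence[Volume3D] | None = None,
        table: pd.DataFrame | None = None,
        coeffs_raw: np.ndarray | None = None,
    ) -> pd.DataFrame:
        """Predict quantiles/intervals for a new cohort (e.g. case groups).

        Images are centred with the CONTROL training mean and scored with
        the control eigenfunctions.  With a table supplied, brainPAD and
        coverage/star flags are included.
        """
        if coeffs_raw is None:
            if volumes is None:
                raise ValueError("supply volumes or coeffs_raw")
            if len(volumes) == 0:
                return build_records(
                    [], None, np.empty(0), np.empty(0), np.empty(0)
                )
            for v in volumes:
                if v.shape != self.model.mask.shape:
                    raise ValueError(
                        "case volume grid does not match the training grid"
                    )
            proj = _basis.project_cohort(
                volumes, self.model.basis, self.model.mask
            )
            coeffs_raw = proj.coeffs_raw
        C = _basis.center_new(coeffs_raw, self.state.mean_coeffs)
        nu = _fpca.compute_scores(C, self.model.gram, self.eigen, self.M)
        tl, tm, tu = self.model.spec.taus
        if table is not None:
            ids = table["id"].astype(str).tolist()
            ages = table["age"].to_numpy(dtype=float)
        else:
            ids = [f"new-{i + 1:04d}" for i in range(len(C))]
            ages = None
        return build_records(
            ids,
            ages,
            self.state.models[tl].predict(nu),
            self.state.models[tm].predict(nu),
            self.state.models[tu].predict(nu),
        )

    def coefficient_map(self, tau: float) -> CoefficientMap:
        """Reconstruct beta_tau on the voxel grid from the full-data fit."""
        if tau not in self.state.models:
            raise KeyError(f"no model at tau={tau}; have {list(self.state.models)}")
        return reconstruct_beta(
            self.state.models[tau], self.eigen, self.model.basis,
            self.model.mask,
        )

    def save(self, path) -> None:
        """Serialise the fitted state (training-set quantities) to ``.npz``.

        Stores the training mean, eigensystem, truncation, per-tau
        regression coefficients, and the basis/mask parameters needed to
        rebuild the design on the same grid.
        """
        import json as _json

        st = self.state
        meta = {
            "grid_shape": list(self.model.basis.grid_shape),
            "voxel_size_mm": list(self.model.basis.voxel_size_mm),
            "knot_spacing_mm": self.model.basis.knot_spacing_mm,
            "degree": self.model.basis.degree,
            "mask_sigma_voxels": self.model.mask.sigma_voxels,
            "mask_threshold": self.model.mask.threshold,
            "delta": self.model.spec.delta,
            "pve": self.model.pve,
            "M": st.M,
            "cholesky_mode": st.eigen.cholesky_mode,
            "seed": st.seed,
            "taus": list(st.models),
            "post_l1": [st.models[t].post_l1 for t in st.models],
            "h_lasso": [st.models[t].h_lasso for t in st.models],
        }
        arrays = {
            "mean_coeffs": st.mean_coeffs,
            "xi": st.eigen.xi,
            "eigenvalues": st.eigen.eigenvalues,
            "meta": np.array(_json.dumps(meta)),
        }
        for t in st.models:
            arrays[f"alpha_{t}"] = np.array(st.models[t].alpha_hat)
            arrays[f"b_{t}"] = st.models[t].b_hat
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path, raw_mask_path) -> "BrainAgeResults":
        """Rebuild a prediction-capable results object from a saved state.

        The raw mask volume is re-smoothed with the stored parameters and
        the basis is rebuilt on the stored grid, so predictions for new
        images reproduce the training-time geometry exactly.
        """
        import json as _json

        from .volumes import build_smooth_mask, read_volume

        with np.load(path, allow_pickle=False) as npz:
            meta = _json.loads(str(npz["meta"]))
            mean = npz["mean_coeffs"]
            xi = npz["xi"]
            eigenvalues = npz["eigenvalues"]
            coef = {
                float(t): (float(npz[f"alpha_{t}"]), npz[f"b_{t}"])
                for t in meta["taus"]
            }
        mask = build_smooth_mask(
            read_volume(raw_mask_path),
            meta["mask_sigma_voxels"],
            meta["mask_threshold"],
        )
        bsys = _basis.build_basis_system(
            meta["grid_shape"], meta["voxel_size_mm"],
            meta["knot_spacing_mm"], meta["degree"], mask,
        )
        total = eigenvalues.sum()
        eigen = _fpca.EigenSystem(
            xi=xi, eigenvalues=eigenvalues,
            pve=np.cumsum(eigenvalues) / total if total > 0 else eigenvalues,
            cholesky_mode=meta["cholesky_mode"], M=meta["M"],
        )
        models = {}
        for (tau, (alpha, b)), h, pl1 in zip(
            coef.items(), meta["h_lasso"], meta["post_l1"]
        ):
            models[tau] = _qr.QuantileModel(
                tau=tau, alpha_hat=alpha, b_hat=b, gamma_hat=None,
                h_lasso=h, support=np.flatnonzero(b),
                standardization=np.ones_like(b), post_l1=pl1,
            )
        state = _PipelineState(
            mean_coeffs=mean, eigen=eigen, M=meta["M"], models=models,
            tuning={t: None for t in models}, seed=meta["seed"],
        )
        stub = _LoadedModelStub(bsys, mask, IntervalSpec(meta["delta"]),
                                meta["pve"])
        return cls(stub, state)

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Scalar-on-image quantile regression — normative brain-age fit",
            "=" * 62,
            f"subjects: {self.model.n_subjects}   "
            f"basis: {self.model.basis.ref}",
            f"mask voxels: {self.model.mask.n_active}   "
            f"mean projection R^2: {self.model.r_squared.mean():.4f}",
            f"FPCA: M = {self.M} components "
            f"(PVE >= {self.model.pve:.2f}; "
            f"Cholesky: {self.eigen.cholesky_mode})",
            f"intervals: nominal {spec.nominal_coverage:.0%} "
            f"(tau = {spec.tau_lower:.3g}, {spec.tau_upper:.3g})",
            "",
            self.params().to_string(index=False, float_format="%.4f"),
        ]
        return "\n".join(lines)


class CrossValidationResults:
    """Out-of-sample records for every control subject, with fold bookkeeping.

    ``fold_of[i]`` is subject i's held-out fold; ``train_indices[f]`` are the
    subjects whose images and ages trained fold f's mean, eigenfunctions,
    truncation and regressions — subject i never appears in
    ``train_indices[fold_of[i]]``.
    """

    def __init__(
        self, model, records, fold_of, train_indices, n_folds, seed,
        cholesky_modes=None,
    ):
        self.model = model
        self.records = records
        self.fold_of = fold_of
        self.train_indices = train_indices
        self.n_folds = n_folds
        self.seed = seed
        self.cholesky_modes = cholesky_modes or []

    @property
    def metrics(self) -> MetricsSummary:
        return compute_metrics(self.records)

    def crossings(self) -> pd.DataFrame:
        return detect_crossings(self.records)

    def summary(self) -> str:
        m = self.metrics
        spec = self.model.spec
        return "\n".join(
            [
                f"Normative {self.n_folds}-fold CV (seed {self.seed}), "
                f"n = {m.n}",
                f"MAE = {m.mae:.2f} y   RMSE = {m.rmse:.2f} y   "
                f"Cor = {m.cor:.2f}"
                + (
                    f" [{m.cor_ci_95[0]:.2f}, {m.cor_ci_95[1]:.2f}]"
                    if m.cor_ci_95
                    else ""
                ),
                f"coverage = {m.coverage:.3f} "
                f"(nominal {spec.nominal_coverage:.2f})   "
                f"*-pos = {m.star_pos_rate:.3f}   "
                f"*-neg = {m.star_neg_rate:.3f}   "
                f"crossings = {m.crossing_count}",
            ]
        )


def sensitivity_grid(
    volumes: Sequence[Volume3D],
    table: pd.DataFrame,
    mask: SmoothMask,
    pve_set: Sequence[float] = (0.65, 0.8, 0.95),
    ks_set: Sequence[float] = (6.0, 9.0, 12.0, 15.0),
    coverage_set: Sequence[float] = (0.8, 0.9),
    *,
    n_folds: int = 10,
    seed: int = 0,
    h: str | float = "cv",
    degree: int = 2,
    **model_kwargs,
) -> pd.DataFrame:
    """Rerun the normative CV over a grid of PVE, knot spacing and coverage.

    Reports per combination the median-prediction MAE (independent of the
    nominal coverage), the relative coverage difference ``1 - observed /
    nominal``, the crossing count, and whether the pivoted Cholesky fallback
    activated.  A failing combination is recorded and the grid continues.
    """
    rows = []
    for ks in ks_set:
        for pve in pve_set:
            for nominal in coverage_set:
                delta = 1.0 - nominal
                try:
                    model = BrainAgeQuantileModel(
                        volumes, table, mask,
                        knot_spacing_mm=ks, degree=degree, pve=pve,
                        delta=delta, h=h, **model_kwargs,
                    )
                    cv = model.fit_cv(n_folds=n_folds, seed=seed)
                    m = cv.metrics
                    pivoted = any(
                        mode == "pivoted" for mode in cv.cholesky_modes
                    )
                    if pivoted:
                        logger.info(
                            "pivoted Cholesky activated for ks=%s, pve=%s",
                            ks, pve,
                        )
                    rows.append(
                        {
                            "pve": pve,
                            "knot_spacing_mm": ks,
                            "nominal_coverage": nominal,
                            "mae": m.mae,
                            "coverage": m.coverage,
                            "coverage_rel_diff": 1.0 - m.coverage / nominal,
                            "crossing_count": m.crossing_count,
                            "pivoted_cholesky": pivoted,
                            "error": "",
                        }
                    )
                except Exception as exc:  # noqa: BLE001 — grid continues
                    logger.warning(
                        "sensitivity combination (pve=%s, ks=%s, cov=%s) "
                        "failed: %s", pve, ks, nominal, exc,
                    )
                    rows.append(
                        {
                            "pve": pve,
                            "knot_spacing_mm": ks,
                            "nominal_coverage": nominal,
                            "mae": np.nan,
                            "coverage": np.nan,
                            "coverage_rel_diff": np.nan,
                            "crossing_count": -1,
                            "pivoted_cholesky": False,
                            "error": str(exc),
                        }
                    )
    return pd.DataFrame(rows)
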