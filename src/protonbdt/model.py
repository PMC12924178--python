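"""Random-forest inter-pulse-time regression: the modelling core.

:class:`DeliveryTimeModel` wraps a per-transition feature table; ``fit``
runs a randomized hyperparameter search with k-fold cross-validation (MAE
in log space) over a pipeline of robust scaling (numeric features only,
booleans passed through) and a random-forest regressor on the
log1p-transformed inter-pulse time, then refits the best candidate on the
full training set and returns a :class:`DeliveryTimeResults`.

Evaluation is interval-stratified: predictions are mapped back to
milliseconds and scored by MAE and MAPE within the delivery-regime bins
0-50, 50-500, 500-1000 and >1000 ms of the reference interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, RandomizedSearchCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import RobustScaler

from .config import MachineConfig
from .features import (BOOLEAN_FEATURES, MODEL_FEATURES, NUMERIC_FEATURES,
                       build_feature_table, inverse_log1p_target)

__all__ = [
    "DEFAULT_BINS",
    "DEFAULT_SEARCH_SPACE",
    "ScalerParams",
    "DeliveryTimeModel",
    "DeliveryTimeResults",
    "fit_scaler",
    "interval_metrics",
    "interfraction_variability",
]

DEFAULT_BINS = (0.0, 50.0, 500.0, 1000.0, np.inf)

DEFAULT_SEARCH_SPACE = {
    "forest__n_estimators": [100, 200, 300],
    "forest__max_depth": [8, 10, 12],
    "forest__min_samples_leaf": [2, 5, 10, 20],
    "forest__max_features": [0.4, 0.6, 0.8, 1.0],
}


@dataclass
class ScalerParams:
    """Robust-scaling parameters: per-feature median and interquartile range."""

    feature_names: list[str]
    center: np.ndarray  # medians
    scale: np.ndarray   # q75 - q25, degenerate features fall back to 1

    def transform(self, X) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) / self.scale

    def inverse_transform(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.scale + self.center


def fit_scaler(X: pd.DataFrame) -> ScalerParams:
    """Fit a median/IQR scaler on numeric training columns.

    Transformed training columns have median zero; constant columns fall
    back to unit scale so the transform stays defined.
    """
    if len(X) < 2:
        raise ValueError("fit_scaler requires at least 2 rows")
    sk = RobustScaler().fit(np.asarray(X, dtype=float))
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.asarray(X).shape[1])]
    return ScalerParams(names, sk.center_.copy(), sk.scale_.copy())


def _make_pipeline(feature_names: list[str], seed: int) -> Pipeline:
    numeric = [f for f in feature_names if f in NUMERIC_FEATURES]
    booleans = [f for f in feature_names if f not in NUMERIC_FEATURES]
    ct = ColumnTransformer(
        [("num", RobustScaler(), numeric), ("bool", "passthrough", booleans)],
        verbose_feature_names_out=False)
    forest = RandomForestRegressor(random_state=seed, n_jobs=1)
    return Pipeline([("scale", ct), ("forest", forest)])


class DeliveryTimeModel:
    """Inter-pulse-time regression model built from a feature table.

    Parameters
    ----------
    table : DataFrame
        Per-transition feature table (see :mod:`protonbdt.features`)
        carrying the model features and the ``log_delta_t`` target.
    feature_names : list of str, optional
        Feature subset/order; defaults to the documented eight features.
    """

    def __init__(self, table: pd.DataFrame,
                 feature_names: list[str] | None = None):
        self.feature_names = list(feature_names or MODEL_FEATURES)
        missing = [f for f in self.feature_names + ["log_delta_t"]
                   if f not in table.columns]
        if missing:
            raise ValueError(f"feature table is missing column(s): {', '.join(missing)}")
        self.table = table.reset_index(drop=True)

    @classmethod
    def from_log(cls, log, config: MachineConfig | None = None,
                 **kwargs) -> "DeliveryTimeModel":
        """Build the model straight from a pulse log (frame or records)."""
        return cls(build_feature_table(log, config), **kwargs)

    def fit(self, seed: int = 0, cv_folds: int = 5, n_candidates: int = 10,
            search_space: dict | None = None,
            hyperparameters: dict | None = None,
            n_jobs: int = 1) -> "DeliveryTimeResults":
        """Tune by randomized search with k-fold CV and refit on all rows.

        ``hyperparameters`` (forest keyword arguments) skips the search and
        fits those parameters directly.  Scoring is MAE in log-target space.
        """
        if cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if len(self.table) < cv_folds:
            raise ValueError("need at least cv_folds training rows")
        X = self.table[self.feature_names]
        y = self.table["log_delta_t"].to_numpy(dtype=float)
        pipeline = _make_pipeline(self.feature_names, seed)

        if hyperparameters is not None:
            pipeline.set_params(**{f"forest__{k}": v for k, v in hyperparameters.items()})
            pipeline.fit(X, y)
            best_params = dict(hyperparameters)
            cv_summary = None
        else:
            space = search_space or DEFAULT_SEARCH_SPACE
            search = RandomizedSearchCV(
                pipeline, space, n_iter=n_candidates,
                cv=KFold(cv_folds, shuffle=True, random_state=seed),
                scoring="neg_mean_absolute_error",
                random_state=seed, n_jobs=n_jobs, refit=True)
            with warnings.catch_warnings():
                # the search space is small; exhausting it is fine
                warnings.simplefilter("ignore", UserWarning)
                search.fit(X, y)
            pipeline = search.best_estimator_
            best_params = {k.removeprefix("forest__"): v
                           for k, v in search.best_params_.items()}
            cv_summary = pd.DataFrame({
                "params": search.cv_results_["params"],
                "mean_cv_mae_log": -search.cv_results_["mean_test_score"],
                "rank": search.cv_results_["rank_test_score"],
            }).sort_values("rank").reset_index(drop=True)

        training_ids = frozenset()
        if {"fraction_id", "beam_id"}.issubset(self.table.columns):
            training_ids = frozenset(
                map(tuple, self.table[["fraction_id", "beam_id"]].drop_duplicates()
                    .itertuples(index=False)))
        return DeliveryTimeResults(self, pipeline, best_params, cv_summary,
                                   seed, training_ids)


class DeliveryTimeResults:
    """Fitted inter-pulse-time model: predictions, metrics, explanations."""

    def __init__(self, model: DeliveryTimeModel, pipeline: Pipeline,
                 best_params: dict, cv_summary: pd.DataFrame | None,
                 seed: int, training_ids: frozenset = frozenset()):
        self.model = model
        self.pipeline = pipeline
        self.best_params = best_params
        self.cv_summary = cv_summary
        self.seed = seed
        self.training_ids = training_ids
        self.feature_names = model.feature_names

    # ---------------- prediction ----------------

    def _X(self, rows: pd.DataFrame) -> pd.DataFrame:
        missing = [f for f in self.feature_names if f not in rows.columns]
        if missing:
            raise ValueError(f"rows are missing feature column(s): {', '.join(missing)}")
        return rows[self.feature_names]

    def predict_log(self, rows: pd.DataFrame) -> np.ndarray:
        """Forest output in log1p target space."""
        return self.pipeline.predict(self._X(rows))

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        """Predicted inter-pulse times in ms (inverse transform, clamped >= 0)."""
        return np.clip(inverse_log1p_target(self.predict_log(rows)), 0.0, None)

    # ---------------- evaluation ----------------

    def interval_metrics(self, rows: pd.DataFrame,
                         bins=DEFAULT_BINS) -> pd.DataFrame:
        """Per-regime MAE/MAPE of this model on rows carrying ``delta_t``."""
        return interval_metrics(rows["delta_t"].to_numpy(dtype=float),
                                self.predict(rows), bins)

    # ---------------- explainability ----------------

    def shapley(self, rows: pd.DataFrame, background: pd.DataFrame,
                grouping: dict | None = None):
        """Interventional Shapley attributions for ``rows``.

        See :mod:`protonbdt.explain`; ``grouping`` sums member attributions
        into physical feature groups while preserving additivity.
        """
        from . import explain
        attr = explain.tree_shap(self.pipeline, self._X(rows),
                                 self._X(background))
        if grouping is not None:
            attr = explain.group_attributions(attr, grouping)
        return attr

    # ---------------- reporting ----------------

    def summary(self, test_rows: pd.DataFrame | None = None) -> str:
        lines = ["Inter-pulse delivery time model (random forest)",
                 "=" * 48,
                 f"training rows:   {len(self.model.table)}",
                 f"features:        {', '.join(self.feature_names)}",
                 f"target:          log1p(delta_t [ms])",
                 f"seed:            {self.seed}",
                 "best hyperparameters:"]
        for k, v in sorted(self.best_params.items()):
            lines.append(f"    {k:<20} {v}")
        if self.cv_summary is not None:
            best = self.cv_summary.iloc[0]
            lines.append(f"CV MAE (log space): {best['mean_cv_mae_log']:.4f} "
                         f"over {len(self.cv_summary)} candidates")
        if test_rows is not None:
            lines.append("")
            lines.append("interval metrics on held-out rows:")
            m = self.interval_metrics(test_rows)
            lines.append(m.to_string(index=False,
                                     float_format=lambda v: f"{v:.2f}"))
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        joblib.dump({
            "pipeline": self.pipeline,
            "best_params": self.best_params,
            "cv_summary": self.cv_summary,
            "seed": self.seed,
            "feature_names": self.feature_names,
            "training_ids": self.training_ids,
        }, path)

    @classmethod
    def load(cls, path: str | Path, table: pd.DataFrame | None = None
             ) -> "DeliveryTimeResults":
        blob = joblib.load(path)
        table = table if table is not None else pd.DataFrame(
            columns=blob["feature_names"] + ["log_delta_t"])
        model = DeliveryTimeModel(table, feature_names=blob["feature_names"])
        return cls(model, blob["pipeline"], blob["best_params"],
                   blob["cv_summary"], blob["seed"], blob["training_ids"])

    # ---------------- plotting ----------------

    def plot_predictions(self, rows: pd.DataFrame, ax=None):
        """Predicted vs reference inter-pulse time scatter (log-log)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ref = rows["delta_t"].to_numpy(dtype=float)
        pred = self.predict(rows)
        ax.loglog(ref, pred, ".", alpha=0.3, markersize=3)
        lim = [min(ref.min(), pred.min()), max(ref.max(), pred.max())]
        ax.loglog(lim, lim, "r--", linewidth=1)
        ax.set_xlabel("reference $\\Delta T$ (ms)")
        ax.set_ylabel("predicted $\\Delta T$ (ms)")
        return ax


def interval_metrics(reference, predicted, bins=DEFAULT_BINS) -> pd.DataFrame:
    """Interval-stratified MAE (ms) and MAPE (%) of predicted vs reference.

    Rows are binned by the *reference* interval into half-open bins
    [lo, hi); MAPE uses the reference in the denominator.
    """
    reference = np.asarray(reference, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if reference.shape != predicted.shape:
        raise ValueError("reference and predicted must have equal length")
    if np.any(reference <= 0):
        raise ValueError("reference intervals must be > 0")
    err = np.abs(reference - predicted)
    rel = err / reference
    edges = np.asarray(bins, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (reference >= lo) & (reference < hi)
        rows.append({
            "bin_lo_ms": lo, "bin_hi_ms": hi, "count": int(m.sum()),
            "mae_ms": float(err[m].mean()) if m.any() else np.nan,
            "mape_pct": float(100.0 * rel[m].mean()) if m.any() else np.nan,
        })
    return pd.DataFrame(rows)


def interfraction_variability(log: pd.DataFrame, band_ms: float = 500.0,
                              bins=DEFAULT_BINS) -> dict:
    """Intrinsic delivery variability of a multi-fraction log.

    The first fraction's inter-pulse times are the reference; every later
    fraction's times are compared against them transition by transition
    (matched by beam and pulse index).  Returns the residual table
    (residual = reference - fraction), per-bin MAE/MAPE of the fractions
    against the reference, and the share of residuals within ``±band_ms``.
    """
    fractions = sorted(log["fraction_id"].unique())
    if len(fractions) < 2:
        raise ValueError("need at least 2 fractions")
    ref_dt = _per_beam_dt(log[log["fraction_id"] == fractions[0]])
    res_rows = []
    for frac in fractions[1:]:
        frac_dt = _per_beam_dt(log[log["fraction_id"] == frac])
        for beam in ref_dt:
            if beam not in frac_dt or len(frac_dt[beam]) != len(ref_dt[beam]):
                raise ValueError(f"fraction {frac} beam {beam}: pulse count "
                                 "does not match the reference fraction")
            r, f = ref_dt[beam], frac_dt[beam]
            res_rows.append(pd.DataFrame({
                "fraction_id": frac, "beam_id": beam,
                "pulse_index": np.arange(2, len(r) + 2),
                "reference_dt_ms": r, "dt_ms": f, "residual_ms": r - f,
            }))
    residuals = pd.concat(res_rows, ignore_index=True)
    metrics = interval_metrics(residuals["reference_dt_ms"], residuals["dt_ms"], bins)
    within = float(np.mean(np.abs(residuals["residual_ms"]) <= band_ms))
    return {"residuals": residuals, "metrics": metrics,
            "within_band_fraction": within, "band_ms": band_ms}


def _per_beam_dt(frac_log: pd.DataFrame) -> dict[str, np.ndarray]:
    out = {}
    for beam, g in frac_log.groupby("beam_id", sort=False):
        ts = g.sort_values("pulse_index")["timestamp_ms"].to_numpy(dtype=float)
        out[beam] = np.diff(ts)
    return out
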