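"""Collapse correlated behavioral metrics into one PC1 score per axis.

Each behavioral axis (exploration, sociability, boldness, activity) is
measured by several correlated metrics per individual and trial; the first
principal component of the standardized metrics serves as that axis's
score.  Because metric units differ by orders of magnitude (seconds vs
squared pixels) the PCA runs on the correlation matrix.  The sign of a
principal component is arbitrary, so every axis declares an orientation
metric whose loading is forced positive — positive score = more of the
trait.  Metrics where *less* means more of the trait (minimum distances,
latencies) are negated before the PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "AXES",
    "PC1Scorer",
    "pc1_score",
    "prepare_axis_inputs",
    "transform_for_lmm",
    "score_axes",
]


@dataclass(frozen=True)
class AxisSpec:
    metrics: tuple[str, ...]          # columns fed to the PCA, in order
    negate: tuple[str, ...]           # metrics flipped so higher = more of trait
    orientation_metric: str           # PC1 loading forced positive here
    log_transform: bool               # shift-log before the mixed model


#: The metric battery per behavioral axis.  Exploration and sociability use
#: the tracking metrics plus the (annotated) approach count; boldness is the
#: three feeding latencies; activity the six open-field metrics.
AXES: dict[str, AxisSpec] = {
    "exploration": AxisSpec(
        metrics=("approaches", "time_outside_s", "min_distance_px", "interaction_time_s"),
        negate=("min_distance_px",),
        orientation_metric="interaction_time_s",
        log_transform=True),
    "sociability": AxisSpec(
        metrics=("time_outside_s", "min_distance_px", "interaction_time_s"),
        negate=("min_distance_px",),
        orientation_metric="interaction_time_s",
        log_transform=True),
    "boldness": AxisSpec(
        metrics=("head_latency_s", "body_latency_s", "first_bite_latency_s"),
        negate=("head_latency_s", "body_latency_s", "first_bite_latency_s"),
        orientation_metric="head_latency_s",
        log_transform=False),
    "activity": AxisSpec(
        metrics=("time_outside_s", "total_distance_px", "turn_mu_rad",
                 "turn_kappa", "area95_px2", "area50_px2"),
        negate=(),
        orientation_metric="total_distance_px",
        log_transform=False),
}


class PC1Scorer(TransformerMixin, BaseEstimator):
    """First-principal-component scorer with a fixed sign convention.

    Parameters
    ----------
    orientation_metric : str or int, optional
        Column whose PC1 loading is forced non-negative.  Defaults to the
        first column.
    standardize : bool
        Standardize columns (correlation-matrix PCA, the default).  With
        ``False`` the PCA runs on the covariance matrix instead.

    Attributes (after ``fit``)
    --------------------------
    loadings_ : ndarray, PC1 loadings (unit eigenvector), oriented.
    pc1_variance_fraction_ : float, fraction of total variance on PC1.
    eigenvalues_ : all eigenvalues, descending.
    mean_, scale_ : per-column centering/scaling applied before projection.
    feature_names_in_ : column names when fitted on a DataFrame.
    """

    def __init__(self, orientation_metric=None, standardize: bool = True):
        self.orientation_metric = orientation_metric
        self.standardize = standardize

    def _coerce(self, X):
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), list(X.columns)
        X = np.asarray(X, dtype=float)
        return X, None

    def fit(self, X, y=None):
        A, names = self._coerce(X)
        if A.ndim != 2 or A.shape[1] < 2:
            raise ValueError("need a 2-D matrix with at least 2 metric columns")
        if A.shape[0] < 3:
            raise ValueError("need at least 3 rows")
        if np.isnan(A).any():
            raise ValueError("missing values must be handled before scoring")
        if A.shape[0] < A.shape[1]:
            warnings.warn("fewer rows than metric columns; PC1 is unstable",
                          UserWarning, stacklevel=2)
        sd = A.std(axis=0, ddof=1)
        if np.any(sd == 0):
            cols = names or list(range(A.shape[1]))
            bad = [str(c) for c, s in zip(cols, sd) if s == 0]
            raise ValueError(f"constant metric column(s): {', '.join(bad)}")
        self.mean_ = A.mean(axis=0)
        self.scale_ = sd if self.standardize else np.ones_like(sd)
        Z = (A - self.mean_) / self.scale_
        C = np.cov(Z, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        v1 = evecs[:, 0]
        idx = 0
        if self.orientation_metric is not None:
            if names is not None and not isinstance(self.orientation_metric, int):
                if self.orientation_metric not in names:
                    raise ValueError(
                        f"orientation metric {self.orientation_metric!r} not a column")
                idx = names.index(self.orientation_metric)
            else:
                idx = int(self.orientation_metric)
        if v1[idx] < 0:
            v1 = -v1
        self.loadings_ = v1
        self.eigenvalues_ = evals
        self.pc1_variance_fraction_ = float(evals[0] / evals.sum())
        self.n_features_in_ = A.shape[1]
        if names is not None:
            self.feature_names_in_ = np.asarray(names, dtype=object)
        return self

    def transform(self, X):
        check_is_fitted(self, "loadings_")
        A, _ = self._coerce(X)
        return (A - self.mean_) / self.scale_ @ self.loadings_

    def get_feature_names_out(self, input_features=None):
        return np.asarray(["pc1_score"], dtype=object)


def pc1_score(metric_matrix, orientation_metric=None):
    """Fit-and-project convenience wrapper.

    Returns ``(scores, pc1_variance_fraction, loadings)`` where loadings is
    a Series when the input is a DataFrame.
    """
    est = PC1Scorer(orientation_metric=orientation_metric).fit(metric_matrix)
    scores = est.transform(metric_matrix)
    loadings = est.loadings_
    if isinstance(metric_matrix, pd.DataFrame):
        loadings = pd.Series(loadings, index=metric_matrix.columns)
    return scores, est.pc1_variance_fraction_, loadings


def prepare_axis_inputs(metrics: pd.DataFrame, axis: str) -> pd.DataFrame:
    """Assemble one axis's metric matrix, indexed by (id, trial).

    ``metrics`` is the long-format table (id, trial, metric, value).
    Distances and latencies are negated so that larger values always mean
    more of the trait.  Rows with any missing metric are dropped
    (listwise); a completely missing metric column raises.
    """
    if axis not in AXES:
        raise ValueError(f"unknown axis {axis!r}; expected one of {sorted(AXES)}")
    spec = AXES[axis]
    # metric names recur across tests (e.g. time_outside_s), so restrict to
    # the axis's own test when the table is labelled per test
    if "test" in metrics.columns:
        metrics = metrics[metrics["test"] == axis]
    wide = metrics.pivot_table(index=["id", "trial"], columns="metric",
                               values="value", aggfunc="first")
    missing = [m for m in spec.metrics if m not in wide.columns]
    if missing:
        raise ValueError(f"axis {axis!r} is missing metric(s): {', '.join(missing)}")
    mat = wide[list(spec.metrics)].dropna(axis=0, how="any").copy()
    for m in spec.negate:
        mat[m] = -mat[m]
    return mat


def transform_for_lmm(scores, axis: str):
    """Axis-specific normalising transform applied before model fitting.

    Exploration and sociability scores go through a shift-log,
    ``log(y - min(y) + 1)`` (PC scores are signed, so a positivity shift is
    required before the log); other axes pass through unchanged.  Returns
    ``(transformed, meta)`` where ``meta`` records the shift constant.
    """
    y = np.asarray(scores, dtype=float)
    spec = AXES.get(axis)
    if spec is None or not spec.log_transform:
        return y, {"transform": "identity"}
    shift = 1.0 - float(y.min())
    return np.log(y + shift), {"transform": "shift-log", "shift": shift}


def score_axes(metrics: pd.DataFrame, covariates: pd.DataFrame | None = None,
               axes=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every axis present in the metric table.

    Returns ``(scores, loadings)``: scores in long format (id, trial, axis,
    score, score_lmm) — ``score_lmm`` being the transform actually fed to
    the mixed models — and a loadings/variance report per axis.
    ``covariates`` (id, sample, length_cm) are merged in when given.
    """
    score_rows, loading_rows = [], []
    for axis in (axes or AXES):
        spec = AXES[axis]
        try:
            mat = prepare_axis_inputs(metrics, axis)
        except ValueError:
            continue
        # orientation metric may have been negated; orientation applies to the
        # (possibly negated) column, keeping "positive = more of the trait"
        est = PC1Scorer(orientation_metric=spec.orientation_metric).fit(mat)
        s = est.transform(mat)
        s_lmm, meta = transform_for_lmm(s, axis)
        for (iid, trial), raw, tr in zip(mat.index, s, s_lmm):
            score_rows.append({"id": iid, "trial": trial, "axis": axis,
                               "score": raw, "score_lmm": tr})
        for m, w in zip(mat.columns, est.loadings_):
            loading_rows.append({"axis": axis, "metric": m, "loading": w,
                                 "pc1_variance_fraction": est.pc1_variance_fraction_,
                                 **{k: v for k, v in meta.items()}})
    scores = pd.DataFrame(score_rows)
    if covariates is not None and not scores.empty:
        scores = scores.merge(covariates.drop_duplicates("id"), on="id", how="left")
    return scores, pd.DataFrame(loading_rows)
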