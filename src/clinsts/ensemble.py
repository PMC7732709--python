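"""Combining constituent scorers and handcrafted features into one score.

Two families of combiner:

* the statistical mean of min-max-normalized scorer outputs (each
  constituent's scores affinely mapped onto [0,5] before averaging), and
* regression stacking — ordinary least squares, Bayesian ridge
  (evidence-maximizing Gaussian-prior linear regression), or L2-penalized
  ridge — over scorer outputs plus optional feature columns.

An exhaustive subset ablation reports the Pearson correlation of the mean
ensemble of every nonempty scorer subset.  Final scores are clipped to
the [0,5] label scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import BayesianRidge, LinearRegression, Ridge

from .evaluation import pearson_correlation

SCALE = (0.0, 5.0)
METHODS = ("mean", "linear", "bayesian_ridge", "ridge")


@dataclass
class PredictionSet:
    """One scorer's id-aligned scores for a set of pairs."""

    name: str
    ids: tuple[str, ...]
    scores: np.ndarray
    constant_flagged: bool = False

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.ids) != len(self.scores):
            raise ValueError(f"{self.name}: ids and scores differ in length")
        if not np.isfinite(self.scores).all():
            raise ValueError(f"{self.name}: non-finite scores")


def _check_alignment(sets: Sequence[PredictionSet]) -> None:
    ref = sets[0].ids
    for ps in sets[1:]:
        if ps.ids != ref:
            offending = sorted(set(ref).symmetric_difference(ps.ids))[:5]
            raise ValueError(
                f"prediction sets {sets[0].name!r} and {ps.name!r} are not "
                f"id-aligned (first differing ids: {offending})")


def normalize_predictions(preds: PredictionSet,
                          scale: tuple[float, float] = SCALE) -> PredictionSet:
    """Affine min-max map of the scores onto the label scale.

    A constant prediction set cannot be normalized; it is passed through
    unchanged with ``constant_flagged`` set.
    """
    lo, hi = preds.scores.min(), preds.scores.max()
    if hi == lo:
        return PredictionSet(preds.name, preds.ids, preds.scores.copy(),
                             constant_flagged=True)
    mapped = (preds.scores - lo) / (hi - lo) * (scale[1] - scale[0]) + scale[0]
    return PredictionSet(preds.name, preds.ids, mapped)


def mean_ensemble(sets: Sequence[PredictionSet]) -> PredictionSet:
    """Per-id arithmetic mean of already-normalized prediction sets."""
    if not sets:
        raise ValueError("mean ensemble needs at least one prediction set")
    _check_alignment(sets)
    mean = np.mean([ps.scores for ps in sets], axis=0)
    return PredictionSet("+".join(ps.name for ps in sets), sets[0].ids, mean)


@dataclass
class EnsembleModel:
    """A fitted combiner: registry of input columns + coefficients."""

    method: str
    columns: tuple[str, ...] = ()
    coef: Optional[np.ndarray] = None
    intercept: float = 0.0
    ridge_lambda: float = 1.0
    train_rmse: Optional[float] = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown ensemble method {self.method!r}")
        if self.coef is not None and len(self.coef) != len(self.columns):
            raise ValueError("coefficient length does not match column registry")


def _design_matrix(design: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    missing = [c for c in columns if c not in design.columns]
    if missing:
        raise ValueError(f"design is missing column(s) {missing}")
    return design.loc[:, list(columns)].to_numpy(dtype=np.float64)


def fit_stacker(design: pd.DataFrame, gold: Sequence[float], method: str,
                ridge_lambda: float = 1.0, fit_intercept: bool = True,
                ) -> EnsembleModel:
    """Fit a regression stacker over scorer-output/feature columns.

    ``linear`` is ordinary least squares and requires a full-rank design
    with at least as many rows as columns; ``ridge`` adds an L2 penalty
    with strength ``ridge_lambda``; ``bayesian_ridge`` maximizes the
    evidence under Gaussian priors.
    """
    y = np.asarray(gold, dtype=np.float64)
    if not np.isfinite(y).all():
        raise ValueError("gold scores must be finite")
    columns = tuple(design.columns)
    X = _design_matrix(design, columns)
    if X.shape[0] != y.size:
        raise ValueError("design and gold differ in length")
    if method == "linear":
        if X.shape[0] < X.shape[1]:
            raise ValueError("fewer rows than columns: use method='ridge'")
        centered = X - X.mean(axis=0) if fit_intercept else X
        if np.linalg.matrix_rank(centered) < X.shape[1]:
            raise ValueError(
                "rank-deficient design under method='linear'; use method='ridge'")
        reg = LinearRegression(fit_intercept=fit_intercept)
    elif method == "ridge":
        reg = Ridge(alpha=ridge_lambda, fit_intercept=fit_intercept)
    elif method == "bayesian_ridge":
        reg = BayesianRidge(fit_intercept=fit_intercept)
    else:
        raise ValueError(f"method {method!r} is not a fitted stacker")
    reg.fit(X, y)
    fitted = EnsembleModel(
        method=method, columns=columns, coef=np.asarray(reg.coef_, dtype=np.float64),
        intercept=float(reg.intercept_) if fit_intercept else 0.0,
        ridge_lambda=ridge_lambda)
    raw = fitted.intercept + X @ fitted.coef
    fitted.train_rmse = float(np.sqrt(np.mean((raw - y) ** 2)))
    return fitted


def predict_stacker(model: EnsembleModel, design: pd.DataFrame) -> PredictionSet:
    """intercept + design·coefficients, clipped to the [0,5] label scale."""
    if model.method == "mean":
        raise ValueError("mean ensembles are not fitted models; use mean_ensemble")
    if model.coef is None:
        raise ValueError("model is not fitted")
    X = _design_matrix(design, model.columns)
    raw = model.intercept + X @ model.coef
    return PredictionSet(f"stack[{model.method}]",
                         tuple(str(i) for i in design.index),
                         np.clip(raw, *SCALE))


def ablate_ensembles(sets: Sequence[PredictionSet], gold: Sequence[float],
                     ) -> pd.DataFrame:
    """Pearson correlation of the mean ensemble of every nonempty subset.

    Each constituent is min-max normalized once; the table has 2^k − 1
    rows and flags the argmax subset.
    """
    if not 1 <= len(sets) <= 6:
        raise ValueError("subset ablation supports 1..6 prediction sets")
    _check_alignment(sets)
    y = np.asarray(gold, dtype=np.float64)
    normalized = [normalize_predictions(ps) for ps in sets]
    rows = []
    for k in range(1, len(sets) + 1):
        for combo in combinations(range(len(sets)), k):
            subset = [normalized[i] for i in combo]
            merged = mean_ensemble(subset)
            rows.append({
                "subset": "+".join(sets[i].name for i in combo),
                "size": k,
                "pcc": pearson_correlation(y, merged.scores),
            })
    table = pd.DataFrame(rows)
    table["best"] = table["pcc"] == table["pcc"].max()
    return table
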