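"""Bias-corrected ensemble of weighted penalized burnout models.

Three elastic-net linear models predict the continuous burnout score
from EHR-use features, one per weighting schema (unweighted, 1/p,
1-p). A physician-grouped 80/20 split of always responders provides a
calibration set on which actual scores are regressed on the three
predictions; the resulting beta coefficients define the ensemble.
Ensemble scores are converted to burnout probabilities with a logistic
sigmoid centered at the 3.325 threshold, scaled by the calibration
residual SD.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import ElasticNetCV
from sklearn.preprocessing import StandardScaler

from . import metrics
from .exceptions import (
    DegenerateOutcomeError,
    DomainError,
    SchemaError,
    ValidationError,
)
from .propensity import SCHEMAS, design_matrix, grouped_folds
from .scoring import BURNOUT_THRESHOLD

ELASTIC_NET_L1_RATIO = 0.5
N_ALPHAS = 40


def split_train_calibrate(
    physicians: Sequence, frac_train: float, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Physician-level train/calibration split.

    Deterministic given seed; the training side holds
    round(frac_train x n) physicians, clamped so both sides are
    nonempty.
    """
    if not 0.0 < frac_train < 1.0:
        raise DomainError("frac_train must be in (0, 1)")
    uniq = np.unique(np.asarray(physicians))
    if len(uniq) < 2:
        raise DomainError("need at least 2 physicians to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq)
    n_train = int(np.floor(frac_train * len(uniq) + 0.5))
    n_train = min(max(n_train, 1), len(uniq) - 1)
    return np.sort(order[:n_train]), np.sort(order[n_train:])


@dataclass
class LinearPredictor:
    """A penalized linear model with its standardization parameters."""

    feature_names: List[str]
    center: np.ndarray
    scale: np.ndarray
    coef: np.ndarray
    intercept: float
    alpha: float

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        x = design_matrix(features)
        missing = [c for c in self.feature_names if c not in x.columns]
        if missing:
            raise SchemaError(f"missing feature column(s): {missing}")
        xv = x[self.feature_names].to_numpy()
        z = (xv - self.center) / self.scale
        return z @ self.coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "center": [float(v) for v in self.center],
            "scale": [float(v) for v in self.scale],
            "coef": [float(v) for v in self.coef],
            "intercept": float(self.intercept),
            "alpha": float(self.alpha),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearPredictor":
        return cls(
            feature_names=list(d["feature_names"]),
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            alpha=float(d["alpha"]),
        )


def fit_weighted_burnout_model(
    features: pd.DataFrame,
    scores: Sequence[float],
    weights: Sequence[float],
    seed: int = 0,
    n_folds: int = 10,
) -> LinearPredictor:
    """Weighted elastic-net regression of burnout score on features.

    Penalty strength is chosen by physician-grouped cross-validated MSE
    within the training data. Coefficients are on the standardized
    feature scale.
    """
    y = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValidationError("weights must be nonnegative")
    if not np.any(w > 0):
        raise ValidationError("weights must not be all zero")
    if len(np.unique(y)) < 2:
        raise DegenerateOutcomeError("scores must take at least 2 distinct values")
    x = design_matrix(features)
    xv = x.to_numpy()
    scaler = StandardScaler().fit(xv)
    scale = np.where(scaler.scale_ > 0, scaler.scale_, 1.0)
    z = (xv - scaler.mean_) / scale

    folds = grouped_folds(features["physician_id"].to_numpy(), n_folds, seed)
    splits = [
        (np.flatnonzero(folds != f), np.flatnonzero(folds == f))
        for f in np.unique(folds)
    ]
    enet = ElasticNetCV(
        l1_ratio=ELASTIC_NET_L1_RATIO,
        alphas=N_ALPHAS,
        cv=splits,
        random_state=seed,
        max_iter=5000,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        enet.fit(z, y, sample_weight=w)
    return LinearPredictor(
        feature_names=list(x.columns),
        center=np.asarray(scaler.mean_, dtype=float),
        scale=np.asarray(scale, dtype=float),
        coef=np.asarray(enet.coef_, dtype=float),
        intercept=float(enet.intercept_),
        alpha=float(enet.alpha_),
    )


def fit_bias_correction(
    actual: Sequence[float], predictions: Sequence[Sequence[float]]
) -> np.ndarray:
    """OLS of actual scores on the three schema predictions.

    Returns beta = (intercept, b_unweighted, b_inverse_p, b_one_minus_p).
    Rank-deficient designs (collinear predictions) fall back to a
    tiny-ridge solve with a warning.
    """
    y = np.asarray(actual, dtype=float)
    preds = np.column_stack([np.asarray(p, dtype=float) for p in predictions])
    if preds.shape[1] != 3:
        raise ValidationError("exactly 3 prediction vectors required")
    if len(y) < 5:
        raise DomainError("calibration set must have >= 5 observations")
    if not np.all(np.isfinite(preds)):
        raise ValidationError("predictions must be finite")
    design = np.column_stack([np.ones(len(y)), preds])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("collinear predictions; falling back to tiny-ridge solve")
        lam = 1e-8
        a = design.T @ design + lam * np.eye(design.shape[1])
        return np.linalg.solve(a, design.T @ y)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return beta


@dataclass
class EnsembleModel:
    """Trained ensemble: per-schema predictors, beta, sigmoid scale.

    ``predictors`` are the models fit on the training split (used for
    held-out evaluation); ``final_predictors``, when present, are refit
    on all responses and used for nonresponder prediction.
    """

    predictors: Dict[str, LinearPredictor]
    beta: np.ndarray
    sigmoid_scale: float
    threshold: float = BURNOUT_THRESHOLD
    operating_threshold: Optional[float] = None
    final_predictors: Optional[Dict[str, LinearPredictor]] = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (4,):
            raise ValidationError("beta must have 4 coefficients")
        if self.sigmoid_scale <= 0:
            raise DomainError("sigmoid scale must be > 0")

    def schema_predictions(
        self, features: pd.DataFrame, final: bool = False
    ) -> np.ndarray:
        preds = self.final_predictors if final and self.final_predictors else self.predictors
        return np.column_stack([preds[s].predict(features) for s in SCHEMAS])

    def to_json(self, path: str | Path) -> None:
        d = {
            "format_version": 1,
            "schemas": list(SCHEMAS),
            "predictors": {k: v.to_dict() for k, v in self.predictors.items()},
            "final_predictors": (
                {k: v.to_dict() for k, v in self.final_predictors.items()}
                if self.final_predictors
                else None
            ),
            "beta": [float(v) for v in self.beta],
            "sigmoid_scale": float(self.sigmoid_scale),
            "threshold": float(self.threshold),
            "operating_threshold": (
                None if self.operating_threshold is None
                else float(self.operating_threshold)
            ),
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "EnsembleModel":
        d = json.loads(Path(path).read_text())
        return cls(
            predictors={k: LinearPredictor.from_dict(v)
                        for k, v in d["predictors"].items()},
            final_predictors=(
                {k: LinearPredictor.from_dict(v)
                 for k, v in d["final_predictors"].items()}
                if d.get("final_predictors")
                else None
            ),
            beta=np.asarray(d["beta"], dtype=float),
            sigmoid_scale=float(d["sigmoid_scale"]),
            threshold=float(d["threshold"]),
            operating_threshold=d.get("operating_threshold"),
        )


def predict_ensemble(
    features: pd.DataFrame, model: EnsembleModel, final: bool = False
) -> np.ndarray:
    """Bias-corrected ensemble score: beta0 + sum_k beta_k yhat_k.

    Not clamped to [0, 10]; probabilities, not raw scores, feed the
    population estimates.
    """
    preds = model.schema_predictions(features, final=final)
    return model.beta[0] + preds @ model.beta[1:]


def score_to_probability(
    score: np.ndarray | float, model_or_scale: EnsembleModel | float
) -> np.ndarray | float:
    """Probability that the true score is at/above the burnout threshold.

    logistic((score - threshold) / s); exactly 0.5 at the threshold and
    strictly increasing in score.
    """
    if isinstance(model_or_scale, EnsembleModel):
        s = model_or_scale.sigmoid_scale
        thr = model_or_scale.threshold
    else:
        s = float(model_or_scale)
        thr = BURNOUT_THRESHOLD
    if s <= 0:
        raise DomainError("sigmoid scale must be > 0")
    out = expit((np.asarray(score, dtype=float) - thr) / s)
    return float(out) if np.isscalar(score) else out


@dataclass
class EvaluationReport:
    auroc: float
    auroc_ci: Tuple[float, float]
    auprc: float
    auprc_ci: Tuple[float, float]
    sensitivity: float
    specificity: float
    operating_threshold: float
    n_boot: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["auroc", "auprc", "sensitivity", "specificity",
                            "operating_threshold"],
                "value": [self.auroc, self.auprc, self.sensitivity,
                           self.specificity, self.operating_threshold],
                "ci_low": [self.auroc_ci[0], self.auprc_ci[0], np.nan, np.nan, np.nan],
                "ci_high": [self.auroc_ci[1], self.auprc_ci[1], np.nan, np.nan, np.nan],
            }
        )


def evaluate(
    probabilities: Sequence[float],
    actual: Sequence[bool],
    n_boot: int = 1000,
    seed: int = 0,
    groups: Optional[Sequence] = None,
    threshold: Optional[float] = None,
) -> EvaluationReport:
    """AUROC/AUPRC with bootstrap CIs plus sensitivity/specificity.

    ``threshold`` is the probability operating point (normally chosen by
    Youden's J on the calibration split); when omitted it is derived
    from the supplied data. Bootstrap resamples physicians when
    ``groups`` is given, observations otherwise.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(actual, dtype=int)
    point_auroc = metrics.auroc(y, p)
    point_auprc = metrics.auprc(y, p)
    if threshold is None:
        threshold = metrics.youden_threshold(y, p)
    sens, spec = metrics.sensitivity_specificity(y, p, threshold)
    g = np.asarray(groups) if groups is not None else np.arange(len(y))

    def make_stat(fn):
        def stat(idx: np.ndarray) -> float:
            if len(np.unique(y[idx])) < 2:
                return float("nan")
            return fn(y[idx], p[idx])
        return stat

    roc_ci = metrics.bootstrap_ci_by_group(make_stat(metrics.auroc), g, n_boot, seed)
    prc_ci = metrics.bootstrap_ci_by_group(make_stat(metrics.auprc), g, n_boot, seed)
    return EvaluationReport(
        auroc=point_auroc,
        auroc_ci=(min(roc_ci[0], point_auroc), max(roc_ci[1], point_auroc)),
        auprc=point_auprc,
        auprc_ci=(min(prc_ci[0], point_auprc), max(prc_ci[1], point_auprc)),
        sensitivity=sens,
        specificity=spec,
        operating_threshold=float(threshold),
        n_boot=n_boot,
        seed=seed,
    )
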