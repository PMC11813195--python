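"""Cross-validated response propensities and observation weights.

The propensity model is an elastic-net penalized logistic regression of
the response indicator on the EHR-use features, fit with 10-fold
cross-validation grouped by physician (both invitations of a physician
share a fold). Penalty strength is chosen by pooled out-of-fold
deviance over a fixed grid, glmnet-style, so every invitation's stored
propensity comes from a model that never saw it.

Three weighting schemas turn propensities into observation weights:

* ``unweighted``  — weight 1 (approximates the responder population);
* ``inverse_p``   — 1/max(p, 0.1) (approximates the full population;
  the 0.1 floor prevents extreme weights, so weights lie in [1, 10]);
* ``one_minus_p`` — 1 - p (approximates the nonresponders; in [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.preprocessing import StandardScaler

from . import metrics
from .exceptions import DegenerateOutcomeError, DomainError, ValidationError

SCHEMA_UNWEIGHTED = "unweighted"
SCHEMA_INVERSE_P = "inverse_p"
SCHEMA_ONE_MINUS_P = "one_minus_p"
SCHEMAS = (SCHEMA_UNWEIGHTED, SCHEMA_INVERSE_P, SCHEMA_ONE_MINUS_P)

#: Propensity floor used by the inverse_p schema only.
PROPENSITY_FLOOR = 0.1

DEFAULT_CS = np.logspace(-2.0, 2.0, 5)
ELASTIC_NET_L1_RATIO = 0.5

ID_COLUMNS = ("physician_id", "wave")


@dataclass
class PropensityResult:
    """Out-of-fold propensities plus the refit coefficient report.

    ``table`` has one row per invitation: physician_id, wave, fold,
    propensity. ``coefficients`` are on the standardized feature scale.
    """

    table: pd.DataFrame
    coefficients: pd.Series
    intercept: float
    C: float
    l1_ratio: float

    @property
    def propensities(self) -> np.ndarray:
        return self.table["propensity"].to_numpy()


def design_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Numeric model matrix from a feature table.

    Identifier columns are dropped; non-numeric columns are one-hot
    encoded (first level dropped). Nonnegative numeric columns (the
    count-like, right-skewed EHR-use measures) additionally get a
    log1p companion so penalized linear models can pick whichever
    scale fits; the rule is data-independent so train and predict
    matrices always align. Column order is deterministic.
    """
    x = features.drop(columns=[c for c in ID_COLUMNS if c in features.columns])
    x = pd.get_dummies(x, drop_first=True, dtype=float)
    x = x.astype(float)
    for col in list(x.columns):
        x[f"{col}__log1p"] = np.log1p(x[col].clip(lower=0.0))
    return x[sorted(x.columns)]


def grouped_folds(physician_ids: Sequence, n_folds: int, seed: int) -> np.ndarray:
    """Fold id (0-based) per row; all rows of a physician share a fold."""
    ids = np.asarray(physician_ids)
    uniq = np.unique(ids)
    if n_folds < 2:
        raise DomainError("n_folds must be >= 2")
    n_folds = min(n_folds, len(uniq))
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq)
    assignment = {pid: i % n_folds for i, pid in enumerate(order)}
    return np.array([assignment[p] for p in ids])


def fit_propensity(
    features: pd.DataFrame,
    responses: Sequence[bool],
    n_folds: int = 10,
    seed: int = 0,
    Cs: Optional[Sequence[float]] = None,
) -> PropensityResult:
    """Fit the grouped cross-validated propensity model.

    Returns out-of-fold response propensities for every invitation and
    the full-data refit at the deviance-optimal penalty.
    """
    y = np.asarray(responses, dtype=bool)
    if y.all():
        raise DegenerateOutcomeError("all invitations are responses")
    if not y.any():
        raise DegenerateOutcomeError("all invitations are nonresponses")
    x = design_matrix(features)
    xv = x.to_numpy()
    folds = grouped_folds(features["physician_id"].to_numpy(), n_folds, seed)
    cs = np.asarray(Cs if Cs is not None else DEFAULT_CS, dtype=float)

    oof = np.full((len(y), len(cs)), np.nan)
    for f in np.unique(folds):
        tr = folds != f
        te = ~tr
        if y[tr].all() or not y[tr].any():
            # degenerate training fold: fall back to the training response rate
            oof[te, :] = y[tr].mean()
            continue
        scaler = StandardScaler().fit(xv[tr])
        xtr = scaler.transform(xv[tr])
        xte = scaler.transform(xv[te])
        clf = LogisticRegression(
            l1_ratio=ELASTIC_NET_L1_RATIO,
            solver="saga",
            max_iter=5000,
            tol=1e-4,
            warm_start=True,
            random_state=seed,
        )
        for ci, c in enumerate(cs):
            clf.C = c
            clf.fit(xtr, y[tr])
            oof[te, ci] = clf.predict_proba(xte)[:, 1]

    deviances = [log_loss(y, np.clip(oof[:, ci], 1e-12, 1 - 1e-12))
                 for ci in range(len(cs))]
    best = int(np.argmin(deviances))
    p = np.clip(oof[:, best], 1e-6, 1.0)

    scaler = StandardScaler().fit(xv)
    final = LogisticRegression(
        l1_ratio=ELASTIC_NET_L1_RATIO,
        solver="saga",
        C=float(cs[best]),
        max_iter=5000,
        tol=1e-4,
        random_state=seed,
    ).fit(scaler.transform(xv), y)

    table = pd.DataFrame(
        {
            "physician_id": features["physician_id"].to_numpy(),
            "wave": features["wave"].to_numpy(),
            "fold": folds + 1,
            "propensity": p,
        }
    )
    return PropensityResult(
        table=table,
        coefficients=pd.Series(final.coef_[0], index=x.columns),
        intercept=float(final.intercept_[0]),
        C=float(cs[best]),
        l1_ratio=ELASTIC_NET_L1_RATIO,
    )


def compute_weights(p: np.ndarray | float, schema: str) -> np.ndarray | float:
    """Observation weight(s) for one schema from propensity value(s)."""
    scalar = np.isscalar(p)
    arr = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any((arr <= 0) | (arr > 1)):
        raise DomainError("propensities must lie in (0, 1]")
    if schema == SCHEMA_UNWEIGHTED:
        w = np.ones_like(arr)
    elif schema == SCHEMA_INVERSE_P:
        w = 1.0 / np.maximum(arr, PROPENSITY_FLOOR)
    elif schema == SCHEMA_ONE_MINUS_P:
        w = 1.0 - arr
    else:
        raise ValidationError(f"unknown weight schema {schema!r}")
    return float(w[0]) if scalar else w


def evaluate_response_auroc(
    result: PropensityResult,
    responses: Sequence[bool],
    n_boot: int = 1000,
    seed: int = 0,
) -> Tuple[float, Tuple[float, float]]:
    """Out-of-fold response AUROC with a physician-bootstrap CI."""
    y = np.asarray(responses, dtype=int)
    p = result.propensities
    point = metrics.auroc(y, p)

    def stat(idx: np.ndarray) -> float:
        if len(np.unique(y[idx])) < 2:
            return float("nan")
        return metrics.auroc(y[idx], p[idx])

    lo, hi = metrics.bootstrap_ci_by_group(
        stat, result.table["physician_id"].to_numpy(), n_boot, seed
    )
    return point, (min(lo, point), max(hi, point))
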