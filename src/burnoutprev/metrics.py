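"""Classification metrics with physician-level bootstrap CIs."""

from __future__ import annotations

from typing import Callable, Tuple

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve

from .exceptions import DegenerateOutcomeError


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise DegenerateOutcomeError("both outcome classes must be present")


def auroc(y_true, y_score) -> float:
    """AUROC with the midrank (trapezoidal) ties convention."""
    y_true = np.asarray(y_true, dtype=int)
    _check_two_classes(y_true)
    return float(roc_auc_score(y_true, np.asarray(y_score, dtype=float)))


def auprc(y_true, y_score) -> float:
    """Area under the precision-recall curve (step interpolation)."""
    y_true = np.asarray(y_true, dtype=int)
    _check_two_classes(y_true)
    return float(average_precision_score(y_true, np.asarray(y_score, dtype=float)))


def youden_threshold(y_true, y_score) -> float:
    """Score threshold maximizing Youden's J = sensitivity + specificity - 1."""
    y_true = np.asarray(y_true, dtype=int)
    _check_two_classes(y_true)
    fpr, tpr, thr = roc_curve(y_true, np.asarray(y_score, dtype=float))
    return float(thr[np.argmax(tpr - fpr)])


def sensitivity_specificity(y_true, y_score, threshold: float) -> Tuple[float, float]:
    """Sensitivity and specificity of ``score >= threshold``."""
    y_true = np.asarray(y_true, dtype=int)
    pred = np.asarray(y_score, dtype=float) >= threshold
    pos = y_true == 1
    neg = ~pos
    sens = float(pred[pos].mean()) if pos.any() else float("nan")
    spec = float((~pred[neg]).mean()) if neg.any() else float("nan")
    return sens, spec


def bootstrap_ci_by_group(
    stat: Callable[[np.ndarray], float],
    groups,
    n_boot: int,
    seed: int,
    alpha: float = 0.05,
) -> Tuple[float, float]:
    """Percentile bootstrap CI resampling whole groups (physicians).

    ``stat`` receives an integer row index array (the rows belonging to
    the resampled groups, with multiplicity) and returns the statistic,
    or NaN when undefined for that resample (dropped).
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    members = {g: np.flatnonzero(groups == g) for g in uniq}
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_boot):
        chosen = rng.choice(uniq, size=len(uniq), replace=True)
        idx = np.concatenate([members[g] for g in chosen])
        v = stat(idx)
        if np.isfinite(v):
            vals.append(v)
    if not vals:
        return float("nan"), float("nan")
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
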