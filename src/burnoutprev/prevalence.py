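"""Population prevalence combination and the response-rate-reduction check.

The population burnout prevalence combines the observed burnout flags
among responses with model-predicted burnout probabilities among
nonresponses. The synthetic reduction experiment conceals the responses
of low-propensity physicians (selected by repeated triangular jitter of
per-physician mean propensity), reruns the whole pipeline on the
reduced data, and compares the resulting estimate with the fully
informed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError

LEVEL_SURVEY = "survey"
LEVEL_PHYSICIAN = "physician"


@dataclass
class PrevalenceEstimate:
    """Observed, predicted-nonresponder, and combined prevalence."""

    n_responses: int
    observed_prevalence: float
    n_nonresponses: int
    predicted_nonresponder_prevalence: float
    predicted_ci: Tuple[float, float]
    population_prevalence: float
    population_ci: Tuple[float, float]
    weighting_level: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quantity": ["observed", "predicted_nonresponder", "population"],
                "prevalence": [
                    self.observed_prevalence,
                    self.predicted_nonresponder_prevalence,
                    self.population_prevalence,
                ],
                "ci_low": [np.nan, self.predicted_ci[0], self.population_ci[0]],
                "ci_high": [np.nan, self.predicted_ci[1], self.population_ci[1]],
                "n": [self.n_responses, self.n_nonresponses,
                      self.n_responses + self.n_nonresponses],
            }
        )


def combine_prevalence(
    observed_flags: Sequence[bool],
    predicted_probs: Sequence[float],
    weighting_level: str = LEVEL_SURVEY,
    n_boot: int = 500,
    seed: int = 0,
    observed_groups: Optional[Sequence] = None,
    predicted_groups: Optional[Sequence] = None,
) -> PrevalenceEstimate:
    """Combine observed flags and predicted probabilities.

    Survey-level: (sum flags + sum probs) / (n_resp + n_nonresp).
    Physician-level: mean over physicians of per-physician means.
    CIs come from a physician bootstrap with Bernoulli resampling of
    the predicted probabilities to propagate prediction uncertainty.
    """
    obs = np.asarray(observed_flags, dtype=float)
    pred = np.asarray(predicted_probs, dtype=float)
    if len(obs) == 0 and len(pred) == 0:
        raise DomainError("need at least one response or one nonresponse")
    if weighting_level not in (LEVEL_SURVEY, LEVEL_PHYSICIAN):
        raise ConfigurationError(f"unknown weighting_level {weighting_level!r}")
    if np.any((pred < 0) | (pred > 1)):
        raise DomainError("predicted probabilities must lie in [0, 1]")

    og = (np.asarray(observed_groups) if observed_groups is not None
          else np.array([f"r{i}" for i in range(len(obs))]))
    pg = (np.asarray(predicted_groups) if predicted_groups is not None
          else np.array([f"n{i}" for i in range(len(pred))]))

    def point(values: np.ndarray, groups: np.ndarray, level: str) -> float:
        if len(values) == 0:
            return float("nan")
        if level == LEVEL_SURVEY:
            return float(values.mean())
        return float(pd.Series(values).groupby(groups).mean().mean())

    observed_prev = point(obs, og, weighting_level)
    predicted_prev = point(pred, pg, weighting_level)
    if weighting_level == LEVEL_SURVEY:
        population = (obs.sum() + pred.sum()) / (len(obs) + len(pred))
    else:
        per_phys = pd.concat(
            [pd.Series(obs).groupby(og).mean(), pd.Series(pred).groupby(pg).mean()]
        )
        population = float(per_phys.groupby(per_phys.index).mean().mean())

    # Bootstrap: resample physicians in each arm; Bernoulli-redraw the
    # predicted probabilities to propagate prediction uncertainty.
    rng = np.random.default_rng(seed)
    pred_vals, pop_vals = [], []
    uniq_o = np.unique(og) if len(obs) else np.array([])
    uniq_p = np.unique(pg) if len(pred) else np.array([])
    members_o = {u: np.flatnonzero(og == u) for u in uniq_o}
    members_p = {u: np.flatnonzero(pg == u) for u in uniq_p}
    for _ in range(n_boot):
        if len(uniq_o):
            ch = rng.choice(uniq_o, size=len(uniq_o), replace=True)
            oidx = np.concatenate([members_o[u] for u in ch])
            bo, bog = obs[oidx], og[oidx]
        else:
            bo, bog = obs, og
        if len(uniq_p):
            ch = rng.choice(uniq_p, size=len(uniq_p), replace=True)
            pidx = np.concatenate([members_p[u] for u in ch])
            bp = (rng.uniform(size=len(pidx)) < pred[pidx]).astype(float)
            bpg = pg[pidx]
        else:
            bp, bpg = pred, pg
        if len(bp):
            pred_vals.append(point(bp, bpg, weighting_level))
        if weighting_level == LEVEL_SURVEY:
            pop_vals.append((bo.sum() + bp.sum()) / (len(bo) + len(bp)))
        else:
            combo = pd.concat(
                [pd.Series(bo).groupby(bog).mean(), pd.Series(bp).groupby(bpg).mean()]
            )
            pop_vals.append(float(combo.groupby(combo.index).mean().mean()))

    def ci(vals, pt):
        if not vals or not np.isfinite(pt):
            return (float("nan"), float("nan"))
        lo, hi = np.quantile(vals, [0.025, 0.975])
        return (min(float(lo), pt), max(float(hi), pt))

    return PrevalenceEstimate(
        n_responses=len(obs),
        observed_prevalence=observed_prev,
        n_nonresponses=len(pred),
        predicted_nonresponder_prevalence=predicted_prev,
        predicted_ci=ci(pred_vals, predicted_prev),
        population_prevalence=float(population),
        population_ci=ci(pop_vals, float(population)),
        weighting_level=weighting_level,
    )


@dataclass
class ReductionConfig:
    """Configuration of the synthetic response-rate reduction."""

    jitter_low: float = -0.5
    jitter_mode: float = 0.0
    jitter_high: float = 0.5
    frac_selected: float = 0.20
    n_cycles: int = 100
    selection_threshold: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.jitter_low < self.jitter_mode < self.jitter_high:
            raise ConfigurationError("jitter_low < jitter_mode < jitter_high required")
        # frac_selected == 0 is admitted as the explicit no-op limit
        if not 0.0 <= self.frac_selected < 1.0:
            raise ConfigurationError("frac_selected must be in [0, 1)")
        if self.n_cycles < 1:
            raise ConfigurationError("n_cycles must be >= 1")
        if not 1 <= self.selection_threshold <= self.n_cycles:
            raise ConfigurationError(
                "selection_threshold must be in [1, n_cycles]"
            )
        if self.seed is None:
            raise ConfigurationError("seed must be explicit")


def select_synthetic_nonresponders(
    propensities: pd.Series, config: ReductionConfig
) -> Set:
    """Choose synthetic nonresponders by repeated jitter-and-rank.

    ``propensities`` maps physician_id -> mean response propensity. Per
    cycle, independent triangular jitter is added and the lowest
    ``frac_selected`` fraction (floor, min 1) become candidates; a
    physician selected in at least ``selection_threshold`` of
    ``n_cycles`` cycles is returned. Deterministic given the seed.
    """
    if config.frac_selected == 0.0:
        return set()
    ids = np.asarray(propensities.index)
    vals = propensities.to_numpy(dtype=float)
    if len(ids) < 5:
        raise DomainError("need at least 5 responding physicians")
    k = max(int(np.floor(config.frac_selected * len(ids))), 1)
    rng = np.random.default_rng(config.seed)
    counts = np.zeros(len(ids), dtype=int)
    for _ in range(config.n_cycles):
        jitter = rng.triangular(
            config.jitter_low, config.jitter_mode, config.jitter_high, size=len(ids)
        )
        lowest = np.argsort(vals + jitter, kind="stable")[:k]
        counts[lowest] += 1
    return set(ids[counts >= config.selection_threshold])


@dataclass
class ReductionResult:
    """Outcome of the synthetic response-rate-reduction experiment."""

    selected: Set
    full_estimate: PrevalenceEstimate
    reduced_estimate: PrevalenceEstimate
    reduced_observed_prevalence: float
    reduced_predicted_prevalence: float
    reduced_population_prevalence: float

    @property
    def shift(self) -> float:
        """Change in population prevalence vs the fully informed run."""
        return (
            self.reduced_estimate.population_prevalence
            - self.full_estimate.population_prevalence
        )
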