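"""End-to-end orchestration of the estimation pipeline.

Stages, in order: score surveys, categorize responders, fit
cross-validated response propensities, split always responders into
train/calibration, fit the three weighted burnout models, calibrate the
bias-corrected ensemble and sigmoid scale, evaluate on partial
responders, refit on all responses, predict nonresponders, and combine
into the population prevalence estimate.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import compare_groups, rows_to_frame
from .ensemble import (
    EnsembleModel,
    EvaluationReport,
    evaluate,
    fit_bias_correction,
    fit_weighted_burnout_model,
    predict_ensemble,
    score_to_probability,
    split_train_calibrate,
)
from .exceptions import ConfigurationError, DomainError
from .metrics import youden_threshold
from .prevalence import LEVEL_SURVEY, PrevalenceEstimate, combine_prevalence
from .propensity import (
    SCHEMAS,
    PropensityResult,
    compute_weights,
    evaluate_response_auroc,
    fit_propensity,
)
from .scoring import CATEGORY_ALWAYS, CATEGORY_PARTIAL, categorize_cohort, score_records

MIN_SIGMOID_SCALE = 1e-3


@dataclass
class PipelineConfig:
    """All knobs and seeds of one pipeline run. Seeds are explicit."""

    n_folds: int = 10
    frac_train: float = 0.8
    n_boot: int = 200
    weighting_level: str = LEVEL_SURVEY
    seed_folds: Optional[int] = None
    seed_split: Optional[int] = None
    seed_boot: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("seed_folds", "seed_split", "seed_boot"):
            if getattr(self, name) is None:
                raise ConfigurationError(f"{name} must be explicit")
        if not 0.0 < self.frac_train < 1.0:
            raise ConfigurationError("frac_train must be in (0, 1)")
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")

    @classmethod
    def with_seed(cls, seed: int, **overrides) -> "PipelineConfig":
        """Derive per-stage seeds deterministically from one master seed."""
        ss = np.random.SeedSequence(seed).generate_state(3)
        params = dict(
            seed_folds=int(ss[0] % 2**31),
            seed_split=int(ss[1] % 2**31),
            seed_boot=int(ss[2] % 2**31),
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class AnalysisResult:
    """Everything one pipeline run produces."""

    scores: pd.DataFrame
    categories: pd.Series
    propensity: PropensityResult
    response_auroc: float
    response_auroc_ci: tuple
    model: EnsembleModel
    evaluation: Optional[EvaluationReport]
    estimate: PrevalenceEstimate
    weights: pd.DataFrame


def _merge_propensity(scores: pd.DataFrame, prop: PropensityResult) -> pd.DataFrame:
    return scores.merge(
        prop.table[["physician_id", "wave", "propensity"]],
        on=["physician_id", "wave"],
        how="left",
    )


def analyze_cohort(
    records: pd.DataFrame,
    features: pd.DataFrame,
    config: PipelineConfig,
) -> AnalysisResult:
    """Run the full estimation pipeline on one cohort in memory."""
    scores = score_records(records)
    categories = categorize_cohort(scores)

    prop = fit_propensity(
        features,
        scores["is_response"].to_numpy(),
        n_folds=config.n_folds,
        seed=config.seed_folds,
    )
    resp_auroc, resp_ci = evaluate_response_auroc(
        prop, scores["is_response"].to_numpy(), n_boot=config.n_boot,
        seed=config.seed_boot,
    )
    merged = _merge_propensity(scores, prop)

    resp_mask = merged["is_response"].to_numpy()
    resp_rows = merged[resp_mask].reset_index(drop=True)
    feat_keyed = features.set_index(["physician_id", "wave"])

    def rows_features(rows: pd.DataFrame) -> pd.DataFrame:
        sel = feat_keyed.loc[list(zip(rows["physician_id"], rows["wave"]))]
        return sel.reset_index()

    weights = pd.DataFrame(
        {
            "physician_id": resp_rows["physician_id"],
            "wave": resp_rows["wave"],
            **{
                s: compute_weights(resp_rows["propensity"].to_numpy(), s)
                for s in SCHEMAS
            },
        }
    )

    always = categories.index[categories == CATEGORY_ALWAYS].to_numpy()
    partial = categories.index[categories == CATEGORY_PARTIAL].to_numpy()
    if len(always) < 5:
        raise DomainError("fewer than 5 always-responder physicians; cannot train")
    train_phys, calib_phys = split_train_calibrate(
        always, config.frac_train, config.seed_split
    )

    train_rows = resp_rows[resp_rows["physician_id"].isin(train_phys)]
    calib_rows = resp_rows[resp_rows["physician_id"].isin(calib_phys)]
    train_x = rows_features(train_rows)
    calib_x = rows_features(calib_rows)

    predictors = {}
    for schema in SCHEMAS:
        w = compute_weights(train_rows["propensity"].to_numpy(), schema)
        predictors[schema] = fit_weighted_burnout_model(
            train_x,
            train_rows["score"].to_numpy(),
            w,
            seed=config.seed_split,
            n_folds=config.n_folds,
        )

    calib_preds = np.column_stack(
        [predictors[s].predict(calib_x) for s in SCHEMAS]
    )
    calib_actual = calib_rows["score"].to_numpy()
    beta = fit_bias_correction(calib_actual, calib_preds.T)
    calib_ens = beta[0] + calib_preds @ beta[1:]
    # logistic error model matched to the calibration residual spread: a
    # logistic with scale s has SD s*pi/sqrt(3), so invert that factor
    resid_sd = float(np.std(calib_actual - calib_ens))
    s_scale = max(resid_sd * np.sqrt(3.0) / np.pi, MIN_SIGMOID_SCALE)

    calib_probs = score_to_probability(calib_ens, s_scale)
    calib_flags = calib_rows["burnout"].to_numpy(dtype=float).astype(int)
    if len(np.unique(calib_flags)) >= 2:
        op_thr = youden_threshold(calib_flags, calib_probs)
    else:
        op_thr = 0.5

    model = EnsembleModel(
        predictors=predictors,
        beta=beta,
        sigmoid_scale=s_scale,
        operating_threshold=op_thr,
    )

    # Held-out evaluation on partial responders' response-year surveys.
    evaluation = None
    test_rows = resp_rows[resp_rows["physician_id"].isin(partial)]
    if len(test_rows) >= 5:
        test_flags = test_rows["burnout"].to_numpy(dtype=float).astype(int)
        if len(np.unique(test_flags)) >= 2:
            test_x = rows_features(test_rows)
            test_probs = score_to_probability(predict_ensemble(test_x, model), model)
            evaluation = evaluate(
                test_probs,
                test_flags,
                n_boot=config.n_boot,
                seed=config.seed_boot,
                groups=test_rows["physician_id"].to_numpy(),
                threshold=op_thr,
            )

    # Final refit on all responses for nonresponder prediction.
    final = {}
    for schema in SCHEMAS:
        w = compute_weights(resp_rows["propensity"].to_numpy(), schema)
        final[schema] = fit_weighted_burnout_model(
            rows_features(resp_rows),
            resp_rows["score"].to_numpy(),
            w,
            seed=config.seed_split,
            n_folds=config.n_folds,
        )
    model.final_predictors = final

    nonresp_rows = merged[~resp_mask].reset_index(drop=True)
    if len(nonresp_rows):
        nonresp_x = rows_features(nonresp_rows)
        nonresp_scores = predict_ensemble(nonresp_x, model, final=True)
        nonresp_probs = score_to_probability(nonresp_scores, model)
    else:
        nonresp_probs = np.array([])

    estimate = combine_prevalence(
        resp_rows["burnout"].to_numpy(dtype=float).astype(bool),
        nonresp_probs,
        weighting_level=config.weighting_level,
        n_boot=config.n_boot,
        seed=config.seed_boot,
        observed_groups=resp_rows["physician_id"].to_numpy(),
        predicted_groups=(
            nonresp_rows["physician_id"].to_numpy() if len(nonresp_rows) else None
        ),
    )

    return AnalysisResult(
        scores=scores,
        categories=categories,
        propensity=prop,
        response_auroc=resp_auroc,
        response_auroc_ci=resp_ci,
        model=model,
        evaluation=evaluation,
        estimate=estimate,
        weights=weights,
    )


def run_pipeline(
    records: pd.DataFrame,
    features: pd.DataFrame,
    config: PipelineConfig,
    outdir: str | Path,
) -> AnalysisResult:
    """Run the pipeline and write all artifacts to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = analyze_cohort(records, features, config)

    result.scores.to_csv(outdir / "scores.csv", index=False)
    result.categories.rename("category").to_csv(outdir / "categories.csv")
    try:
        rows = compare_groups(features, result.categories, seed=config.seed_boot)
        rows_to_frame(rows).to_csv(outdir / "comparisons.csv", index=False)
    except DomainError:
        (outdir / "comparisons.csv").write_text("measure,test,p_value\n")
    result.propensity.table.to_csv(outdir / "propensities.csv", index=False)
    result.propensity.coefficients.rename("coefficient").to_csv(
        outdir / "propensity_coefficients.csv"
    )
    result.weights.to_csv(outdir / "weights.csv", index=False)
    result.model.to_json(outdir / "model.json")
    if result.evaluation is not None:
        result.evaluation.to_frame().to_csv(outdir / "evaluation.csv", index=False)
    result.estimate.to_frame().to_csv(outdir / "prevalence.csv", index=False)

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config": dataclasses.asdict(config),
        "response_auroc": result.response_auroc,
        "response_auroc_ci": list(result.response_auroc_ci),
        "population_prevalence": result.estimate.population_prevalence,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return result


def run_reduction_experiment(
    records: pd.DataFrame,
    features: pd.DataFrame,
    config: PipelineConfig,
    reduction,
):
    """Synthetic response-rate-reduction validation.

    Runs the full pipeline, conceals the responses of jitter-selected
    low-propensity physicians, reruns every stage on the reduced
    response set, and reports the reduced observed / predicted /
    combined triple next to the fully informed estimate.
    """
    from .prevalence import ReductionResult, select_synthetic_nonresponders
    from .scoring import ITEM_COLUMNS

    full = analyze_cohort(records, features, config)
    merged = _merge_propensity(full.scores, full.propensity)
    responders = merged[merged["is_response"]]
    mean_prop = responders.groupby("physician_id")["propensity"].mean()
    selected = select_synthetic_nonresponders(mean_prop, reduction)

    reduced_records = records.copy()
    conceal = reduced_records["physician_id"].isin(selected)
    reduced_records.loc[conceal, ITEM_COLUMNS] = np.nan
    n_responding = (
        score_records(reduced_records)
        .groupby("physician_id")["is_response"]
        .any()
        .sum()
    )
    if n_responding < 10:
        raise DomainError("reduced response set has fewer than 10 physicians")

    reduced = analyze_cohort(reduced_records, features, config)
    return ReductionResult(
        selected=selected,
        full_estimate=full.estimate,
        reduced_estimate=reduced.estimate,
        reduced_observed_prevalence=reduced.estimate.observed_prevalence,
        reduced_predicted_prevalence=reduced.estimate.predicted_nonresponder_prevalence,
        reduced_population_prevalence=reduced.estimate.population_prevalence,
    )
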