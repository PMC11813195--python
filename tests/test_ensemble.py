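import numpy as np
import pandas as pd
import pytest

from burnoutprev import ensemble
from burnoutprev.cohort import example_config, generate_cohort
from burnoutprev.ensemble import (
    EnsembleModel,
    LinearPredictor,
    evaluate,
    fit_bias_correction,
    fit_weighted_burnout_model,
    predict_ensemble,
    score_to_probability,
    split_train_calibrate,
)
from burnoutprev.exceptions import (
    DegenerateOutcomeError,
    DomainError,
    SchemaError,
    ValidationError,
)
from burnoutprev.metrics import auprc, auroc
from burnoutprev.scoring import BURNOUT_THRESHOLD, score_records
from conftest import make_feature_table


class TestSplit:
    def test_paper_sized_split(self):
        phys = [f"p{i}" for i in range(340)]
        train, calib = split_train_calibrate(phys, 0.8, seed=0)
        assert len(train) == 272 and len(calib) == 68

    def test_five_physicians(self):
        train, calib = split_train_calibrate(list("abcde"), 0.8, seed=1)
        assert len(train) == 4 and len(calib) == 1

    def test_deterministic_and_disjoint(self):
        phys = [f"p{i}" for i in range(37)]
        a = split_train_calibrate(phys, 0.8, seed=5)
        b = split_train_calibrate(phys, 0.8, seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        assert not set(a[0]) & set(a[1])
        assert set(a[0]) | set(a[1]) == set(phys)

    def test_bad_frac(self):
        with pytest.raises(DomainError):
            split_train_calibrate(list("abcdef"), 1.0, seed=0)


class TestFitWeightedModel:
    def test_single_linear_feature_r2_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(80, 1)) * 2
        y = 2.0 * x[:, 0] + 1.0
        feats = make_feature_table(x)
        pred = fit_weighted_burnout_model(feats, y, np.ones(80), seed=0, n_folds=5)
        yhat = pred.predict(feats)
        ss = 1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)
        assert ss >= 0.99

    def test_constant_weights_match_unweighted(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(60, 3))
        y = x @ [1.0, -0.5, 0.0] + rng.normal(scale=0.2, size=60)
        feats = make_feature_table(x)
        a = fit_weighted_burnout_model(feats, y, np.ones(60), seed=2, n_folds=4)
        b = fit_weighted_burnout_model(feats, y, np.full(60, 3.0), seed=2, n_folds=4)
        assert np.allclose(a.coef, b.coef, atol=1e-8)

    def test_sign_recovery_on_synthetic_cohort(self):
        cfg = example_config(2000, seed=21)
        records, features, _ = generate_cohort(cfg)
        scores = score_records(records)
        resp = scores[scores["is_response"]]
        fk = features.set_index(["physician_id", "wave"])
        x = fk.loc[list(zip(resp["physician_id"], resp["wave"]))].reset_index()
        pred = fit_weighted_burnout_model(
            x, resp["score"].to_numpy(), np.ones(len(resp)), seed=3
        )
        coefs = pd.Series(pred.coef, index=pred.feature_names)
        for j, effect in enumerate(cfg.feature_effect_on_burnout):
            if abs(effect) < 0.5:
                continue
            combined = coefs[f"f_{j:02d}"] + coefs[f"f_{j:02d}__log1p"]
            assert np.sign(combined) == np.sign(effect)

    def test_zero_weights_rejected(self):
        feats = make_feature_table(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.raises(ValidationError):
            fit_weighted_burnout_model(feats, np.arange(10.0), np.zeros(10))

    def test_constant_scores_rejected(self):
        feats = make_feature_table(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.raises(DegenerateOutcomeError):
            fit_weighted_burnout_model(feats, np.ones(10), np.ones(10))


class TestBiasCorrection:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        actual = rng.normal(loc=3, size=6)
        preds = [rng.normal(size=6) for _ in range(3)]
        beta = fit_bias_correction(actual, preds)
        design = np.column_stack([np.ones(6), *preds])
        oracle = np.linalg.solve(design.T @ design, design.T @ actual)
        assert np.allclose(beta, oracle, atol=1e-8)

    def test_identical_predictions_fallback_reproduces_actual(self):
        rng = np.random.default_rng(5)
        actual = rng.normal(loc=3, size=10)
        with pytest.warns(UserWarning, match="collinear"):
            beta = fit_bias_correction(actual, [actual, actual, actual])
        recombined = beta[0] + np.column_stack([actual] * 3) @ beta[1:]
        assert np.allclose(recombined, actual, atol=1e-5)

    def test_perfect_single_schema(self):
        rng = np.random.default_rng(6)
        actual = rng.normal(loc=3, size=20)
        others = [rng.normal(size=20), rng.normal(size=20)]
        beta = fit_bias_correction(actual, [actual, *others])
        assert beta[1] == pytest.approx(1.0, abs=1e-8)
        assert beta[0] == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(beta[2:], 0.0, atol=1e-8)

    def test_calibration_mse_not_worse_than_best_single(self):
        # OLS optimality over the spanned space (intercept included)
        rng = np.random.default_rng(7)
        actual = rng.normal(loc=3, scale=2, size=50)
        preds = [actual + rng.normal(scale=s, size=50) for s in (0.5, 1.0, 2.0)]
        beta = fit_bias_correction(actual, preds)
        ens = beta[0] + np.column_stack(preds) @ beta[1:]
        mse_ens = np.mean((actual - ens) ** 2)
        for p in preds:
            b = np.polyfit(p, actual, 1)  # best affine use of one schema
            mse_single = np.mean((actual - (b[0] * p + b[1])) ** 2)
            assert mse_ens <= mse_single + 1e-9

    def test_too_small_calibration(self):
        with pytest.raises(DomainError):
            fit_bias_correction([1, 2, 3], [[1, 2, 3]] * 3)


def _toy_model(beta, scale=1.0):
    # predictors with a single feature 'x0'; schema k predicts k * x0
    preds = {}
    for k, schema in enumerate(["unweighted", "inverse_p", "one_minus_p"]):
        preds[schema] = LinearPredictor(
            feature_names=["x0"], center=np.zeros(1), scale=np.ones(1),
            coef=np.array([float(k)]), intercept=float(k), alpha=0.1,
        )
    return EnsembleModel(predictors=preds, beta=np.asarray(beta, float),
                         sigmoid_scale=scale)


class TestPredictEnsemble:
    def test_beta_selects_single_schema(self):
        model = _toy_model([0, 1, 0, 0])
        feats = make_feature_table(np.array([[1.0], [2.0]]))
        out = predict_ensemble(feats, model)
        # unweighted schema predicts 0 * x0 + 0
        assert np.allclose(out, [0.0, 0.0])

    def test_constant_beta(self):
        model = _toy_model([2, 0, 0, 0])
        feats = make_feature_table(np.array([[5.0]]))
        assert predict_ensemble(feats, model) == pytest.approx([2.0])

    def test_hand_arithmetic(self):
        model = _toy_model([1.0, 0.5, 2.0, -1.0])
        feats = make_feature_table(np.array([[3.0]]))
        # yhat = (0, 1*3+1, 2*3+2) = (0, 4, 8)
        expected = 1.0 + 0.5 * 0.0 + 2.0 * 4.0 - 1.0 * 8.0
        assert predict_ensemble(feats, model) == pytest.approx([expected])

    def test_missing_column_schema_error(self):
        model = _toy_model([0, 1, 0, 0])
        feats = make_feature_table(np.array([[1.0]]))
        feats = feats.rename(columns={"x0": "other"})
        with pytest.raises(SchemaError, match="x0"):
            predict_ensemble(feats, model)


class TestScoreToProbability:
    def test_center(self):
        assert score_to_probability(BURNOUT_THRESHOLD, 1.3) == pytest.approx(0.5)

    def test_limit(self):
        assert score_to_probability(1e6, 1.0) == pytest.approx(1.0)

    def test_closed_form_quartile(self):
        s = 0.7
        assert score_to_probability(BURNOUT_THRESHOLD + s * np.log(3), s) == (
            pytest.approx(0.75)
        )

    def test_strictly_increasing(self):
        s = np.linspace(-5, 15, 200)
        p = score_to_probability(s, 1.1)
        assert (np.diff(p) > 0).all()

    def test_invalid_scale(self):
        with pytest.raises(DomainError):
            score_to_probability(5.0, 0.0)
        with pytest.raises(DomainError):
            _toy_model([0, 1, 0, 0], scale=-1.0)

    def test_auroc_invariant_under_conversion(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        scores = rng.normal(loc=3, size=60)
        assert auroc(y, scores) == pytest.approx(
            auroc(y, score_to_probability(scores, 0.9)), rel=1e-12
        )


class TestEvaluate:
    def test_perfect(self):
        y = np.tile([0, 1], 10)
        p = y.astype(float)
        rep = evaluate(p, y, n_boot=30, seed=0)
        assert rep.auroc == 1.0 and rep.auprc == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_constant_predictions(self):
        y = np.array([0, 1, 0, 1, 1, 0, 0, 0])
        rep = evaluate(np.full(8, 0.4), y, n_boot=20, seed=0)
        assert rep.auroc == pytest.approx(0.5)
        assert rep.auprc == pytest.approx(y.mean())

    def test_eight_point_pair_counting_oracle(self):
        y = np.array([1, 0, 1, 1, 0, 0, 1, 0])
        p = np.array([0.9, 0.8, 0.8, 0.6, 0.5, 0.3, 0.3, 0.1])
        pos, neg = p[y == 1], p[y == 0]
        oracle = sum((a > b) + 0.5 * (a == b) for a in pos for b in neg) / 16
        rep = evaluate(p, y, n_boot=20, seed=0)
        assert rep.auroc == pytest.approx(oracle, rel=1e-12)

    def test_cis_contain_point(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, size=100)
        y[:2] = [0, 1]
        p = np.clip(y * 0.4 + rng.uniform(size=100) * 0.6, 0, 1)
        rep = evaluate(p, y, n_boot=100, seed=1)
        assert rep.auroc_ci[0] <= rep.auroc <= rep.auroc_ci[1]
        assert rep.auprc_ci[0] <= rep.auprc <= rep.auprc_ci[1]

    def test_one_class_errors(self):
        with pytest.raises(DegenerateOutcomeError):
            evaluate([0.1, 0.9], [1, 1], n_boot=10, seed=0)


class TestModelSerialization:
    def test_json_roundtrip(self, tmp_path):
        model = _toy_model([0.5, 1.0, -0.2, 0.1], scale=0.8)
        model.operating_threshold = 0.44
        path = tmp_path / "model.json"
        model.to_json(path)
        back = EnsembleModel.from_json(path)
        assert np.allclose(back.beta, model.beta)
        assert back.sigmoid_scale == pytest.approx(0.8)
        assert back.operating_threshold == pytest.approx(0.44)
        feats = make_feature_table(np.array([[2.0]]))
        assert predict_ensemble(feats, back) == pytest.approx(
            predict_ensemble(feats, model)
        )

    def test_bad_beta_shape(self):
        with pytest.raises(ValidationError):
            EnsembleModel(predictors={}, beta=np.zeros(3), sigmoid_scale=1.0)
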