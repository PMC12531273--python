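"""Penalized logistic classifier: feature prep, elastic-net fit, nested CV,
Platt calibration, Brier, thresholds, calibration diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from cohortcapture.model import (
    ModelConfig,
    ZeroVarianceWarning,
    brier,
    calibration_report,
    fit_elastic_net,
    nested_cv,
    platt_calibrate,
    prepare_features,
    select_threshold,
    threshold_sweep,
)

FAST = ModelConfig(
    lambda_grid=(1e-4, 1e-3, 1e-2, 1e-1),
    inner_folds=3,
    outer_folds=3,
    outer_repeats=1,
    tol=1e-5,
    max_iter=3000,
    seed=0,
)


def _logistic_data(rng, n, coefs, intercept=-1.0):
    X = pd.DataFrame(
        rng.integers(0, 2, size=(n, len(coefs))).astype(float),
        columns=[f"db{i}" for i in range(len(coefs))],
    )
    p = expit(X.to_numpy() @ np.asarray(coefs) + intercept)
    y = (rng.random(n) < p).astype(int)
    return X, y


def test_prepare_features_excludes_demographics_by_pattern():
    membership = pd.DataFrame({"icd10": [1, 0], "letters": [0, 1]},
                              index=pd.Index(["a", "b"], name="patient_id"))
    demo = pd.DataFrame(
        {"patient_id": ["a", "b"], "age": [30, 40], "sex": ["f", "m"],
         "ethnicity": ["white", "asian"], "imd_decile": [3, 7],
         "referral_year": [2010, 2012]}
    )
    feats = prepare_features(membership, demo)
    assert list(feats.columns) == ["icd10", "letters"]


def test_prepare_features_constant_column_warns():
    membership = pd.DataFrame({"flat": [1, 1, 1], "var": [0, 1, 0]})
    with pytest.warns(ZeroVarianceWarning):
        feats = prepare_features(membership)
    assert "flat" in feats.columns  # retained, not dropped


def test_elastic_net_full_shrinkage_limit(rng):
    """At very large lambda all coefficients vanish and the intercept
    approaches the logit of the base rate."""
    X, y = _logistic_data(rng, 800, [1.0, -0.5, 0.8])
    model = fit_elastic_net(X, y, lam=1e4, config=FAST)
    assert np.abs(model.coefficients).max() < 1e-3
    base_logit = np.log(y.mean() / (1 - y.mean()))
    assert model.intercept == pytest.approx(base_logit, abs=0.05)
    assert np.allclose(model.odds_ratios(), 1.0, atol=2e-3)


def test_elastic_net_lambda_zero_matches_unpenalized(rng):
    """At tiny lambda the fit matches a direct unpenalized solve."""
    X, y = _logistic_data(rng, 400, [1.2, -0.7])
    model = fit_elastic_net(X, y, lam=1e-10, config=FAST)
    Z = model.scaler.transform(X.to_numpy())
    ref = LogisticRegression(C=np.inf, max_iter=10000, tol=1e-10).fit(Z, y)
    assert np.allclose(model.coefficients, ref.coef_.ravel(), atol=0.02)
    assert model.intercept == pytest.approx(float(ref.intercept_[0]), abs=0.02)


def test_elastic_net_single_class_rejected(rng):
    X, _ = _logistic_data(rng, 50, [1.0])
    with pytest.raises(ValueError, match="single class"):
        fit_elastic_net(X, np.ones(50, dtype=int), lam=0.01, config=FAST)


def test_elastic_net_deterministic(rng):
    X, y = _logistic_data(rng, 300, [0.8, -0.4])
    a = fit_elastic_net(X, y, lam=0.01, config=FAST)
    b = fit_elastic_net(X, y, lam=0.01, config=FAST)
    assert np.array_equal(a.coefficients, b.coefficients)


def test_odds_ratio_identity(rng):
    """Every reported odds ratio equals exp(coefficient), including 1 for
    zeroed features."""
    X, y = _logistic_data(rng, 500, [1.0, 0.0, -0.5])
    model = fit_elastic_net(X, y, lam=0.05, config=FAST)
    frame = model.coefficients_frame()
    assert np.allclose(frame["odds_ratio"], np.exp(frame["coefficient"]))


def test_nested_cv_separable_data_perfect_auc(rng):
    X, _ = _logistic_data(rng, 300, [0.0])
    y = (X["db0"] > 0.5).astype(int).to_numpy()
    res = nested_cv(X, y, FAST)
    assert res.outer_aucs.min() == 1.0


def test_nested_cv_one_se_lambda_at_least_best(rng):
    """The 1-SE rule never selects less regularization than the best-AUC
    lambda."""
    X, y = _logistic_data(rng, 400, [0.9, -0.6, 0.3])
    res = nested_cv(X, y, FAST)
    assert res.lambda_selected >= res.lambda_best


def test_nested_cv_null_labels_auc_near_half(rng):
    """Labels independent of features give chance-level outer AUROC —
    the no-leakage check."""
    X = pd.DataFrame(rng.integers(0, 2, size=(2000, 5)).astype(float),
                     columns=[f"db{i}" for i in range(5)])
    y = rng.integers(0, 2, size=2000)
    res = nested_cv(X, y, FAST)
    assert abs(res.auc_mean - 0.5) < 0.05


def test_platt_identity_on_calibrated_scores(rng):
    p = rng.uniform(0.02, 0.98, size=4000)
    y = (rng.random(4000) < p).astype(int)
    cal = platt_calibrate(p, y)
    assert cal.a == pytest.approx(1.0, abs=0.1)
    assert cal.b == pytest.approx(0.0, abs=0.1)
    assert np.allclose(cal(p), p, atol=0.03)


def test_platt_single_class_identity_with_warning():
    with pytest.warns(UserWarning, match="single-class"):
        cal = platt_calibrate([0.2, 0.7], [1, 1])
    assert cal.identity and np.allclose(cal([0.3, 0.9]), [0.3, 0.9])


def test_platt_improves_brier_on_distorted_scores(rng):
    """Sigmoid-distorted probabilities recalibrate to a Brier score no
    worse than before."""
    p_true = rng.uniform(0.05, 0.95, size=5000)
    y = (rng.random(5000) < p_true).astype(int)
    distorted = expit(2.5 * np.log(p_true / (1 - p_true)) + 0.8)
    cal = platt_calibrate(distorted, y)
    assert brier(cal(distorted), y) <= brier(distorted, y)


def test_brier_closed_form():
    assert brier([0.5, 0.5], [0, 1]) == pytest.approx(0.25)
    assert brier([1.0, 0.0], [1, 0]) == 0.0


def test_threshold_sweep_counts_and_identity(rng):
    p = rng.uniform(0, 1, size=300)
    y = (rng.random(300) < p).astype(int)
    pop = rng.uniform(0, 1, size=2000)
    sweep = threshold_sweep(p, y, pop, thresholds=[0.25, 0.5, 0.75],
                            n_boot=50, seed=0)
    # population counts shrink as the threshold rises
    assert (np.diff(sweep["predicted_total"]) <= 0).all()
    for _, row in sweep.iterrows():
        assert row["actual_predicted_total"] <= row["predicted_total"]
        expected = round(row["predicted_total"] * row["precision"])
        assert row["actual_predicted_total"] == pytest.approx(expected, abs=1)


def test_threshold_sweep_validation():
    with pytest.raises(ValueError, match="non-empty"):
        threshold_sweep([0.5], [1], [0.5], thresholds=[])
    with pytest.raises(ValueError, match="strictly"):
        threshold_sweep([0.5], [1], [0.5], thresholds=[1.0])


def test_select_threshold_rules():
    scores = np.array([0.1, 0.1, 0.9, 0.9])
    labels = np.array([0, 0, 1, 1])
    t = select_threshold(scores, labels, "max_f1")
    assert 0.1 < t <= 0.9
    assert select_threshold(scores, labels, "youden") == t
    assert select_threshold(scores, labels, "fixed", fixed_value=0.496) == 0.496
    with pytest.raises(ValueError):
        select_threshold(scores, np.ones_like(labels), "max_f1")
    with pytest.raises(ValueError):
        select_threshold(scores, labels, "unknown")


def test_calibration_report_well_calibrated(rng):
    p = rng.uniform(0.01, 0.99, size=10000)
    y = (rng.random(10000) < p).astype(int)
    rep = calibration_report(p, y, n_bins=10)
    assert len(rep.binned) == 10
    assert rep.binned["count"].sum() == 10000
    assert rep.slope == pytest.approx(1.0, abs=0.07)
    assert rep.intercept == pytest.approx(0.0, abs=0.07)
    # binned curve hugs the diagonal
    assert (np.abs(rep.binned["mean_predicted"] - rep.binned["observed"]) < 0.06).all()


def test_calibration_report_shifted_scores_overpredict(rng):
    """Probabilities shifted upward show observed < predicted in every
    populated bin."""
    p_true = rng.uniform(0.05, 0.7, size=8000)
    y = (rng.random(8000) < p_true).astype(int)
    shifted = np.clip(p_true + 0.2, 0, 0.999)
    rep = calibration_report(shifted, y, n_bins=8)
    populated = rep.binned[rep.binned["count"] > 50]
    assert (populated["observed"] < populated["mean_predicted"]).all()


def test_calibration_report_empty_bins_dropped(rng):
    p = rng.uniform(0.4, 0.6, size=500)
    y = (rng.random(500) < p).astype(int)
    rep = calibration_report(p, y, n_bins=10)
    assert len(rep.dropped_bins) > 0
    assert len(rep.binned) + len(rep.dropped_bins) == 10
    with pytest.raises(ValueError):
        calibration_report(p, y, n_bins=1)
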