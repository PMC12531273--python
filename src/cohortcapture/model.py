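"""Elastic-net logistic cohort classifier with nested CV and calibration.

Fits a 50:50 elastic-net penalized logistic regression over the binary
database flags (demographic columns are excluded by name pattern), selects
the regularization strength λ by the one-standard-error rule on inner-fold
AUROC, reports the outer-fold AUROC distribution from repeated nested
cross-validation, recalibrates scores by Platt scaling fitted on held-out
predictions only, and supports Brier scoring, threshold sweeps with
bootstrap intervals, and three-way calibration diagnostics (binned curve,
LOWESS curve, logistic recalibration slope/intercept).

λ follows the glmnet convention — the penalized objective is
(1/n)·Σ logloss + λ·[α‖β‖₁ + (1−α)/2·‖β‖²] — mapped onto scikit-learn's
``C`` as C = 1/(n·λ).  Features are z-scored with statistics learned on
training folds only; all selection happens inside folds to avoid leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._rounding import round_half_away
from .metrics import confusion, metrics

__all__ = [
    "ModelConfig",
    "FittedModel",
    "NestedCVResult",
    "PlattCalibrator",
    "CalibrationReport",
    "ModelReport",
    "prepare_features",
    "fit_elastic_net",
    "nested_cv",
    "platt_calibrate",
    "brier",
    "threshold_sweep",
    "select_threshold",
    "calibration_report",
    "build_model_report",
]

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-5, 0, 8))


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the penalized classifier.

    ``outer_repeats`` defaults to a desk-scale 5 (the estimator is
    identical at 100 repeats, only the outer AUROC distribution is
    smoother).  ``demographic_exclusion_patterns`` are case-insensitive
    substrings matched against feature-column names.
    """

    l1_mix: float = 0.5
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    inner_folds: int = 10
    outer_folds: int = 10
    outer_repeats: int = 5
    seed: int = 0
    tol: float = 1e-6
    max_iter: int = 10000
    demographic_exclusion_patterns: tuple[str, ...] = (
        "age",
        "sex",
        "ethnic",
        "imd",
        "referral_year",
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.l1_mix <= 1.0:
            raise ValueError("l1_mix must lie in [0, 1]")
        if self.inner_folds < 2 or self.outer_folds < 2:
            raise ValueError("folds must be >= 2")
        if any(l <= 0 for l in self.lambda_grid):
            raise ValueError("lambda grid must be strictly positive")


class ZeroVarianceWarning(UserWarning):
    """A feature column is constant; it is retained with zero weight."""


def prepare_features(
    membership: pd.DataFrame,
    demographics: pd.DataFrame | None = None,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Assemble the feature table, excluding demographic columns by pattern.

    Returns unscaled features; z-scoring happens inside fold fitting so
    scaling statistics never leak from validation folds.  Constant columns
    are retained (the penalty zeroes them) with a warning.
    """
    config = config or ModelConfig()
    table = membership.copy()
    if demographics is not None:
        demo = demographics.set_index("patient_id") if "patient_id" in demographics.columns else demographics
        table = table.join(demo, how="left")
    patterns = tuple(p.lower() for p in config.demographic_exclusion_patterns)
    keep = [c for c in table.columns if not any(p in c.lower() for p in patterns)]
    out = table[keep]
    non_numeric = out.select_dtypes(exclude="number").columns
    if len(non_numeric):
        out = out.drop(columns=list(non_numeric))
    constant = [c for c in out.columns if out[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"zero-variance feature columns retained: {constant}",
            ZeroVarianceWarning,
            stacklevel=2,
        )
    return out


class _SafeScaler(StandardScaler):
    """StandardScaler that leaves constant columns at 0 instead of dividing by ~0."""

    def fit(self, X, y=None, **kw):
        super().fit(X, y, **kw)
        self.scale_ = np.where(self.scale_ == 0, 1.0, self.scale_)
        return self


@dataclass
class FittedModel:
    """A fitted penalized logistic model on standardized features."""

    feature_names: list[str]
    coefficients: np.ndarray  # on the standardized scale
    intercept: float
    lam: float
    scaler: _SafeScaler = field(repr=False, default=None)

    def predict_proba(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        Z = self.scaler.transform(X)
        return expit(Z @ self.coefficients + self.intercept)

    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    def coefficients_frame(self) -> pd.DataFrame:
        """Ranked coefficient / odds-ratio table (intercept first)."""
        rows = [{"feature": "Intercept", "coefficient": self.intercept,
                 "odds_ratio": float(np.exp(self.intercept))}]
        order = np.argsort(-self.coefficients)
        for i in order:
            rows.append(
                {
                    "feature": self.feature_names[i],
                    "coefficient": float(self.coefficients[i]),
                    "odds_ratio": float(np.exp(self.coefficients[i])),
                }
            )
        return pd.DataFrame(rows)


def fit_elastic_net(
    features: pd.DataFrame | np.ndarray,
    labels,
    lam: float,
    config: ModelConfig | None = None,
) -> FittedModel:
    """Fit the elastic-net logistic regression at one λ (SAGA solver).

    Deterministic given the config seed and tolerance.  Raises on
    single-class labels.
    """
    config = config or ModelConfig()
    names = (
        list(features.columns)
        if isinstance(features, pd.DataFrame)
        else [f"x{i}" for i in range(np.asarray(features).shape[1])]
    )
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; cannot fit")
    scaler = _SafeScaler().fit(X)
    Z = scaler.transform(X)
    C = 1.0 / (lam * len(y))
    clf = LogisticRegression(
        l1_ratio=config.l1_mix,
        C=C,
        solver="saga",
        tol=config.tol,
        max_iter=config.max_iter,
        random_state=config.seed,
    ).fit(Z, y)
    coef = clf.coef_.ravel().copy()
    # The intercept is unpenalized, so given the coefficients its optimum
    # solves mean(sigmoid(Zβ + b)) = mean(y) — a monotone 1-D root.  SAGA
    # under-optimizes the intercept at extreme λ (it can declare
    # convergence with zero coefficient movement), so profile it out.
    eta = Z @ coef
    ybar = y.mean()

    def grad(b: float) -> float:
        return float(expit(eta + b).mean() - ybar)

    intercept = brentq(grad, -40.0, 40.0, xtol=1e-12)
    return FittedModel(
        feature_names=names,
        coefficients=coef,
        intercept=float(intercept),
        lam=lam,
        scaler=scaler,
    )


def _inner_select_lambda(
    X: np.ndarray, y: np.ndarray, config: ModelConfig, seed: int
) -> tuple[float, float]:
    """One-SE λ selection by inner-fold AUROC.

    Returns (λ_1se, λ_best): the most regularized λ whose mean inner AUROC
    is within one standard error of the best, and the best-AUROC λ itself.
    """
    grid = sorted(config.lambda_grid)
    skf = StratifiedKFold(config.inner_folds, shuffle=True, random_state=seed)
    aucs = np.zeros((len(grid), config.inner_folds))
    for f, (tr, va) in enumerate(skf.split(X, y)):
        if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
            warnings.warn("inner fold with a single class; scored as 0.5", stacklevel=2)
            aucs[:, f] = 0.5
            continue
        for g, lam in enumerate(grid):
            model = fit_elastic_net(X[tr], y[tr], lam, config)
            aucs[g, f] = roc_auc_score(y[va], model.predict_proba(X[va]))
    mean = aucs.mean(axis=1)
    se = aucs.std(axis=1, ddof=1) / np.sqrt(config.inner_folds)
    best = int(np.argmax(mean))
    threshold = mean[best] - se[best]
    eligible = [g for g in range(len(grid)) if mean[g] >= threshold]
    lam_1se = max(grid[g] for g in eligible)  # most regularization allowed
    return lam_1se, grid[best]


@dataclass
class NestedCVResult:
    lambda_selected: float
    lambda_best: float
    outer_aucs: np.ndarray
    oof_scores: pd.Series = field(repr=False, default=None)  # first repeat
    oof_labels: pd.Series = field(repr=False, default=None)

    @property
    def auc_mean(self) -> float:
        return float(self.outer_aucs.mean())

    @property
    def auc_sd(self) -> float:
        return float(self.outer_aucs.std(ddof=1)) if len(self.outer_aucs) > 1 else 0.0


def nested_cv(
    features: pd.DataFrame | np.ndarray, labels, config: ModelConfig | None = None
) -> NestedCVResult:
    """Repeated nested cross-validation.

    The inner loop selects λ by the one-SE rule on AUROC; the outer loop
    refits at the selected λ and scores the held-out fold, yielding an
    AUROC distribution over ``outer_folds × outer_repeats`` splits.
    Out-of-fold scores from the first repeat are kept for downstream
    Platt calibration, which must never see training-fold predictions.
    The reported ``lambda_selected`` comes from a final inner selection
    on the full data.
    """
    config = config or ModelConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    rskf = RepeatedStratifiedKFold(
        n_splits=config.outer_folds,
        n_repeats=config.outer_repeats,
        random_state=config.seed,
    )
    outer_aucs = []
    oof = np.full(len(y), np.nan)
    for k, (tr, te) in enumerate(rskf.split(X, y)):
        lam, _ = _inner_select_lambda(X[tr], y[tr], config, seed=config.seed + k + 1)
        model = fit_elastic_net(X[tr], y[tr], lam, config)
        scores = model.predict_proba(X[te])
        if len(np.unique(y[te])) >= 2:
            outer_aucs.append(roc_auc_score(y[te], scores))
        if k < config.outer_folds:  # first repeat covers each patient once
            oof[te] = scores
    lam_1se, lam_best = _inner_select_lambda(X, y, config, seed=config.seed)
    index = (
        features.index if isinstance(features, pd.DataFrame) else pd.RangeIndex(len(y))
    )
    return NestedCVResult(
        lambda_selected=lam_1se,
        lambda_best=lam_best,
        outer_aucs=np.asarray(outer_aucs),
        oof_scores=pd.Series(oof, index=index),
        oof_labels=pd.Series(y, index=index),
    )


@dataclass
class PlattCalibrator:
    """Two-parameter logistic map on the logit of the raw score.

    calibrated = σ(a·logit(p) + b); the identity map is (a, b) = (1, 0).
    """

    a: float
    b: float
    identity: bool = False

    def __call__(self, p) -> np.ndarray:
        p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
        if self.identity:
            return p
        return expit(self.a * logit(p) + self.b)


def platt_calibrate(raw_scores, labels) -> PlattCalibrator:
    """Fit Platt scaling on held-out (score, label) pairs.

    A single-class calibration set yields the identity map with a warning.
    """
    y = np.asarray(labels, dtype=int)
    p = np.clip(np.asarray(raw_scores, dtype=float), 1e-12, 1 - 1e-12)
    if not np.isfinite(p).all():
        raise ValueError("raw scores must be finite")
    if len(np.unique(y)) < 2:
        warnings.warn(
            "single-class calibration set; returning the identity map", stacklevel=2
        )
        return PlattCalibrator(a=1.0, b=0.0, identity=True)
    z = logit(p).reshape(-1, 1)
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=10000).fit(z, y)
    return PlattCalibrator(a=float(clf.coef_[0, 0]), b=float(clf.intercept_[0]))


def brier(probabilities, labels) -> float:
    """Mean squared error between predicted probabilities and outcomes."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    return float(np.mean((p - y) ** 2))


def threshold_sweep(
    probabilities,
    labels,
    population_probabilities,
    thresholds,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-threshold validation metrics and projected population totals.

    At each threshold: precision/recall/accuracy on the labeled validation
    set with percentile-bootstrap 95% CIs; ``predicted_total`` counts
    population probabilities at or above the threshold; and the projected
    true-positive total ``actual_predicted_total`` is
    round(predicted_total × precision).  Bootstrap resamples the labeled
    set only; population totals are rescaled per resample by the ratio of
    resampled to observed flag rate, so the paired CIs share the same
    resamples.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("threshold list must be non-empty")
    if any(not 0.0 < t < 1.0 for t in thresholds):
        raise ValueError("thresholds must lie strictly in (0, 1)")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    pop = np.asarray(population_probabilities, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y)
    boot_idx = rng.integers(0, n, size=(n_boot, n))
    rows = []
    for t in thresholds:
        pred = (p >= t).astype(int)
        ms = metrics(confusion(pred, y), warn=False)
        predicted_total = int(np.count_nonzero(pop >= t))
        actual_total = round_half_away(predicted_total * ms.precision)
        flag_rate = max(pred.mean(), 1e-12)
        stats_b = {k: [] for k in ("precision", "recall", "accuracy", "pt", "apt")}
        for b in range(n_boot):
            idx = boot_idx[b]
            msb = metrics(confusion(pred[idx], y[idx]), warn=False)
            ratio = pred[idx].mean() / flag_rate
            ptb = round_half_away(predicted_total * ratio)
            stats_b["precision"].append(msb.precision)
            stats_b["recall"].append(msb.recall)
            stats_b["accuracy"].append(msb.accuracy)
            stats_b["pt"].append(ptb)
            stats_b["apt"].append(round_half_away(ptb * msb.precision))
        def ci(v):
            return float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5))
        row = {"threshold": t,
               "precision": ms.precision, "recall": ms.recall, "accuracy": ms.accuracy,
               "predicted_total": predicted_total,
               "actual_predicted_total": actual_total}
        for key, out_key in (("precision", "precision"), ("recall", "recall"),
                             ("accuracy", "accuracy"), ("pt", "predicted_total"),
                             ("apt", "actual_predicted_total")):
            lo, hi = ci(stats_b[key])
            row[f"{out_key}_lo"], row[f"{out_key}_hi"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows)


def select_threshold(
    probabilities,
    labels,
    criterion: str = "max_f1",
    fixed_value: float | None = None,
    candidates=None,
) -> float:
    """Deterministic threshold choice: ``max_f1``, ``youden`` or ``fixed``.

    Candidates default to the sorted unique scores; ties resolve to the
    lowest threshold.
    """
    if criterion == "fixed":
        if fixed_value is None:
            raise ValueError("criterion='fixed' requires fixed_value")
        return float(fixed_value)
    if criterion not in ("max_f1", "youden"):
        raise ValueError(f"unknown criterion {criterion!r}")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("threshold selection needs both classes present")
    cand = np.sort(np.unique(p)) if candidates is None else np.sort(np.asarray(candidates))
    if criterion == "youden":
        fpr, tpr, thr = roc_curve(y, p)
        j = tpr - fpr
        best = j.max()
        # roc_curve thresholds descend; take the lowest threshold achieving max J
        return float(min(t for t, v in zip(thr, j) if v >= best - 1e-12 and t <= 1))
    best_f1, best_t = -1.0, cand[0]
    for t in cand:
        ms = metrics(confusion((p >= t).astype(int), y), warn=False)
        if ms.f1 > best_f1 + 1e-12:
            best_f1, best_t = ms.f1, t
    return float(best_t)


@dataclass
class CalibrationReport:
    """Three calibration views: binned curve, LOWESS curve, recalibration fit."""

    binned: pd.DataFrame  # bin, mean_predicted, observed, count
    lowess_curve: np.ndarray  # (m, 2) array of (predicted, smoothed observed)
    slope: float
    intercept: float
    dropped_bins: tuple[int, ...] = ()


def calibration_report(probabilities, labels, n_bins: int = 10) -> CalibrationReport:
    """Binned, LOWESS-smoothed and logistic-recalibration calibration checks.

    The recalibration logistic regresses outcomes on the logit of the
    predicted probabilities; a well-calibrated model has slope ≈ 1 and
    intercept ≈ 0.  Empty bins are dropped and noted.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    p = np.clip(np.asarray(probabilities, dtype=float), 1e-12, 1 - 1e-12)
    y = np.asarray(labels, dtype=int)
    edges = np.linspace(0, 1, n_bins + 1)
    which = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    rows, dropped = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            dropped.append(b)
            continue
        rows.append(
            {
                "bin": b,
                "mean_predicted": float(p[mask].mean()),
                "observed": float(y[mask].mean()),
                "count": int(mask.sum()),
            }
        )
    smoothed = lowess(y, p, frac=0.5, return_sorted=True)
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=10000).fit(
        logit(p).reshape(-1, 1), y
    )
    return CalibrationReport(
        binned=pd.DataFrame(rows),
        lowess_curve=smoothed,
        slope=float(clf.coef_[0, 0]),
        intercept=float(clf.intercept_[0]),
        dropped_bins=tuple(dropped),
    )


@dataclass
class ModelReport:
    """Everything the pipeline reports about the fitted classifier."""

    model: FittedModel
    cv: NestedCVResult
    auroc_validation: float
    brier_before: float
    brier_after: float
    calibrator: PlattCalibrator
    calibration: CalibrationReport
    threshold: float
    sweep: pd.DataFrame

    def summary(self) -> dict:
        return {
            "lambda_selected": self.model.lam,
            "auroc_outer_mean": self.cv.auc_mean,
            "auroc_outer_sd": self.cv.auc_sd,
            "auroc_validation": self.auroc_validation,
            "brier_before_platt": self.brier_before,
            "brier_after_platt": self.brier_after,
            "platt_a": self.calibrator.a,
            "platt_b": self.calibrator.b,
            "calibration_slope": self.calibration.slope,
            "calibration_intercept": self.calibration.intercept,
            "threshold": self.threshold,
        }


def build_model_report(
    membership: pd.DataFrame,
    gold: pd.DataFrame,
    demographics: pd.DataFrame | None = None,
    config: ModelConfig | None = None,
    thresholds=(0.25, 0.31, 0.38, 0.44, 0.5, 0.56, 0.62, 0.69, 0.75),
    threshold_criterion: str = "max_f1",
    n_boot: int = 1000,
) -> ModelReport:
    """End-to-end model fit and evaluation on a gold-standard table.

    Trains on the gold standard's training split at the nested-CV-selected
    λ, Platt-calibrates on out-of-fold training scores, and evaluates
    AUROC, Brier, calibration and the threshold sweep on the validation
    split, projecting totals onto the full population.
    """
    config = config or ModelConfig()
    gold_idx = gold.set_index("patient_id")
    features_all = prepare_features(membership, demographics, config)
    train_ids = gold_idx.index[gold_idx["split"] == "training"]
    val_ids = gold_idx.index[gold_idx["split"] == "validation"]
    X_train = features_all.reindex(train_ids).fillna(0)
    y_train = gold_idx.loc[train_ids, "label"].astype(int)
    X_val = features_all.reindex(val_ids).fillna(0)
    y_val = gold_idx.loc[val_ids, "label"].astype(int).to_numpy()

    cv = nested_cv(X_train, y_train, config)
    model = fit_elastic_net(X_train, y_train, cv.lambda_selected, config)
    # Platt scaling fitted on out-of-fold training scores only
    mask = cv.oof_scores.notna()
    calibrator = platt_calibrate(cv.oof_scores[mask], cv.oof_labels[mask])

    raw_val = model.predict_proba(X_val)
    cal_val = calibrator(raw_val)
    pop_probs = calibrator(model.predict_proba(features_all))
    auroc = float(roc_auc_score(y_val, cal_val))
    report = ModelReport(
        model=model,
        cv=cv,
        auroc_validation=auroc,
        brier_before=brier(raw_val, y_val),
        brier_after=brier(cal_val, y_val),
        calibrator=calibrator,
        calibration=calibration_report(cal_val, y_val),
        threshold=select_threshold(cal_val, y_val, criterion=threshold_criterion),
        sweep=threshold_sweep(
            cal_val, y_val, pop_probs, thresholds, n_boot=n_boot, seed=config.seed
        ),
    )
    return report
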