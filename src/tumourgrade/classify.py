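"""Low- vs high-grade tumour classification from ADC and CBF biomarkers.

Three classifiers mirror clinical practice:

* **Single-parameter ROC thresholds** — the empirical ROC over observed
  values, AUC by the Mann–Whitney rank statistic (tie-corrected), and the
  optimal cut maximising Youden's J (sensitivity + specificity - 1), placed
  midway between adjacent observed values.
* **Fixed-threshold flowchart** — the published decision rules: ADC_ROI-mean
  >= 0.95e-3 mm²/s or ADC_ROI-min >= 0.82e-3 mm²/s -> low grade (WHO I-II),
  below -> high grade (III-IV); nCBF_ROI-max <= 1.45 -> low grade, above ->
  high grade.  Equality keeps the low-grade (less aggressive) call.
* **Two-predictor logistic model** — grade ~ ADC + nCBF, fitted by
  maximum-likelihood IRLS; complete or quasi-complete separation (which a
  cleanly separable cohort produces) triggers a Jeffreys-prior (Firth)
  penalised refit so the coefficients and the p=0.5 decision boundary stay
  finite.

Diffuse midline glioma — a high-grade subtype whose ADC/CBF values resemble
low-grade tumours — is excluded from fitting and ROC analysis by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger(__name__)

#: Published decision thresholds (ADC in mm²/s; nCBF dimensionless).
FLOWCHART_THRESHOLDS = {
    "adc_roi_mean": 0.95e-3,
    "adc_roi_min": 0.82e-3,
    "ncbf_roi_max": 1.45,
}

#: Parameters for which a LOW value indicates high grade.
LOW_IS_HIGH_GRADE = ("adc_roi_mean", "adc_roi_min")

DEFAULT_EXCLUDED_SUBTYPES = ("diffuse_midline_glioma",)

#: ADC predictors are rescaled to 1e-3 mm²/s units inside the fit for
#: conditioning; coefficients are reported back on the input scale.
_ADC_SCALE = 1e-3


class SingleClassError(ValueError):
    """ROC analysis needs observations from both grade classes."""


class SampleSizeError(ValueError):
    """Too few records per class to fit the logistic model."""


@dataclass(frozen=True)
class RocResult:
    auc: float
    threshold: float
    direction: str
    sensitivity: float
    specificity: float
    accuracy: float


@dataclass
class LogisticGradeModel:
    """Fitted two-predictor logistic grade classifier.

    ``coefficients`` maps predictor name -> coefficient on the input scale;
    the decision boundary is the locus beta0 + sum(beta_j x_j) = 0 where
    the predicted probability of high grade is exactly 0.5.
    """

    intercept: float
    coefficients: dict[str, float]
    fit_method: str  # 'ml' or 'penalised'
    training_accuracy: float
    converged: bool = True
    n_low: int = 0
    n_high: int = 0

    @property
    def penalised(self) -> bool:
        return self.fit_method == "penalised"

    def linear_predictor(self, X: pd.DataFrame | dict) -> np.ndarray:
        eta = np.full(len(next(iter(X.values()))) if isinstance(X, dict)
                      else len(X), self.intercept, dtype=float)
        for name, beta in self.coefficients.items():
            eta = eta + beta * np.asarray(X[name], dtype=float)
        return eta

    def predict_proba(self, X) -> np.ndarray:
        return _sigmoid(self.linear_predictor(X))


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta, dtype=float)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


# ---------------------------------------------------------------------------
# ROC analysis

def auc_mann_whitney(values: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the tie-corrected Mann–Whitney probability.

    ``labels`` True marks the positive (high-grade) class; ``values`` are
    oriented so larger means more positive.  Midranks handle ties, so a
    tied pair contributes 1/2.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("both classes must be represented")
    ranks = rankdata(values)
    r_pos = ranks[labels].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_threshold(
    values: Sequence[float],
    labels: Sequence[bool],
    direction: str,
    criterion: str = "youden",
) -> RocResult:
    """Empirical ROC with an optimal threshold.

    ``direction='high_is_high_grade'`` (CBF-like) predicts high grade for
    values strictly above the threshold; ``'low_is_high_grade'`` (ADC-like)
    for values strictly below it.  Candidate thresholds are the midpoints
    between adjacent distinct observed values (plus outer sentinels);
    ``criterion`` is ``'youden'`` (default) or ``'accuracy'``, with the
    other statistic breaking ties, then the first candidate in ascending
    order.
    """
    if direction not in ("high_is_high_grade", "low_is_high_grade"):
        raise ValueError(f"unknown direction {direction!r}")
    if criterion not in ("youden", "accuracy"):
        raise ValueError(f"unknown criterion {criterion!r}")
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.size != y.size:
        raise ValueError("values and labels differ in length")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    score = v if direction == "high_is_high_grade" else -v
    auc = auc_mann_whitney(score, y)

    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    distinct = np.unique(v)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    span = max(distinct[-1] - distinct[0], 1.0)
    cands = np.concatenate([[distinct[0] - 0.5 * span], mids,
                            [distinct[-1] + 0.5 * span]])
    best: tuple[float, float, RocResult] | None = None
    for t in cands:
        pred_high = v > t if direction == "high_is_high_grade" else v < t
        sens = float(np.count_nonzero(pred_high & y) / n_pos)
        spec = float(np.count_nonzero(~pred_high & ~y) / n_neg)
        acc = float(np.count_nonzero(pred_high == y) / y.size)
        youden = sens + spec - 1.0
        key = (youden, acc) if criterion == "youden" else (acc, youden)
        if best is None or key > (best[0], best[1]):
            best = (key[0], key[1],
                    RocResult(auc=auc, threshold=float(t), direction=direction,
                              sensitivity=sens, specificity=spec, accuracy=acc))
    assert best is not None
    return best[2]


# ---------------------------------------------------------------------------
# Fixed-threshold flowchart

def classify_flowchart(
    measurements: dict,
    thresholds: dict | None = None,
    subtype: str | None = None,
) -> dict:
    """Per-parameter grade verdicts at the published thresholds.

    ``measurements`` maps parameter name (``adc_roi_mean``, ``adc_roi_min``,
    ``ncbf_roi_max``) to value; absent or None parameters are skipped.
    Equality at a threshold keeps the low-grade call.  The returned dict
    maps parameter -> ``'low'``/``'high'`` and carries a ``caveat`` entry
    for diffuse midline glioma inputs, whose values mimic low-grade tumours.
    """
    thresholds = {**FLOWCHART_THRESHOLDS, **(thresholds or {})}
    verdicts: dict = {}
    seen = False
    for name, thr in thresholds.items():
        value = measurements.get(name)
        if value is None:
            continue
        seen = True
        if name in LOW_IS_HIGH_GRADE:
            verdicts[name] = "low" if value >= thr else "high"
        else:
            verdicts[name] = "low" if value <= thr else "high"
    if not seen:
        raise ValueError("no recognised parameter present in measurements")
    if subtype in DEFAULT_EXCLUDED_SUBTYPES:
        verdicts["caveat"] = (
            f"{subtype}: thresholds unreliable for this subtype"
        )
    return verdicts


# ---------------------------------------------------------------------------
# Two-predictor logistic model

def _design_matrix(df: pd.DataFrame, predictors: Sequence[str]) -> np.ndarray:
    cols = []
    for name in predictors:
        x = np.asarray(df[name], dtype=float)
        if name.startswith("adc"):
            x = x / _ADC_SCALE
        cols.append(x)
    X = np.column_stack([np.ones(len(df)), *cols])
    if not np.all(np.isfinite(X)):
        raise ValueError("predictors must be finite")
    return X


def _irls_ml(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
             tol: float = 1e-10) -> tuple[np.ndarray, bool]:
    """Plain maximum-likelihood logistic fit from zero coefficients."""
    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(max_iter):
        p = _sigmoid(X @ beta)
        grad = X.T @ (y - p)
        w = np.clip(p * (1 - p), 1e-12, None)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 1e4:
            break
    return beta, converged


def _irls_firth(X: np.ndarray, y: np.ndarray, max_iter: int = 200,
                tol: float = 1e-10) -> tuple[np.ndarray, bool]:
    """Jeffreys-prior penalised logistic fit (Firth's modified score).

    The score is adjusted by the hat-matrix leverages,
    U*_j = sum_i (y_i - p_i + h_i (1/2 - p_i)) x_ij, which keeps the
    estimates finite under complete separation.
    """
    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(max_iter):
        p = _sigmoid(X @ beta)
        w = np.clip(p * (1 - p), 1e-12, None)
        info = (X * w[:, None]).T @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        h = np.einsum("ij,jk,ik->i", X * w[:, None], info_inv, X)
        grad = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ grad
        # step-halving keeps the penalised likelihood ascent stable
        for _ in range(12):
            if np.max(np.abs(step)) <= 5.0:
                break
            step = step / 2.0
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    return beta, converged


def _is_separated(X: np.ndarray, y: np.ndarray, beta: np.ndarray,
                  converged: bool) -> bool:
    p = _sigmoid(X @ beta)
    perfect = np.all((p >= 0.5) == y.astype(bool))
    return (np.max(np.abs(beta)) > 30.0) or (perfect and not converged)


def fit_logistic_grade(
    cohort: pd.DataFrame,
    predictors: Sequence[str] = ("adc_roi_mean", "ncbf_roi_max"),
    grade_column: str = "grade",
) -> LogisticGradeModel:
    """Fit grade ~ predictors by IRLS, falling back to a Firth fit.

    ``cohort`` needs the predictor columns and a ``grade`` column coded
    ``'low'``/``'high'``.  Fewer than 3 records in either class is refused.
    Separation (diverging coefficients, or a perfect training split with a
    non-converged likelihood) triggers the Jeffreys-penalised refit and
    sets ``fit_method='penalised'``.  ADC predictors are standardised to
    1e-3 mm²/s units internally; coefficients are reported on the input
    scale.
    """
    y = (cohort[grade_column].astype(str) == "high").to_numpy(dtype=float)
    n_high = int(y.sum())
    n_low = int(len(y) - n_high)
    if n_low < 3 or n_high < 3:
        raise SampleSizeError(
            f"need >= 3 records per class, got low={n_low}, high={n_high}"
        )
    X = _design_matrix(cohort, predictors)
    beta, converged = _irls_ml(X, y)
    method = "ml"
    if _is_separated(X, y, beta, converged):
        log.info("separation detected; refitting with Jeffreys penalisation")
        beta, converged = _irls_firth(X, y)
        method = "penalised"
    coeffs: dict[str, float] = {}
    for j, name in enumerate(predictors, start=1):
        scale = _ADC_SCALE if name.startswith("adc") else 1.0
        coeffs[name] = float(beta[j] / scale)
    model = LogisticGradeModel(
        intercept=float(beta[0]), coefficients=coeffs, fit_method=method,
        training_accuracy=0.0, converged=converged,
        n_low=n_low, n_high=n_high,
    )
    p = model.predict_proba(cohort[list(predictors)])
    model.training_accuracy = float(np.mean((p >= 0.5) == y.astype(bool)))
    return model


def apply_model(
    model: LogisticGradeModel,
    cohort: pd.DataFrame,
    grade_column: str = "grade",
) -> tuple[pd.DataFrame, dict]:
    """Per-case probabilities and binary calls at p = 0.5.

    Cases missing a predictor are skipped and tallied.  When a grade column
    is present the summary carries accuracy, sensitivity and specificity
    against it.
    """
    predictors = list(model.coefficients)
    missing = [c for c in predictors if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks predictor column(s) {missing}")
    usable = cohort.dropna(subset=predictors)
    n_skipped = len(cohort) - len(usable)
    prob = model.predict_proba(usable[predictors])
    pred = np.where(prob >= 0.5, "high", "low")
    out = usable.copy()
    out["prob_high"] = prob
    out["predicted_grade"] = pred
    summary: dict = {"n_cases": len(usable), "n_skipped": int(n_skipped)}
    if grade_column in usable.columns:
        truth = usable[grade_column].astype(str).to_numpy()
        is_high = truth == "high"
        correct = pred == truth
        summary["accuracy"] = float(np.mean(correct))
        if is_high.any():
            summary["sensitivity"] = float(np.mean(correct[is_high]))
        if (~is_high).any():
            summary["specificity"] = float(np.mean(correct[~is_high]))
    return out, summary


def filter_cohort(
    cohort: pd.DataFrame,
    exclude_subtypes: Sequence[str] = DEFAULT_EXCLUDED_SUBTYPES,
    subtype_column: str = "subtype",
) -> pd.DataFrame:
    """Drop excluded subtypes (diffuse midline glioma by default)."""
    if subtype_column not in cohort.columns or not exclude_subtypes:
        return cohort
    keep = ~cohort[subtype_column].isin(list(exclude_subtypes))
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("excluded %d case(s) of subtype(s) %s", n_dropped,
                 list(exclude_subtypes))
    return cohort[keep].reset_index(drop=True)
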