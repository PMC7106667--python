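"""Young/old classification of mosquitoes from spectra.

A mosquito is "old" when its age is at or beyond the 8-day threshold — the
approximate extrinsic-incubation-period boundary past which a vector can
transmit disease.  Two routes are implemented:

* ``classify_via_regression`` — the traditional route: predict age in days,
  then threshold the prediction.
* ``resampling_classify`` — direct classification: PLS score extraction on
  the centred 0/1 class, a binomial logistic regression on the training
  scores (IRLS), a misclassification-optimal cut-point on the linear
  predictor chosen on the validation partition, all inside the same
  resampling framework used for regression.  Final calls compare each
  sample's test-averaged linear predictor to the average cut-point.

ROC curves and AUC are computed by threshold sweep with trapezoidal area;
the AUC equals the Mann-Whitney pairwise concordance with ties counted 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_selection import SplitPlan, ValidationCurve, ResamplingRegressionResult
from .pls_core import PLSModel, nipals_pls1
from .spectra_io import SampleTable

__all__ = [
    "AgeClassLabel",
    "PLSLogisticModel",
    "ROCResult",
    "ConfusionSummary",
    "ResamplingClassificationResult",
    "binarize_age",
    "fit_pls_logistic",
    "linear_predictor",
    "optimal_threshold",
    "confusion",
    "roc_auc",
    "select_K_auc",
    "resampling_classify",
    "transfer_classify",
    "classify_via_regression",
]

OLD_THRESHOLD_DAYS = 8.0

IRLS_MAX_ITER = 25
IRLS_COEF_CAP = 1e3  # keeps eta usable for ranking under perfect separation


@dataclass(frozen=True)
class AgeClassLabel:
    sample_id: str
    age_days: float
    is_old: bool

    @property
    def label(self) -> str:
        return "old" if self.is_old else "young"


@dataclass
class PLSLogisticModel:
    """PLS score extraction (binary response) + binomial logistic fit.

    The linear predictor is eta(x) = alpha + scores(x) . beta, with scores
    taken from the PLS decomposition of the spectra against the centred
    0/1 class.  ``threshold`` is the cut-point on eta chosen to minimise
    validation misclassification (old is called when eta >= threshold).
    """

    pls: PLSModel
    alpha: float
    beta: np.ndarray
    threshold: float = np.nan

    @property
    def n_components(self) -> int:
        return self.beta.size


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    per_randomisation_aucs: np.ndarray | None = None
    auc_percentiles: dict = field(default_factory=dict)


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def tpr(self) -> float:  # sensitivity
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else np.nan

    @property
    def tnr(self) -> float:  # specificity
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else np.nan

    @property
    def fpr(self) -> float:
        return 1.0 - self.tnr

    @property
    def fnr(self) -> float:
        return 1.0 - self.tpr

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    sensitivity = tpr
    specificity = tnr


@dataclass
class ResamplingClassificationResult:
    selected_K: int
    models: list[PLSLogisticModel]
    eta: pd.DataFrame  # sample_id, is_old, eta_mean, n_test_appearances, call_old
    tau_mean: float
    confusion: ConfusionSummary
    roc: ROCResult
    validation_curve: ValidationCurve


def binarize_age(
    meta: SampleTable, threshold_days: float = OLD_THRESHOLD_DAYS
) -> list[AgeClassLabel]:
    """Label each sample old (age >= threshold) or young (age < threshold)."""
    return [
        AgeClassLabel(row.sample_id, float(row.age_days), row.age_days >= threshold_days)
        for row in meta.df.itertuples()
    ]


def _as_bool(labels) -> np.ndarray:
    if len(labels) and isinstance(labels[0], AgeClassLabel):
        return np.array([lab.is_old for lab in labels], dtype=bool)
    return np.asarray(labels, dtype=bool)


def _logistic_irls(T: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Binomial logistic fit by iteratively reweighted least squares.

    Returns the coefficient vector for the design ``[1, T]``.  Iterations are
    capped and the coefficient norm clamped so that perfectly separable data
    still yields a finite, rank-preserving linear predictor.
    """
    X = np.column_stack([np.ones(len(T)), T])
    y = y.astype(float)
    beta = np.zeros(X.shape[1])
    for _ in range(IRLS_MAX_ITER):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        w = np.clip(p * (1.0 - p), 1e-10, None)
        z = eta + (y - p) / w
        Xw = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ z)
        except np.linalg.LinAlgError:
            break
        norm = np.linalg.norm(beta_new)
        if norm > IRLS_COEF_CAP:
            beta_new *= IRLS_COEF_CAP / norm
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    return beta


def fit_pls_logistic(X: np.ndarray, labels, K: int) -> PLSLogisticModel:
    """PLS scores against the centred 0/1 class, then a logistic fit on the
    K training scores."""
    y01 = _as_bool(labels)
    if y01.all() or not y01.any():
        raise ValueError("training data must contain both classes")
    pls = nipals_pls1(np.asarray(X, dtype=float), y01.astype(float), K)
    T = pls.scores(X)
    coefs = _logistic_irls(T, y01)
    return PLSLogisticModel(pls=pls, alpha=float(coefs[0]), beta=coefs[1:])


def linear_predictor(model: PLSLogisticModel, X: np.ndarray) -> np.ndarray:
    """eta(x) = alpha + scores(x) . beta for new spectra."""
    return model.alpha + model.pls.scores(X)[:, : model.n_components] @ model.beta


def optimal_threshold(eta: np.ndarray, labels) -> float:
    """Cut-point on the linear predictor minimising misclassification.

    Candidates are the midpoints between consecutive sorted unique eta
    values plus -inf/+inf; old is called when eta >= tau.  Ties are broken
    by the candidate maximising tpr + tnr, then by the smallest tau.
    """
    eta = np.asarray(eta, dtype=float)
    is_old = _as_bool(labels)
    if is_old.all() or not is_old.any():
        raise ValueError("optimal_threshold needs both classes")
    uniq = np.unique(eta)
    candidates = np.concatenate(
        [[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]]
    )
    best_tau, best_err, best_j = np.nan, np.inf, -np.inf
    for tau in candidates:
        call_old = eta >= tau
        err = int(np.sum(call_old != is_old))
        tpr = np.mean(call_old[is_old])
        tnr = np.mean(~call_old[~is_old])
        j = tpr + tnr
        if err < best_err or (err == best_err and j > best_j + 1e-12):
            best_tau, best_err, best_j = float(tau), err, j
    return best_tau


def confusion(eta: np.ndarray, tau: float, labels) -> ConfusionSummary:
    """Confusion counts for the rule old <=> eta >= tau."""
    eta = np.asarray(eta, dtype=float)
    is_old = _as_bool(labels)
    call_old = eta >= tau
    return ConfusionSummary(
        tp=int(np.sum(call_old & is_old)),
        fp=int(np.sum(call_old & ~is_old)),
        tn=int(np.sum(~call_old & ~is_old)),
        fn=int(np.sum(~call_old & is_old)),
    )


def roc_auc(eta: np.ndarray, labels) -> ROCResult:
    """ROC by sweeping the cut-point over all distinct eta values; AUC by
    trapezoid (identical to Mann-Whitney concordance with ties at 1/2)."""
    eta = np.asarray(eta, dtype=float)
    is_old = _as_bool(labels)
    n_pos = int(is_old.sum())
    n_neg = int((~is_old).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-eta, kind="stable")
    eta_sorted = eta[order]
    pos_sorted = is_old[order].astype(float)
    # collapse tied thresholds: cumulative counts at the last index of each tie
    distinct = np.r_[np.flatnonzero(np.diff(eta_sorted)), eta.size - 1]
    tp = np.cumsum(pos_sorted)[distinct]
    fp = np.cumsum(1.0 - pos_sorted)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, eta_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def select_K_auc(curve: ValidationCurve, tol: float = 0.01) -> int:
    """Smallest K whose mean validation AUC is within ``tol`` of the best."""
    best = curve.metric_per_K.max()
    ok = curve.metric_per_K >= best - tol
    return int(curve.K_grid[np.argmax(ok)])


def _finite_mean(values: np.ndarray) -> float:
    finite = values[np.isfinite(values)]
    return float(finite.mean()) if finite.size else 0.0


def resampling_classify(
    X: np.ndarray,
    labels,
    plan: SplitPlan,
    Kmax: int,
    sample_ids=None,
    auc_tol: float = 0.01,
) -> ResamplingClassificationResult:
    """Direct young/old classification under the resampling framework.

    Stage 1 fits PLS-logistic models per randomisation and builds the mean
    validation-AUC curve over K; the component count is the smallest K within
    ``auc_tol`` of the best mean AUC.  Stage 2 refits the logistic at that K,
    takes the misclassification-optimal cut-point on the validation
    partition, and accumulates blinded test linear predictors.  Final calls
    compare each sample's test-averaged eta to the average cut-point.
    """
    X = np.asarray(X, dtype=float)
    is_old = _as_bool(labels)
    n = X.shape[0]
    ids = [str(s) for s in (sample_ids if sample_ids is not None else range(n))]

    pls_models: list[PLSModel] = []
    val_auc = np.empty((plan.R, Kmax))
    for r, (tr, va, _) in enumerate(plan.splits):
        if is_old[tr].all() or not is_old[tr].any():
            raise ValueError(f"randomisation {r}: single-class training partition")
        pls = nipals_pls1(X[tr], is_old[tr].astype(float), Kmax)
        pls_models.append(pls)
        T_tr = pls.scores(X[tr])
        T_va = pls.scores(X[va])
        for K in range(1, Kmax + 1):
            coefs = _logistic_irls(T_tr[:, :K], is_old[tr])
            eta_va = coefs[0] + T_va[:, :K] @ coefs[1:]
            val_auc[r, K - 1] = roc_auc(eta_va, is_old[va]).auc
    curve = ValidationCurve(
        np.arange(1, Kmax + 1), val_auc.mean(axis=0), val_auc, metric_name="auc"
    )
    K = select_K_auc(curve, auc_tol)

    eta_sum = np.zeros(n)
    eta_count = np.zeros(n, dtype=int)
    taus = np.empty(plan.R)
    test_aucs = np.empty(plan.R)
    models: list[PLSLogisticModel] = []
    for r, (tr, va, te) in enumerate(plan.splits):
        pls = pls_models[r]
        T_tr = pls.scores(X[tr])[:, :K]
        coefs = _logistic_irls(T_tr, is_old[tr])
        eta_va = coefs[0] + pls.scores(X[va])[:, :K] @ coefs[1:]
        taus[r] = optimal_threshold(eta_va, is_old[va])
        eta_te = coefs[0] + pls.scores(X[te])[:, :K] @ coefs[1:]
        eta_sum[te] += eta_te
        eta_count[te] += 1
        test_aucs[r] = roc_auc(eta_te, is_old[te]).auc
        models.append(
            PLSLogisticModel(
                pls=pls, alpha=float(coefs[0]), beta=coefs[1:], threshold=taus[r]
            )
        )

    seen = eta_count > 0
    eta_bar = np.full(n, np.nan)
    eta_bar[seen] = eta_sum[seen] / eta_count[seen]
    tau_mean = _finite_mean(taus)
    call_old = eta_bar[seen] >= tau_mean
    conf = ConfusionSummary(
        tp=int(np.sum(call_old & is_old[seen])),
        fp=int(np.sum(call_old & ~is_old[seen])),
        tn=int(np.sum(~call_old & ~is_old[seen])),
        fn=int(np.sum(~call_old & is_old[seen])),
    )
    roc = roc_auc(eta_bar[seen], is_old[seen])
    roc.per_randomisation_aucs = test_aucs
    roc.auc_percentiles = {
        p: float(np.percentile(test_aucs, p)) for p in (5, 15, 25, 50, 75, 85, 95)
    }
    eta_df = pd.DataFrame(
        {
            "sample_id": np.asarray(ids)[seen],
            "is_old": is_old[seen],
            "eta_mean": eta_bar[seen],
            "n_test_appearances": eta_count[seen],
            "call_old": call_old,
        }
    )
    return ResamplingClassificationResult(
        selected_K=K,
        models=models,
        eta=eta_df,
        tau_mean=tau_mean,
        confusion=conf,
        roc=roc,
        validation_curve=curve,
    )


def transfer_classify(
    result: ResamplingClassificationResult,
    X_other: np.ndarray,
    labels_other,
    sample_ids=None,
) -> tuple[ConfusionSummary, ROCResult, pd.DataFrame]:
    """Apply a trained classifier ensemble to another population: average
    each model's linear predictor and compare to the training-time average
    cut-point."""
    X_other = np.asarray(X_other, dtype=float)
    is_old = _as_bool(labels_other)
    p = result.models[0].pls.n_channels
    if X_other.shape[1] != p:
        raise ValueError(
            f"channel grid mismatch: classifier expects {p} channels, got "
            f"{X_other.shape[1]}; re-trim and re-preprocess the transfer spectra"
        )
    eta_bar = np.mean([linear_predictor(m, X_other) for m in result.models], axis=0)
    call_old = eta_bar >= result.tau_mean
    conf = ConfusionSummary(
        tp=int(np.sum(call_old & is_old)),
        fp=int(np.sum(call_old & ~is_old)),
        tn=int(np.sum(~call_old & ~is_old)),
        fn=int(np.sum(~call_old & is_old)),
    )
    roc = roc_auc(eta_bar, is_old)
    n = X_other.shape[0]
    ids = [str(s) for s in (sample_ids if sample_ids is not None else range(n))]
    df = pd.DataFrame(
        {"sample_id": ids, "is_old": is_old, "eta_mean": eta_bar, "call_old": call_old}
    )
    return conf, roc, df


def classify_via_regression(
    predictions: pd.DataFrame | ResamplingRegressionResult,
    threshold_days: float = OLD_THRESHOLD_DAYS,
) -> ConfusionSummary:
    """Threshold continuous age predictions at ``threshold_days``: a sample
    is called old when its predicted age is >= the threshold, and truly old
    when its actual age is."""
    if isinstance(predictions, ResamplingRegressionResult):
        predictions = predictions.predictions
    is_old = predictions["y_true"].to_numpy() >= threshold_days
    call_old = predictions["y_hat"].to_numpy() >= threshold_days
    return ConfusionSummary(
        tp=int(np.sum(call_old & is_old)),
        fp=int(np.sum(call_old & ~is_old)),
        tn=int(np.sum(~call_old & ~is_old)),
        fn=int(np.sum(~call_old & is_old)),
    )
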