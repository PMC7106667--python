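"""Model-building procedures: leave-one-out "standard PLS" and the
resampling PLS framework, plus cross-population transfer evaluation.

Standard PLS mirrors classical chemometrics practice: leave-one-out
cross-validation over a component grid, choosing the smallest component
count whose LOOCV error is within a relative tolerance of the best — an
algorithmic stand-in for the traditional by-eye elbow choice.

Resampling PLS repeatedly splits the data into train (50%), validation (25%)
and test (25%) partitions.  The component count is chosen once, as the
smallest K whose mean validation RMSD is within 0.5 days of the best, and a
model with that K is fitted per randomisation; each sample's reported
prediction is the average of its blinded test-set predictions across
randomisations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pls_core import PLSModel, coef_path, group_summary, nipals_pls1, predict_age, rmsd

__all__ = [
    "SplitPlan",
    "ValidationCurve",
    "ResamplingRegressionResult",
    "make_splits",
    "loocv_curve",
    "select_K_standard",
    "resampling_validation",
    "select_K_resampling",
    "resampling_fit_predict",
    "transfer_evaluate",
]

TRAIN_FRACTION, VALIDATION_FRACTION, TEST_FRACTION = 0.5, 0.25, 0.25


@dataclass
class SplitPlan:
    """R reproducible train/validation/test partitions of n samples."""

    n: int
    R: int
    splits: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    seed: int
    stratified: bool
    fractions: tuple[float, float, float] = (
        TRAIN_FRACTION,
        VALIDATION_FRACTION,
        TEST_FRACTION,
    )

    def __post_init__(self) -> None:
        # generated plans are true partitions; hand-built degenerate plans
        # (e.g. train == test == everything, for consistency checks) are
        # allowed as long as every index is covered and sets have no
        # internal duplicates
        for r, (tr, va, te) in enumerate(self.splits):
            union = np.unique(np.concatenate([tr, va, te]))
            if union.size != self.n or (union != np.arange(self.n)).any():
                raise ValueError(f"randomisation {r}: indices do not cover 0..n-1")
            for part in (tr, va, te):
                if len(np.unique(part)) != len(part):
                    raise ValueError(f"randomisation {r}: duplicate indices in a set")


@dataclass
class ValidationCurve:
    """Mean validation metric (RMSD in days, or AUC) per component count."""

    K_grid: np.ndarray
    metric_per_K: np.ndarray
    per_randomisation_metric: np.ndarray | None = None
    metric_name: str = "rmsd"

    def __post_init__(self) -> None:
        self.K_grid = np.asarray(self.K_grid, dtype=int)
        self.metric_per_K = np.asarray(self.metric_per_K, dtype=float)
        if self.K_grid.size != self.metric_per_K.size or self.K_grid.size == 0:
            raise ValueError("K_grid and metric_per_K must align and be non-empty")
        if self.per_randomisation_metric is not None:
            m = np.asarray(self.per_randomisation_metric, dtype=float)
            if m.shape[1] != self.K_grid.size:
                raise ValueError("per-randomisation matrix width must match K_grid")
            if not np.allclose(m.mean(axis=0), self.metric_per_K):
                raise ValueError("metric_per_K must be the column mean")
            self.per_randomisation_metric = m


@dataclass
class ResamplingRegressionResult:
    """Output of the resampling PLS regression: averaged blinded predictions,
    overall RMSD, and the per-randomisation coefficient functions."""

    selected_K: int
    predictions: pd.DataFrame  # sample_id, y_true, y_hat, n_test_appearances
    rmsd: float
    coefs: np.ndarray  # (R, n_channels) best-fit coefficient vectors
    coef_mean: np.ndarray
    models: list[PLSModel]
    plan: SplitPlan
    excluded_sample_ids: list[str] = field(default_factory=list)


def make_splits(
    n: int,
    R: int = 100,
    seed: int = 0,
    strata: Sequence | None = None,
) -> SplitPlan:
    """Draw R random 50/25/25 train/validation/test partitions.

    With ``strata`` (e.g. age-group labels) each stratum is split
    separately so every group is represented in all three partitions of
    every randomisation; validation and test take floor(m/4) members of a
    stratum of size m and the remainder trains.  Unstratified splits use
    floor(n/4) for validation and test globally.
    """
    rng = np.random.default_rng(seed)
    if strata is not None:
        strata = np.asarray(strata)
        if strata.size != n:
            raise ValueError("strata must have one label per sample")
        groups = [np.flatnonzero(strata == g) for g in pd.unique(strata)]
        for g, idx in zip(pd.unique(strata), groups):
            if idx.size < 4:
                raise ValueError(
                    f"stratum {g!r} has only {idx.size} members; need >= 4"
                )
    else:
        if n < 4:
            raise ValueError("need at least 4 samples to split 50/25/25")
        groups = [np.arange(n)]

    splits = []
    for _ in range(R):
        tr_parts, va_parts, te_parts = [], [], []
        for idx in groups:
            perm = rng.permutation(idx)
            m = idx.size
            q = m // 4
            te_parts.append(perm[:q])
            va_parts.append(perm[q : 2 * q])
            tr_parts.append(perm[2 * q :])
        splits.append(
            (
                np.sort(np.concatenate(tr_parts)),
                np.sort(np.concatenate(va_parts)),
                np.sort(np.concatenate(te_parts)),
            )
        )
    return SplitPlan(
        n=n, R=R, splits=splits, seed=seed, stratified=strata is not None
    )


def _predictions_per_K(
    model: PLSModel, X: np.ndarray
) -> np.ndarray:
    """Predictions of every truncated model K=1..Kmax; shape (n, Kmax)."""
    B = coef_path(model)  # (p, Kmax)
    Xc = np.atleast_2d(X) - model.x_center
    if model.scale is not None:
        Xc = Xc / model.scale
    return model.y_center + Xc @ B


def loocv_curve(X: np.ndarray, y: np.ndarray, Kmax: int) -> ValidationCurve:
    """Leave-one-out cross-validation RMSD for each component count.

    Per held-out sample one NIPALS run with Kmax components supplies the
    predictions of every nested K at once.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    if Kmax > n - 2:
        raise ValueError(f"Kmax={Kmax} infeasible for n={n} (need Kmax <= n-2)")
    held_out = np.empty((n, Kmax))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = nipals_pls1(X[mask], y[mask], Kmax)
        held_out[i] = _predictions_per_K(model, X[i][None, :])[0]
    per_K = np.sqrt(np.mean((held_out - y[:, None]) ** 2, axis=0))
    return ValidationCurve(np.arange(1, Kmax + 1), per_K)


def select_K_standard(curve: ValidationCurve, rel_tol: float = 0.02) -> int:
    """Smallest K whose metric is within ``rel_tol`` (relative) of the
    curve minimum — the algorithmic version of the classical elbow choice."""
    best = curve.metric_per_K.min()
    ok = curve.metric_per_K <= (1.0 + rel_tol) * best
    return int(curve.K_grid[np.argmax(ok)])


def resampling_validation(
    X: np.ndarray, y: np.ndarray, plan: SplitPlan, Kmax: int
) -> ValidationCurve:
    """Per randomisation, fit on the training partition and score the
    validation partition for every K; average over randomisations."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    per = np.empty((plan.R, Kmax))
    for r, (tr, va, _) in enumerate(plan.splits):
        try:
            model = nipals_pls1(X[tr], y[tr], Kmax)
        except ValueError as exc:
            raise ValueError(f"randomisation {r}: {exc}") from exc
        preds = _predictions_per_K(model, X[va])
        per[r] = np.sqrt(np.mean((preds - y[va, None]) ** 2, axis=0))
    return ValidationCurve(np.arange(1, Kmax + 1), per.mean(axis=0), per)


def select_K_resampling(curve: ValidationCurve, tol_days: float = 0.5) -> int:
    """Smallest K whose mean validation RMSD is within ``tol_days`` of the
    best-fitting model's — trading a little accuracy for generalisability."""
    best = curve.metric_per_K.min()
    ok = curve.metric_per_K <= best + tol_days
    return int(curve.K_grid[np.argmax(ok)])


def resampling_fit_predict(
    X: np.ndarray,
    y: np.ndarray,
    plan: SplitPlan,
    K: int,
    sample_ids: Sequence[str] | None = None,
) -> ResamplingRegressionResult:
    """Fit one K-component model per randomisation and average each sample's
    blinded test-set predictions.

    The overall RMSD is computed on the averaged predictions, so it reflects
    the estimate a user would actually report per mosquito.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    ids = [str(s) for s in (sample_ids if sample_ids is not None else range(n))]
    pred_sum = np.zeros(n)
    pred_count = np.zeros(n, dtype=int)
    coefs = np.empty((plan.R, X.shape[1]))
    models: list[PLSModel] = []
    for r, (tr, _, te) in enumerate(plan.splits):
        try:
            model = nipals_pls1(X[tr], y[tr], K)
        except ValueError as exc:
            raise ValueError(f"randomisation {r}: {exc}") from exc
        models.append(model)
        coefs[r] = model.coef
        yhat = predict_age(model, X[te])
        pred_sum[te] += yhat
        pred_count[te] += 1

    seen = pred_count > 0
    excluded = [ids[i] for i in np.flatnonzero(~seen)]
    y_bar = np.full(n, np.nan)
    y_bar[seen] = pred_sum[seen] / pred_count[seen]
    predictions = pd.DataFrame(
        {
            "sample_id": np.asarray(ids)[seen],
            "y_true": y[seen],
            "y_hat": y_bar[seen],
            "n_test_appearances": pred_count[seen],
        }
    )
    return ResamplingRegressionResult(
        selected_K=K,
        predictions=predictions,
        rmsd=rmsd(y[seen], y_bar[seen]),
        coefs=coefs,
        coef_mean=coefs.mean(axis=0),
        models=models,
        plan=plan,
        excluded_sample_ids=excluded,
    )


def transfer_evaluate(
    fitted: PLSModel | ResamplingRegressionResult,
    X_other: np.ndarray,
    y_other: np.ndarray,
    groups_other: Sequence[str],
    sample_ids: Sequence[str] | None = None,
    old_threshold_days: float = 8.0,
) -> tuple[float, pd.DataFrame, pd.DataFrame]:
    """Apply a fitted model (or resampling ensemble) to another population.

    For a single standard-PLS model the predictions are direct; for a
    resampling result each sample's prediction is the mean over the R
    per-randomisation models.  Returns ``(rmsd, group_summary, predictions)``.
    """
    X_other = np.asarray(X_other, dtype=float)
    y_other = np.asarray(y_other, dtype=float).ravel()
    n = X_other.shape[0]
    models = (
        [fitted] if isinstance(fitted, PLSModel) else fitted.models
    )
    p = models[0].n_channels
    if X_other.shape[1] != p:
        raise ValueError(
            f"channel grid mismatch: model expects {p} channels, transfer set "
            f"has {X_other.shape[1]}; re-trim and re-preprocess the transfer "
            "spectra with the training settings"
        )
    yhat = np.mean([predict_age(m, X_other) for m in models], axis=0)
    ids = [str(s) for s in (sample_ids if sample_ids is not None else range(n))]
    predictions = pd.DataFrame(
        {
            "sample_id": ids,
            "y_true": y_other,
            "y_hat": yhat,
            "n_test_appearances": len(models),
        }
    )
    summary = group_summary(predictions, groups_other, old_threshold_days)
    return rmsd(y_other, yhat), summary, predictions
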