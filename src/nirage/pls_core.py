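"""NIPALS partial least squares regression with a single response (PLS1).

For one response variable NIPALS needs no inner iteration: per component the
weight vector is w = X'y on the deflated matrix, giving a fully deterministic
decomposition.  The class stores the weights W, loadings P, response loadings
q and the centres, from which the regression-coefficient function

    b = W (P'W)^-1 q

is derived; b is the curve over wavelength that shows which spectral regions
drive the age prediction.  Columns of X are mean-centred but not variance
scaled by default (all channels share absorbance units).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PLSModel",
    "nipals_pls1",
    "fit_pls",
    "predict_age",
    "rmsd",
    "group_summary",
]

#: Component loop aborts when the weight norm falls below this fraction of
#: the first component's weight norm (residual rank exhausted).
RANK_TOL = 1e-12


@dataclass
class PLSModel:
    """Fitted NIPALS PLS1 model.

    Attributes
    ----------
    n_components
        Number of latent components K.
    x_weights, x_loadings
        ``(n_channels, K)`` matrices W and P from the NIPALS deflation.
    y_loadings
        Length-K vector q.
    x_center, y_center
        Training means used for centring.
    coef
        The regression-coefficient vector b = W (P'W)^-1 q.
    scale
        Optional per-channel scaling applied after centring (None = no
        autoscaling, the default for spectra).
    fitted_on
        Provenance record (sample count, channels, flags).
    """

    n_components: int
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_center: np.ndarray
    y_center: float
    coef: np.ndarray
    scale: np.ndarray | None = None
    fitted_on: dict = field(default_factory=dict)

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Project new rows onto the K latent components."""
        Xc = _center_scale(X, self.x_center, self.scale, self.n_channels)
        return Xc @ rotation(self.x_weights, self.x_loadings)

    @property
    def n_channels(self) -> int:
        return self.x_center.size

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "x_center": self.x_center.tolist(),
            "y_center": float(self.y_center),
            "coef": self.coef.tolist(),
            "scale": None if self.scale is None else self.scale.tolist(),
            "fitted_on": self.fitted_on,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        return cls(
            n_components=int(d["n_components"]),
            x_weights=np.asarray(d["x_weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            x_center=np.asarray(d["x_center"], dtype=float),
            y_center=float(d["y_center"]),
            coef=np.asarray(d["coef"], dtype=float),
            scale=None if d.get("scale") is None else np.asarray(d["scale"]),
            fitted_on=d.get("fitted_on", {}),
        )


def _center_scale(
    X: np.ndarray, center: np.ndarray, scale: np.ndarray | None, p: int
) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != p:
        raise ValueError(
            f"channel mismatch: model has {p} channels, input has {X.shape[1]}"
        )
    Xc = X - center
    if scale is not None:
        Xc = Xc / scale
    return Xc


def rotation(W: np.ndarray, P: np.ndarray) -> np.ndarray:
    """The rotation R = W (P'W)^-1 mapping centred X to scores."""
    K = W.shape[1]
    return W @ np.linalg.solve(P.T @ W, np.eye(K))


def nipals_pls1(
    X: np.ndarray, y: np.ndarray, n_components: int, autoscale: bool = False
) -> PLSModel:
    """Run the NIPALS deflation and return the fitted model.

    Raises if the residual matrix loses rank before ``n_components``
    components are extracted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y sample counts differ")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} infeasible for n={n}, p={p}"
        )
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("missing or non-finite values in X or y")

    x_center = X.mean(axis=0)
    y_center = float(y.mean())
    scale = None
    Xc = X - x_center
    if autoscale:
        scale = Xc.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
        Xc = Xc / scale
    yc = y - y_center

    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    q = np.empty(n_components)
    w0_norm = None
    for k in range(n_components):
        w = Xc.T @ yc
        norm = np.linalg.norm(w)
        if w0_norm is None:
            w0_norm = norm if norm > 0 else 1.0
        if norm < RANK_TOL * w0_norm or norm == 0.0:
            raise ValueError(f"rank exhausted at component {k + 1}")
        w /= norm
        t = Xc @ w
        tt = float(t @ t)
        if tt == 0.0:
            raise ValueError(f"rank exhausted at component {k + 1}")
        pvec = (Xc.T @ t) / tt
        qk = float(yc @ t) / tt
        Xc = Xc - np.outer(t, pvec)
        yc = yc - qk * t
        W[:, k], P[:, k], q[k] = w, pvec, qk

    coef = rotation(W, P) @ q
    return PLSModel(
        n_components=n_components,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        x_center=x_center,
        y_center=y_center,
        coef=coef,
        scale=scale,
        fitted_on={"n_samples": n, "n_channels": p, "autoscale": bool(autoscale)},
    )


def fit_pls(
    X: np.ndarray, y: np.ndarray, n_components: int, autoscale: bool = False
) -> PLSModel:
    """Fit a PLS1 model of the response (age in days) on spectra."""
    return nipals_pls1(X, y, n_components, autoscale=autoscale)


def coef_path(model: PLSModel) -> np.ndarray:
    """Regression-coefficient vectors for every truncation K = 1..n_components.

    Returns a ``(n_channels, n_components)`` matrix whose column K-1 is the
    coefficient vector of the model truncated to its first K components.
    NIPALS components are nested, so one deflation serves the whole grid.
    """
    W, P, q = model.x_weights, model.x_loadings, model.y_loadings
    p, Kmax = W.shape
    out = np.empty((p, Kmax))
    for K in range(1, Kmax + 1):
        out[:, K - 1] = rotation(W[:, :K], P[:, :K]) @ q[:K]
    return out


def predict_age(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predict the response: y_center + (X - x_center) . b.

    Out-of-range (e.g. negative) ages are reported as-is; clipping would
    bias RMSD.
    """
    Xc = _center_scale(X, model.x_center, model.scale, model.n_channels)
    return model.y_center + Xc @ model.coef


def rmsd(y_true: np.ndarray, y_hat: np.ndarray) -> float:
    """Root-mean-square deviation between true and predicted ages, in days."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y_true.size == 0 or y_true.size != y_hat.size:
        raise ValueError("y_true and y_hat must have equal nonzero lengths")
    return float(np.sqrt(np.mean((y_true - y_hat) ** 2)))


def group_summary(
    predictions: pd.DataFrame,
    groups: Sequence[str],
    old_threshold_days: float = 8.0,
    classified_old: Sequence[bool] | None = None,
) -> pd.DataFrame:
    """Per-group mean predicted age, SEM and percentage classed old.

    ``predictions`` needs columns ``sample_id, y_true, y_hat``; ``groups``
    aligns with its rows.  By default a sample is classed old when its
    predicted age is >= ``old_threshold_days``; a classifier's boolean calls
    can be supplied instead.  Groups with a single sample get SEM = NaN.
    """
    df = predictions.copy()
    df["group"] = np.asarray(groups)
    if classified_old is None:
        df["old_call"] = df["y_hat"] >= old_threshold_days
    else:
        df["old_call"] = np.asarray(classified_old, dtype=bool)
    rows = []
    for g, sub in df.groupby("group", sort=True):
        n = len(sub)
        rows.append(
            {
                "group": g,
                "n": n,
                "true_age_days": sub["y_true"].mean(),
                "mean_predicted_age": sub["y_hat"].mean(),
                "sem": sub["y_hat"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "pct_classed_old": 100.0 * sub["old_call"].mean(),
            }
        )
    return pd.DataFrame(rows).sort_values("true_age_days").reset_index(drop=True)
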