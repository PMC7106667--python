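"""PCA diagnostics for spectra: variance decomposition, Hotelling-T²
outlier screening at the 95% level, and loading-peak identification.

The T² statistic of a sample is its squared Mahalanobis distance in the
retained score space; the control limit uses the classical F-form

    limit = A (n - 1) / (n - A) * F_{alpha}(A, n - A)

for A retained components and n samples, approximating the 95% confidence
ellipse used in chemometrics software.  Screening is single-pass: flagged
samples are removed once, without re-fitting and repeating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spectra_io import SampleTable, SpectraSet

__all__ = [
    "PCAResult",
    "fit_pca",
    "hotelling_t2",
    "remove_outliers",
    "loading_peaks",
]


@dataclass
class PCAResult:
    n_components: int
    scores: np.ndarray  # (n_samples, A)
    loadings: np.ndarray  # (n_channels, A), orthonormal columns
    explained_fraction: np.ndarray  # per retained component
    mean: np.ndarray
    t2: np.ndarray | None = None
    t2_limit: float | None = None
    outlier_mask: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]


def fit_pca(X: np.ndarray, A: int) -> PCAResult:
    """PCA of column-mean-centred X by singular value decomposition.

    ``explained_fraction[k]`` is sigma_k^2 over the total sum of squared
    singular values (all components, not just the retained A).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= A <= min(n - 1, p):
        raise ValueError(f"A={A} infeasible for n={n}, p={p}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0:
        raise ValueError("zero-variance matrix")
    return PCAResult(
        n_components=A,
        scores=U[:, :A] * s[:A],
        loadings=Vt[:A].T,
        explained_fraction=s[:A] ** 2 / total,
        mean=mean,
    )


def hotelling_t2(p: PCAResult, alpha: float = 0.95) -> PCAResult:
    """Per-sample Hotelling T² over the retained scores, with the
    F-distribution control limit; fills t2, t2_limit and outlier_mask."""
    A, n = p.n_components, p.n_samples
    if n <= A:
        raise ValueError("need more samples than retained components")
    lam = p.scores.var(axis=0, ddof=1)
    if np.any(lam <= 0):
        raise ValueError("degenerate component with zero score variance")
    p.t2 = np.sum(p.scores**2 / lam, axis=1)
    p.t2_limit = float(
        A * (n - 1) / (n - A) * stats.f.ppf(alpha, A, n - A)
    )
    p.outlier_mask = p.t2 > p.t2_limit
    return p


def remove_outliers(
    spectra: SpectraSet,
    meta: SampleTable,
    A: int = 4,
    alpha: float = 0.95,
) -> tuple[SpectraSet, SampleTable, pd.DataFrame]:
    """Single-pass T² screen: fit PCA on the spectra, flag samples beyond
    the ``alpha`` limit, and drop them from both tables.

    Returns the filtered pair and a removal report (sample_id, t2, limit).
    """
    pca = hotelling_t2(fit_pca(spectra.values, A), alpha)
    flagged = np.flatnonzero(pca.outlier_mask)
    if flagged.size == spectra.n_samples:
        raise ValueError("all samples flagged as outliers; screen is degenerate")
    report = pd.DataFrame(
        {
            "sample_id": [spectra.sample_ids[i] for i in flagged],
            "t2": pca.t2[flagged],
            "t2_limit": pca.t2_limit,
        }
    )
    if flagged.size == 0:
        return spectra, meta, report
    keep_ids = [s for i, s in enumerate(spectra.sample_ids) if i not in set(flagged)]
    return spectra.subset(keep_ids), meta.subset(keep_ids), report


def loading_peaks(
    p: PCAResult,
    wavelengths_nm: np.ndarray,
    component: int,
    candidate_bands_nm,
    window_nm: float = 15.0,
) -> pd.DataFrame:
    """For each candidate band, report whether a local maximum of the
    absolute loading of ``component`` (1-based) lies within ±window_nm."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    if not 1 <= component <= p.n_components:
        raise ValueError(f"component {component} not retained")
    load = np.abs(p.loadings[:, component - 1])
    interior = (load[1:-1] >= load[:-2]) & (load[1:-1] >= load[2:])
    peak_idx = np.flatnonzero(interior) + 1
    # a strictly flat loading vector has no informative peaks
    if load.max() - load.min() < 1e-12 * max(load.max(), 1e-300):
        peak_idx = np.array([], dtype=int)
    peak_wl = wl[peak_idx]
    rows = []
    for band in candidate_bands_nm:
        if not wl[0] <= band <= wl[-1]:
            raise ValueError(f"candidate band {band} nm outside the grid")
        hit = bool(np.any(np.abs(peak_wl - band) <= window_nm)) if peak_wl.size else False
        nearest = float(peak_wl[np.argmin(np.abs(peak_wl - band))]) if peak_wl.size else np.nan
        rows.append({"band_nm": float(band), "peak_found": hit, "nearest_peak_nm": nearest})
    return pd.DataFrame(rows)
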