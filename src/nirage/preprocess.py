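"""Spectral pre-treatments: SNV, mean normalisation, detrend-SNV and
Savitzky-Golay second-derivative filtering.

All methods operate per spectrum (row-wise).  SNV standardises each spectrum
to mean 0 / sample standard deviation 1, which removes per-sample additive
offsets and multiplicative scatter.  Detrend-SNV additionally removes a
low-order polynomial baseline in wavelength from the SNV spectrum.  The
Savitzky-Golay filter differentiates twice with a local polynomial fit; edge
channels where the window does not fit are dropped rather than padded, so the
output grid shrinks by ``window - 1`` channels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .spectra_io import ABSORBANCE, SpectraSet

__all__ = [
    "PreprocessSpec",
    "snv",
    "mean_normalize",
    "detrend_snv",
    "sg_second_derivative",
    "apply_preprocess",
]

METHODS = ("none", "snv", "mean_normalize", "detrend_snv", "sg_second_derivative")


@dataclass(frozen=True)
class PreprocessSpec:
    """Choice of pre-treatment and its parameters.

    sg_window is in channels (default 17, about 51 nm at 3 nm spacing);
    sg_polyorder defaults to 3 with a second derivative; detrend_degree
    defaults to 2, the usual detrend-SNV baseline order.
    """

    method: str = "none"
    sg_window: int = 17
    sg_polyorder: int = 3
    detrend_degree: int = 2

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; one of {METHODS}")
        if self.sg_window < 5 or self.sg_window % 2 == 0:
            raise ValueError("sg_window must be an odd integer >= 5")
        if self.sg_polyorder < 2 or self.sg_polyorder >= self.sg_window:
            raise ValueError("require 2 <= sg_polyorder < sg_window")
        if self.detrend_degree < 1:
            raise ValueError("detrend_degree must be >= 1")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "sg_window": self.sg_window,
            "sg_polyorder": self.sg_polyorder,
            "detrend_degree": self.detrend_degree,
        }


def snv(row: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale one spectrum to unit
    sample (n-1) standard deviation."""
    row = np.asarray(row, dtype=float)
    if row.size < 2:
        raise ValueError("SNV needs at least 2 channels")
    sd = row.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance spectrum")
    return (row - row.mean()) / sd


def mean_normalize(row: np.ndarray) -> np.ndarray:
    """Divide a spectrum by its mean, so the output mean is exactly 1."""
    row = np.asarray(row, dtype=float)
    m = row.mean()
    if m == 0:
        raise ValueError("zero-mean spectrum cannot be mean-normalised")
    return row / m


def detrend_snv(
    row: np.ndarray, wavelengths_nm: np.ndarray, degree: int = 2
) -> np.ndarray:
    """SNV followed by removal of a degree-``degree`` polynomial baseline in
    wavelength (Barnes-style detrend): the residual of a least-squares fit."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    z = snv(row)
    if z.size <= degree + 1:
        raise ValueError("spectrum too short for the requested detrend degree")
    # Scale wavelengths to [-1, 1] for a well-conditioned Vandermonde basis.
    x = (wl - wl.mean()) / (0.5 * (wl.max() - wl.min()))
    basis = np.polynomial.polynomial.polyvander(x, degree)
    coef, *_ = np.linalg.lstsq(basis, z, rcond=None)
    return z - basis @ coef


def sg_second_derivative(
    values: np.ndarray, wavelengths_nm: np.ndarray, spec: PreprocessSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Savitzky-Golay second derivative of each row, in absorbance * nm^-2.

    Requires a uniform wavelength grid.  Edge channels where the window runs
    off the spectrum are dropped; returns ``(matrix, trimmed_wavelengths)``.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    values = np.asarray(values, dtype=float)
    one_dim = values.ndim == 1
    values = np.atleast_2d(values)
    steps = np.diff(wl)
    h = steps.mean()
    if np.max(np.abs(steps - h)) > 1e-6 * h:
        raise ValueError("Savitzky-Golay filtering needs a uniform wavelength grid")
    if spec.sg_window > wl.size:
        raise ValueError("sg_window larger than the number of channels")
    deriv = savgol_filter(
        values, spec.sg_window, spec.sg_polyorder, deriv=2, delta=h, axis=1
    )
    half = (spec.sg_window - 1) // 2
    deriv = deriv[:, half:-half]
    if one_dim:
        deriv = deriv[0]
    return deriv, wl[half:-half]


def apply_preprocess(spectra: SpectraSet, spec: PreprocessSpec) -> SpectraSet:
    """Apply the selected pre-treatment row-wise to an absorbance SpectraSet."""
    if spectra.mode != ABSORBANCE:
        raise ValueError("pre-processing expects absorbance spectra")
    prov = dict(spectra.provenance)
    prov["preprocess"] = spec.to_dict()
    if spec.method == "none":
        return replace(spectra, provenance=prov)
    if spec.method == "sg_second_derivative":
        deriv, wl = sg_second_derivative(spectra.values, spectra.wavelengths_nm, spec)
        return replace(spectra, values=deriv, wavelengths_nm=wl, provenance=prov)
    out = np.empty_like(spectra.values)
    for i, row in enumerate(spectra.values):
        try:
            if spec.method == "snv":
                out[i] = snv(row)
            elif spec.method == "mean_normalize":
                out[i] = mean_normalize(row)
            else:
                out[i] = detrend_snv(row, spectra.wavelengths_nm, spec.detrend_degree)
        except ValueError as exc:
            raise ValueError(f"sample {spectra.sample_ids[i]!r}: {exc}") from exc
    return replace(spectra, values=out, provenance=prov)
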