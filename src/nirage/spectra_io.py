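"""Spectra and metadata containers, CSV interchange, and basic transforms.

The canonical interchange format is plain CSV: a wide spectra table with a
``wavelength_nm`` column followed by one column per sample (one row per
channel), and a per-sample metadata table with columns
``sample_id,age_days,cohort,group``.  Reflectance spectra are converted to
absorbance as log10(1/R) — the standard spectroscopy convention — before any
modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "SampleTable",
    "read_spectra",
    "write_spectra",
    "to_absorbance",
    "trim_window",
]

REFLECTANCE = "reflectance"
ABSORBANCE = "absorbance"

METADATA_COLUMNS = ("sample_id", "age_days", "cohort", "group")


@dataclass
class SpectraSet:
    """A wavelength grid plus a samples x channels intensity matrix.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing channel positions in nanometres.
    values
        Matrix of shape ``(n_samples, n_channels)``.
    mode
        ``"reflectance"`` (values in (0, 1]) or ``"absorbance"`` (any finite
        values, log10(1/R) units).
    sample_ids
        Unique string identifiers, one per row of ``values``.
    provenance
        Free-form record of the transforms applied so far.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    mode: str
    sample_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.wavelengths_nm.ndim != 1:
            raise ValueError("wavelengths_nm must be one-dimensional")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x channels matrix")
        if self.values.shape[1] != self.wavelengths_nm.size:
            raise ValueError(
                f"values has {self.values.shape[1]} channels but the grid has "
                f"{self.wavelengths_nm.size}"
            )
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids must align 1:1 with rows of values")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite spectral values")
        if self.mode not in (REFLECTANCE, ABSORBANCE):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == REFLECTANCE and (
            np.any(self.values <= 0) or np.any(self.values > 1)
        ):
            raise ValueError("reflectance values must lie in (0, 1]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def subset(self, sample_ids: Iterable[str]) -> "SpectraSet":
        """Return the rows for ``sample_ids``, in the given order."""
        ids = list(sample_ids)
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        rows = [index[s] for s in ids]
        return replace(self, values=self.values[rows], sample_ids=ids)


@dataclass
class SampleTable:
    """Per-sample metadata: age in days, cohort (lab|field) and group label."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"metadata is missing columns {missing}")
        df = df.loc[:, list(METADATA_COLUMNS)].copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["age_days"] = pd.to_numeric(df["age_days"], errors="raise")
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in metadata: {dupes}")
        if (df["age_days"] < 0).any():
            raise ValueError("age_days must be non-negative")
        bad = set(df["cohort"]) - {"lab", "field"}
        if bad:
            raise ValueError(f"unknown cohort labels: {sorted(bad)}")
        self.df = df.reset_index(drop=True)

    def aligned_to(self, sample_ids: Iterable[str]) -> pd.DataFrame:
        """Metadata rows reordered to match ``sample_ids`` exactly."""
        ids = list(sample_ids)
        sub = self.df.set_index("sample_id")
        missing = [s for s in ids if s not in sub.index]
        if missing:
            raise KeyError(f"unmatched sample ids: {missing}")
        return sub.loc[ids].reset_index()

    def subset(self, sample_ids: Iterable[str]) -> "SampleTable":
        return SampleTable(self.aligned_to(sample_ids))

    def ages(self, sample_ids: Iterable[str]) -> np.ndarray:
        return self.aligned_to(sample_ids)["age_days"].to_numpy(dtype=float)

    def groups(self, sample_ids: Iterable[str]) -> np.ndarray:
        return self.aligned_to(sample_ids)["group"].to_numpy()

    def cohorts(self, sample_ids: Iterable[str]) -> np.ndarray:
        return self.aligned_to(sample_ids)["cohort"].to_numpy()


def read_spectra(
    path: str | Path, metadata_path: str | Path, mode: str = ABSORBANCE
) -> tuple[SpectraSet, SampleTable]:
    """Read a wide spectra CSV and its metadata CSV as a validated pair.

    The spectra file must have ``wavelength_nm`` as its first column and one
    column per sample; channels may appear in any order and are sorted
    ascending.  Every sample column must have a metadata record.
    """
    wide = pd.read_csv(path)
    if wide.columns[0] != "wavelength_nm":
        raise ValueError("first column of the spectra CSV must be 'wavelength_nm'")
    try:
        wl = wide["wavelength_nm"].astype(float).to_numpy()
        mat = wide.iloc[:, 1:].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in spectra CSV: {exc}") from exc
    order = np.argsort(wl, kind="stable")
    wl_sorted = wl[order]
    if np.any(np.diff(wl_sorted) <= 0):
        raise ValueError("wavelength column contains duplicate values")
    sample_ids = [str(c) for c in wide.columns[1:]]
    spectra = SpectraSet(
        wavelengths_nm=wl_sorted,
        values=mat[order].T,
        mode=mode,
        sample_ids=sample_ids,
        provenance={"source": str(path)},
    )
    meta = SampleTable(pd.read_csv(metadata_path))
    known = set(meta.df["sample_id"])
    unmatched = [s for s in sample_ids if s not in known]
    if unmatched:
        raise ValueError(f"unmatched sample ids (no metadata record): {unmatched}")
    return spectra, meta.subset(sample_ids)


def write_spectra(
    spectra: SpectraSet,
    path: str | Path,
    meta: SampleTable | None = None,
    metadata_path: str | Path | None = None,
) -> None:
    """Write the wide spectra CSV (and optionally the metadata CSV)."""
    wide = pd.DataFrame(
        spectra.values.T, columns=spectra.sample_ids
    )
    wide.insert(0, "wavelength_nm", spectra.wavelengths_nm)
    wide.to_csv(path, index=False)
    if meta is not None:
        if metadata_path is None:
            raise ValueError("metadata_path required when meta is given")
        meta.aligned_to(spectra.sample_ids).to_csv(metadata_path, index=False)


def to_absorbance(spectra: SpectraSet) -> SpectraSet:
    """Convert reflectance R to absorbance log10(1/R)."""
    if spectra.mode != REFLECTANCE:
        raise ValueError("to_absorbance expects a reflectance SpectraSet")
    bad = np.argwhere(spectra.values <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive reflectance for sample {spectra.sample_ids[i]!r} "
            f"at {spectra.wavelengths_nm[j]:g} nm"
        )
    prov = dict(spectra.provenance)
    prov["absorbance"] = "log10(1/R)"
    return replace(
        spectra,
        values=np.log10(1.0 / spectra.values),
        mode=ABSORBANCE,
        provenance=prov,
    )


def trim_window(spectra: SpectraSet, lo_nm: float, hi_nm: float) -> SpectraSet:
    """Restrict to channels with lo_nm <= wavelength <= hi_nm (closed interval)."""
    if not lo_nm < hi_nm:
        raise ValueError("require lo_nm < hi_nm")
    keep = (spectra.wavelengths_nm >= lo_nm) & (spectra.wavelengths_nm <= hi_nm)
    if not keep.any():
        raise ValueError(f"no channels in window [{lo_nm}, {hi_nm}] nm")
    prov = dict(spectra.provenance)
    prov["window_nm"] = (float(lo_nm), float(hi_nm))
    return replace(
        spectra,
        wavelengths_nm=spectra.wavelengths_nm[keep],
        values=spectra.values[:, keep],
        provenance=prov,
    )
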