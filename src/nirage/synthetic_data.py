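"""Seeded generator of synthetic mosquito NIR spectra.

No public spectral dataset accompanies the age-grading problem, so the
generator produces absorbance spectra with the statistical structure the
analysis assumes: Gaussian absorbance bands whose amplitudes carry a linear
age signal in the C-H overtone regions (~1170 and ~1400 nm), dominant water
bands at 1450 and 1930 nm, per-sample additive/multiplicative scatter
baselines, and iid channel noise.

The laboratory/field domain shift — the phenomenon that breaks model
transfer — is modelled as a hydration effect on the water bands: field
mosquitoes carry a higher mean water-band amplitude and a much larger
per-sample spread of water content.  A model trained on laboratory data,
where water content tracks age tightly, leans on the water bands; on field
material the erratic hydration then corrupts both the location and the
ranking of its predictions.  Within each cohort the C-H age signal is
intact, so cohort-internal models keep working.

Everything is driven by one master seed; identical configs give
bit-identical spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectra_io import ABSORBANCE, SampleTable, SpectraSet

__all__ = [
    "Band",
    "CohortDesign",
    "SimulationConfig",
    "default_config",
    "simulate",
    "inject_outliers",
]


@dataclass(frozen=True)
class Band:
    """One Gaussian absorbance band.

    Per-sample amplitude = base_amplitude + age_slope * age
    + cohort_delta (field samples only) + N(0, amplitude_jitter_sd)
    + water_coupling * per-sample water factor.
    """

    center_nm: float
    width_nm: float  # Gaussian standard deviation
    base_amplitude: float
    age_slope: float = 0.0  # absorbance per day
    cohort_delta: float = 0.0  # additive amplitude for cohort == "field"
    amplitude_jitter_sd: float = 0.0
    water_coupling: float = 0.0

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("width_nm must be positive")


@dataclass(frozen=True)
class CohortDesign:
    cohort: str  # "lab" | "field"
    ages_days: tuple
    n_per_age: tuple  # one count per age group

    def __post_init__(self) -> None:
        if len(self.ages_days) != len(self.n_per_age):
            raise ValueError("ages_days and n_per_age must align")
        if any(n < 1 for n in self.n_per_age):
            raise ValueError("need at least one sample per age group")


@dataclass(frozen=True)
class SimulationConfig:
    grid_start_nm: float = 350.0
    grid_stop_nm: float = 2500.0
    grid_step_nm: float = 3.0
    designs: tuple = ()
    bands: tuple = ()
    baseline_offset_sd: float = 0.015
    scatter_slope_sd: float = 0.02
    noise_sd: float = 0.01
    water_content_sd: dict = field(default_factory=dict)  # per cohort
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_step_nm <= 0:
            raise ValueError("grid_step_nm must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        # inclusive of the stop point only when it falls on the grid
        return np.arange(
            self.grid_start_nm, self.grid_stop_nm + 1e-6, self.grid_step_nm
        )


def default_config(seed: int = 0) -> SimulationConfig:
    """Study conditions: a laboratory cohort sampled at 2, 5, 8, 12 and 15
    days post-emergence and a field-derived cohort at 1, 7 and 14 days, on a
    350-2500 nm grid at 3 nm resolution.

    Band placement follows the spectral interpretation of mosquito NIRS:
    age-informative C-H overtone bands near 1170 and 1400 nm, dominant water
    bands at 1450 and 1930 nm whose amplitude declines with age (younger
    insects are wetter) and whose per-sample spread is far larger in
    field-derived material.
    """
    return SimulationConfig(
        designs=(
            CohortDesign("lab", (2, 5, 8, 12, 15), (41, 42, 42, 42, 44)),
            CohortDesign("field", (1, 7, 14), (50, 50, 100)),
        ),
        bands=(
            Band(1170.0, 30.0, 0.12, age_slope=0.0045, amplitude_jitter_sd=0.025),
            Band(1400.0, 40.0, 0.15, age_slope=0.0055, amplitude_jitter_sd=0.025),
            Band(
                1450.0, 35.0, 0.45,
                age_slope=-0.006, cohort_delta=0.03, water_coupling=1.0,
            ),
            Band(
                1930.0, 45.0, 0.55,
                age_slope=-0.007, cohort_delta=0.04, water_coupling=1.0,
            ),
        ),
        baseline_offset_sd=0.015,
        scatter_slope_sd=0.02,
        noise_sd=0.01,
        water_content_sd={"lab": 0.008, "field": 0.15},
        seed=seed,
    )


def simulate(config: SimulationConfig) -> tuple[SpectraSet, SampleTable]:
    """Draw one dataset from the generative model.

    Per sample: Gaussian band superposition with age/cohort/hydration
    amplitude terms, a random additive offset, a random linear scatter
    slope across the window, and iid channel noise.  Returns an absorbance
    SpectraSet and the matching SampleTable (group label "<cohort>_day<a>").
    """
    if not config.designs or not config.bands:
        raise ValueError("config needs at least one cohort design and one band")
    rng = np.random.default_rng(config.seed)
    wl = config.wavelengths_nm
    span = wl[-1] - wl[0]
    ramp = (wl - wl.mean()) / span

    profiles = np.stack(
        [
            np.exp(-((wl - b.center_nm) ** 2) / (2.0 * b.width_nm**2))
            for b in config.bands
        ]
    )  # (n_bands, n_channels)

    rows, ids, ages, cohorts, groups = [], [], [], [], []
    counter = 0
    for design in config.designs:
        for age, n in zip(design.ages_days, design.n_per_age):
            for _ in range(n):
                water_sd = config.water_content_sd.get(design.cohort, 0.0)
                w_i = rng.normal(0.0, water_sd) if water_sd > 0 else 0.0
                amps = np.array(
                    [
                        b.base_amplitude
                        + b.age_slope * age
                        + (b.cohort_delta if design.cohort == "field" else 0.0)
                        + (
                            rng.normal(0.0, b.amplitude_jitter_sd)
                            if b.amplitude_jitter_sd > 0
                            else 0.0
                        )
                        + b.water_coupling * w_i
                        for b in config.bands
                    ]
                )
                offset = rng.normal(0.0, config.baseline_offset_sd)
                slope = rng.normal(0.0, config.scatter_slope_sd)
                noise = (
                    rng.normal(0.0, config.noise_sd, wl.size)
                    if config.noise_sd > 0
                    else 0.0
                )
                rows.append(amps @ profiles + offset + slope * ramp + noise)
                counter += 1
                ids.append(f"{design.cohort}_{counter:04d}")
                ages.append(float(age))
                cohorts.append(design.cohort)
                groups.append(f"{design.cohort}_day{age:g}")

    spectra = SpectraSet(
        wavelengths_nm=wl,
        values=np.vstack(rows),
        mode=ABSORBANCE,
        sample_ids=ids,
        provenance={"simulated": True, "seed": config.seed},
    )
    meta = SampleTable(
        pd.DataFrame(
            {"sample_id": ids, "age_days": ages, "cohort": cohorts, "group": groups}
        )
    )
    return spectra, meta


def inject_outliers(
    spectra: SpectraSet, sample_ids, scale: float
) -> SpectraSet:
    """Multiply the named spectra by ``scale`` (a fixture for the T² screen)."""
    index = {s: i for i, s in enumerate(spectra.sample_ids)}
    missing = [s for s in sample_ids if s not in index]
    if missing:
        raise KeyError(f"unknown sample ids: {missing}")
    values = spectra.values.copy()
    for s in sample_ids:
        values[index[s]] *= scale
    return replace(spectra, values=values)
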