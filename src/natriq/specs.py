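"""Tissue, phantom and subject specifications for the synthetic cohort.

``REGION_REFERENCE`` holds the cohort-mean relaxometry and concentration
values (with between-subject standard deviations) for the ten brain ROIs
the pipeline quantifies: whole grey and white matter plus eight sub-regions.
These anchor the synthetic-data generator so that simulated cohorts have
realistic decay constants, short-fraction weights and sodium levels.

Signal fractions ``f`` are only reported for a subset of regions (GM 0.46,
caudate 0.52, pons 0.52, centrum semiovale 0.70); the remaining regions use
the literature short:long split of ~60:40.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RegionReference",
    "REGION_REFERENCE",
    "DEFAULT_REGIONS",
    "BetweenSubjectSpread",
    "TissueSpec",
    "PhantomSpec",
    "SubjectProfile",
    "default_tissue_specs",
    "ECF_REFERENCE_MM",
]

#: Extracellular sodium reference concentration (mM); EcF = Na_LF / this.
ECF_REFERENCE_MM: float = 140.0

#: Default signal units generated per millimolar of sodium (simulation choice).
DEFAULT_SIGNAL_PER_MM: float = 2.0


@dataclass(frozen=True)
class RegionReference:
    """Cohort mean and s.d. of each quantified metric for one ROI."""

    t2s: float
    t2s_sd: float
    t2l: float
    t2l_sd: float
    na_sf: float
    na_sf_sd: float
    na_lf: float
    na_lf_sd: float
    tsc: float
    tsc_sd: float
    ecf: float
    ecf_sd: float
    f: float
    f_sd: float


# mean/sd per region: T2*short (ms), T2*long (ms), Na_SF (mM), Na_LF (mM),
# TSC (mM), EcF (-), then the short signal fraction f.
REGION_REFERENCE: dict[str, RegionReference] = {
    "GM": RegionReference(4.99, 0.41, 31.51, 1.78, 21.16, 0.87, 25.75, 2.97,
                          46.92, 2.83, 0.18, 0.02, 0.46, 0.03),
    "WM": RegionReference(4.44, 0.34, 38.25, 2.45, 22.28, 0.97, 15.87, 1.49,
                          38.15, 1.97, 0.11, 0.01, 0.60, 0.07),
    "thalamus": RegionReference(3.70, 0.41, 40.13, 7.50, 24.28, 1.66, 16.02, 2.85,
                                40.30, 2.33, 0.11, 0.02, 0.60, 0.07),
    "putamen": RegionReference(3.72, 0.61, 32.66, 7.00, 23.04, 2.82, 13.25, 3.19,
                               36.29, 1.76, 0.09, 0.02, 0.60, 0.07),
    "pallidum": RegionReference(2.82, 0.44, 31.62, 6.87, 21.99, 2.08, 11.25, 2.62,
                                33.24, 2.62, 0.08, 0.02, 0.60, 0.07),
    "caudate": RegionReference(4.00, 0.61, 34.79, 6.37, 19.26, 2.10, 17.80, 2.95,
                               37.06, 2.09, 0.13, 0.02, 0.52, 0.06),
    "corpus_callosum": RegionReference(3.48, 0.42, 39.82, 9.16, 19.57, 3.30,
                                       15.96, 4.87, 35.52, 3.35, 0.11, 0.03,
                                       0.60, 0.07),
    "cerebellar_WM": RegionReference(3.57, 0.81, 35.51, 7.26, 16.29, 2.34,
                                     12.31, 2.35, 28.60, 2.88, 0.09, 0.02,
                                     0.60, 0.07),
    "centrum_semiovale": RegionReference(4.37, 0.43, 54.74, 14.98, 23.93, 2.83,
                                         8.46, 1.68, 32.39, 2.74, 0.06, 0.01,
                                         0.70, 0.04),
    "pons": RegionReference(2.43, 0.58, 31.52, 11.45, 13.19, 3.68, 11.99, 3.53,
                            25.18, 3.17, 0.09, 0.03, 0.52, 0.10),
}

DEFAULT_REGIONS: tuple[str, ...] = tuple(REGION_REFERENCE)


@dataclass(frozen=True)
class BetweenSubjectSpread:
    """Per-parameter between-subject variation.

    Coefficients of variation apply multiplicatively (log-normal) to the
    amplitude and both time constants; ``f_sd`` is the natural-scale s.d.
    of the short fraction, applied additively on the logit scale so draws
    stay inside (0, 1).
    """

    amplitude_cv: float = 0.0
    f_sd: float = 0.0
    t2s_cv: float = 0.0
    t2l_cv: float = 0.0

    def __post_init__(self) -> None:
        for name in ("amplitude_cv", "f_sd", "t2s_cv", "t2l_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def scaled(self, factor: float) -> "BetweenSubjectSpread":
        return BetweenSubjectSpread(
            self.amplitude_cv * factor,
            self.f_sd * factor,
            self.t2s_cv * factor,
            self.t2l_cv * factor,
        )


@dataclass(frozen=True)
class TissueSpec:
    """Generating parameters of one brain region's decay curve."""

    region_name: str
    amplitude_A: float
    short_fraction_f: float
    t2star_short: float
    t2star_long: float
    between_subject_sd: BetweenSubjectSpread = field(
        default_factory=BetweenSubjectSpread
    )

    def __post_init__(self) -> None:
        if self.amplitude_A <= 0:
            raise ValueError("amplitude_A must be positive")
        if not 0.0 <= self.short_fraction_f <= 1.0:
            raise ValueError("short_fraction_f must lie in [0, 1]")
        if not 0.0 < self.t2star_short < self.t2star_long:
            raise ValueError("require 0 < t2star_short < t2star_long")


@dataclass(frozen=True)
class PhantomSpec:
    """Reference-tube phantom: agar gels of known sodium concentration.

    Tube t's noiseless signal is ``(signal_per_mM * C_t + intercept) *
    exp(-TE / tube_t2star_t)``. Agar tubes relax monoexponentially; the
    default single time constant of 12 ms is a simulation choice.
    """

    tube_concentrations: tuple[float, ...] = (10.0, 23.0, 36.0, 49.0, 62.0, 75.0)
    tube_t2star: tuple[float, ...] | float = 12.0
    signal_per_mM: float = DEFAULT_SIGNAL_PER_MM
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if len(self.tube_concentrations) < 2:
            raise ValueError("need at least two reference tubes")
        if len(set(self.tube_concentrations)) != len(self.tube_concentrations):
            raise ValueError("tube concentrations must be distinct")
        if any(c <= 0 for c in self.tube_concentrations):
            raise ValueError("tube concentrations must be positive")
        if self.signal_per_mM <= 0:
            raise ValueError("signal_per_mM must be positive")
        t2 = self.t2stars
        if len(t2) != len(self.tube_concentrations):
            raise ValueError("tube_t2star must be scalar or one value per tube")
        if any(t <= 0 for t in t2):
            raise ValueError("tube T2* values must be positive")

    @property
    def t2stars(self) -> tuple[float, ...]:
        if np.ndim(self.tube_t2star) == 0:
            return (float(self.tube_t2star),) * len(self.tube_concentrations)
        return tuple(float(t) for t in self.tube_t2star)

    @property
    def n_tubes(self) -> int:
        return len(self.tube_concentrations)

    def m0(self, concentration: float) -> float:
        """Noiseless TE=0 magnetization for a given concentration (mM)."""
        return self.signal_per_mM * concentration + self.intercept


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    sex: str
    age: float

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")
        if self.age <= 0:
            raise ValueError("age must be positive")


def default_tissue_specs(
    regions: tuple[str, ...] | list[str] = DEFAULT_REGIONS,
    signal_per_mM: float = DEFAULT_SIGNAL_PER_MM,
    intercept: float = 0.0,
) -> dict[str, TissueSpec]:
    """Build TissueSpecs anchored to the cohort reference table.

    The amplitude of each region is set so that, through the default
    calibration line, the region's total sodium concentration matches its
    reference TSC: ``A = signal_per_mM * TSC + 2 * intercept`` (each of the
    two magnetization fractions picks up one intercept on inversion).
    """
    specs: dict[str, TissueSpec] = {}
    for name in regions:
        try:
            ref = REGION_REFERENCE[name]
        except KeyError:
            raise KeyError(
                f"unknown region {name!r}; choose from {sorted(REGION_REFERENCE)}"
            ) from None
        spread = BetweenSubjectSpread(
            amplitude_cv=ref.tsc_sd / ref.tsc,
            f_sd=ref.f_sd,
            t2s_cv=ref.t2s_sd / ref.t2s,
            t2l_cv=ref.t2l_sd / ref.t2l,
        )
        specs[name] = TissueSpec(
            region_name=name,
            amplitude_A=signal_per_mM * ref.tsc + 2.0 * intercept,
            short_fraction_f=ref.f,
            t2star_short=ref.t2s,
            t2star_long=ref.t2l,
            between_subject_sd=spread,
        )
    return specs
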