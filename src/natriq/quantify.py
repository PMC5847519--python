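"""Phantom calibration and tissue sodium quantification.

The reference tubes' TE->0 magnetizations (M0, from monoexponential fits)
are regressed on their known concentrations, giving a linear signal-to-
concentration map. In-vivo magnetizations of the short and long fractions
(M0_SF = A*f, M0_LF = A*(1-f)) are pushed through the inverse map to give
Na_SF and Na_LF in mM; the total sodium concentration is their sum and the
extracellular fraction is Na_LF relative to the 140 mM extracellular
reference. Using M0 rather than any finite-TE signal makes the map immune
to relaxation differences between agar tubes and tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import BiexpParams, FitResult
from .specs import ECF_REFERENCE_MM

__all__ = [
    "CalibrationModel",
    "RoiQuantification",
    "fit_calibration",
    "to_concentration",
    "quantify_roi",
    "quantification_frame",
    "summarize_cohort",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Linear map M0 = slope * concentration + intercept."""

    slope: float
    intercept: float
    fit_r_squared: float
    n_tubes: int
    with_intercept: bool = True

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if self.n_tubes < 2:
            raise ValueError("calibration requires at least two tubes")


def fit_calibration(
    tube_m0, tube_concentrations, include_intercept: bool = True
) -> CalibrationModel:
    """Ordinary least squares of tube M0 against known concentration (mM).

    ``include_intercept=False`` forces the line through the origin
    (sensitivity-analysis mode).
    """
    m0 = np.asarray(tube_m0, dtype=float)
    conc = np.asarray(tube_concentrations, dtype=float)
    if m0.shape != conc.shape or m0.ndim != 1:
        raise ValueError("tube_m0 and tube_concentrations must be 1-D, equal length")
    if m0.size < 2:
        raise ValueError("need at least two tubes")
    if np.unique(conc).size < 2:
        raise ValueError("tube concentrations must not all be equal")
    if include_intercept:
        res = sps.linregress(conc, m0)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    else:
        slope = float(conc @ m0 / (conc @ conc))
        intercept = 0.0
        fitted = slope * conc
        ss_tot = float(np.sum((m0 - m0.mean()) ** 2))
        r2 = 1.0 - float(np.sum((m0 - fitted) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return CalibrationModel(
        slope=slope,
        intercept=intercept,
        fit_r_squared=r2,
        n_tubes=int(m0.size),
        with_intercept=include_intercept,
    )


def to_concentration(m0, model: CalibrationModel):
    """Invert the calibration line: (m0 - intercept) / slope, in mM.

    Negative results (m0 below the intercept) are returned as-is with a
    ``RuntimeWarning`` so callers can flag rather than silently clip them.
    """
    conc = (np.asarray(m0, dtype=float) - model.intercept) / model.slope
    if np.any(conc < 0):
        warnings.warn(
            "magnetization below calibration intercept: negative concentration",
            RuntimeWarning,
            stacklevel=2,
        )
    return conc if np.ndim(m0) else float(conc)


@dataclass(frozen=True)
class RoiQuantification:
    """Quantified sodium metrics of one subject x ROI.

    Identities hold exactly by construction: ``tsc = na_sf + na_lf`` and
    ``ecf = na_lf / ecf_reference``.
    """

    subject_id: str
    roi: str
    na_sf: float
    na_lf: float
    tsc: float
    ecf: float
    t2star_short: float
    t2star_long: float
    short_fraction_f: float
    r_squared: float
    ecf_reference: float = ECF_REFERENCE_MM
    flags: tuple[str, ...] = field(default=())


def quantify_roi(
    fit: FitResult,
    model: CalibrationModel,
    subject_id: str = "",
    roi: str = "",
    ecf_reference: float = ECF_REFERENCE_MM,
    force: bool = False,
) -> RoiQuantification:
    """Map a converged biexponential ROI fit to concentrations.

    Degenerate or non-converged fits are rejected unless ``force=True``
    (the result is then flagged). Negative concentrations are flagged,
    never clipped.
    """
    if not isinstance(fit.params, BiexpParams):
        raise TypeError("quantify_roi requires a biexponential fit")
    flags: list[str] = []
    if not fit.converged:
        if not force:
            raise ValueError("fit did not converge; pass force=True to override")
        flags.append("non_converged")
    if fit.degenerate:
        if not force:
            raise ValueError("degenerate fit; pass force=True to override")
        flags.append("degenerate")
    p = fit.params
    mag = _magnetizations(fit)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        na_sf = to_concentration(mag[0], model)
        na_lf = to_concentration(mag[1], model)
    if na_sf < 0:
        flags.append("negative_na_sf")
    if na_lf < 0:
        flags.append("negative_na_lf")
    return RoiQuantification(
        subject_id=subject_id,
        roi=roi,
        na_sf=na_sf,
        na_lf=na_lf,
        tsc=na_sf + na_lf,
        ecf=na_lf / ecf_reference,
        t2star_short=p.t2star_short,
        t2star_long=p.t2star_long,
        short_fraction_f=p.short_fraction_f,
        r_squared=fit.r_squared,
        ecf_reference=ecf_reference,
        flags=tuple(flags),
    )


def _magnetizations(fit: FitResult) -> tuple[float, float]:
    """(M0_SF, M0_LF) without the convergence gate (caller handles flags)."""
    p = fit.params
    return (
        p.amplitude_A * p.short_fraction_f,
        p.amplitude_A * (1.0 - p.short_fraction_f),
    )


def quantification_frame(records: list[RoiQuantification]) -> pd.DataFrame:
    """Per-subject-per-ROI table with the standard column layout."""
    return pd.DataFrame(
        [
            (
                r.subject_id, r.roi, r.t2star_short, r.t2star_long,
                r.short_fraction_f, r.r_squared, r.na_sf, r.na_lf, r.tsc,
                r.ecf, ";".join(r.flags),
            )
            for r in records
        ],
        columns=[
            "subject_id", "roi", "t2s_ms", "t2l_ms", "f", "r2",
            "na_sf_mM", "na_lf_mM", "tsc_mM", "ecf", "flags",
        ],
    )


def summarize_cohort(frame: pd.DataFrame, decimals: int | None = None) -> pd.DataFrame:
    """Cohort summary: mean and s.d. of each metric per ROI.

    Internal arithmetic stays full precision; pass ``decimals`` to round at
    presentation time only.
    """
    metrics = ["t2s_ms", "t2l_ms", "f", "r2", "na_sf_mM", "na_lf_mM", "tsc_mM", "ecf"]
    grouped = frame.groupby("roi", sort=False)[metrics]
    out = grouped.agg(["mean", "std"])
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    out = out.reset_index()
    if decimals is not None:
        num = out.select_dtypes(include="number").columns
        out[num] = out[num].round(decimals)
    return out
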