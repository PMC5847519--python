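"""Synthetic multi-echo sodium MRI cohort generator.

Emulates the study conditions the analysis pipeline assumes: a 13-subject
cohort (5 female, ages 20-32) scanned with the 24-echo three-run schedule,
ten brain ROIs decaying biexponentially with region-specific parameters,
six agar reference tubes (10-75 mM) decaying monoexponentially, Rician
magnitude noise, and log-normal/logit-normal between-subject parameter
variation. Every curve carries its generating truth, so parameter-recovery
and end-to-end quantification tests need no external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import DecayCurve
from .schedule import AcquisitionSchedule, make_schedule
from .specs import (
    DEFAULT_REGIONS,
    PhantomSpec,
    SubjectProfile,
    TissueSpec,
    default_tissue_specs,
)

__all__ = [
    "rician_sample",
    "simulate_roi_curve",
    "simulate_phantom",
    "simulate_cohort",
    "make_subjects",
    "CohortConfig",
    "CohortDataset",
]


def rician_sample(true_signal, sigma: float, rng: np.random.Generator):
    """Draw Rician-distributed magnitude samples around ``true_signal``.

    The magnitude of a complex Gaussian measurement: with independent
    zero-mean Gaussian noise n1, n2 of s.d. ``sigma`` on the two channels,
    returns sqrt((S + n1)^2 + n2^2). ``sigma=0`` returns S unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    s = np.asarray(true_signal, dtype=float)
    if sigma == 0:
        out = s.copy()
    else:
        n1 = rng.normal(0.0, sigma, size=s.shape)
        n2 = rng.normal(0.0, sigma, size=s.shape)
        out = np.hypot(s + n1, n2)
    return out if np.ndim(true_signal) else float(out)


def simulate_roi_curve(
    spec: TissueSpec,
    schedule: AcquisitionSchedule,
    sigma: float,
    rng: np.random.Generator,
    source_id: str = "",
) -> DecayCurve:
    """Simulate one ROI-mean decay curve under Rician noise.

    Noiseless mean: ``A (f e^{-TE/T2*s} + (1-f) e^{-TE/T2*l})`` at each
    scheduled echo time; each sample is then Rician-corrupted with noise
    s.d. ``sigma``. Generating parameters are attached as ``meta['truth']``.
    """
    te = np.asarray(schedule.echo_times, dtype=float)
    clean = spec.amplitude_A * (
        spec.short_fraction_f * np.exp(-te / spec.t2star_short)
        + (1.0 - spec.short_fraction_f) * np.exp(-te / spec.t2star_long)
    )
    signals = rician_sample(clean, sigma, rng)
    truth = {
        "amplitude_A": spec.amplitude_A,
        "short_fraction_f": spec.short_fraction_f,
        "t2star_short": spec.t2star_short,
        "t2star_long": spec.t2star_long,
        "sigma": float(sigma),
        "region": spec.region_name,
    }
    return DecayCurve(
        te,
        signals,
        source_id=source_id or spec.region_name,
        run_labels=np.asarray(schedule.run_labels),
        meta={"truth": truth},
    )


def simulate_phantom(
    spec: PhantomSpec,
    schedule: AcquisitionSchedule,
    sigma: float,
    rng: np.random.Generator,
    id_prefix: str = "tube",
) -> dict[str, DecayCurve]:
    """Simulate the reference-tube curves of one exam.

    Tube t decays monoexponentially from ``M0_t = signal_per_mM * C_t +
    intercept`` with its own T2*; samples are Rician-corrupted.
    """
    te = np.asarray(schedule.echo_times, dtype=float)
    curves: dict[str, DecayCurve] = {}
    for i, (conc, t2) in enumerate(
        zip(spec.tube_concentrations, spec.t2stars), start=1
    ):
        m0 = spec.m0(conc)
        clean = m0 * np.exp(-te / t2)
        tube_id = f"{id_prefix}-{i:02d}"
        curves[tube_id] = DecayCurve(
            te,
            rician_sample(clean, sigma, rng),
            source_id=tube_id,
            run_labels=np.asarray(schedule.run_labels),
            meta={
                "truth": {
                    "concentration_mM": float(conc),
                    "m0": float(m0),
                    "t2star": float(t2),
                    "sigma": float(sigma),
                }
            },
        )
    return curves


def make_subjects(
    n_subjects: int,
    n_female: int,
    age_range: tuple[float, float],
    rng: np.random.Generator,
) -> list[SubjectProfile]:
    """Draw a cohort roster: sexes assigned at random, integer ages uniform."""
    if not 0 <= n_female <= n_subjects:
        raise ValueError("n_female must lie in [0, n_subjects]")
    lo, hi = age_range
    if lo > hi or lo <= 0:
        raise ValueError("invalid age range")
    sexes = np.array(["male"] * n_subjects, dtype=object)
    sexes[rng.choice(n_subjects, size=n_female, replace=False)] = "female"
    ages = rng.integers(int(lo), int(hi) + 1, size=n_subjects)
    return [
        SubjectProfile(f"sub-{i + 1:02d}", str(sexes[i]), float(ages[i]))
        for i in range(n_subjects)
    ]


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of a simulated cohort.

    ``snr`` sets the noise level relative to each curve's own TE=0
    amplitude (sigma = amplitude / snr); pass ``sigma`` instead for an
    absolute noise level in signal units. ``spread_scale`` multiplies the
    between-subject spreads (0 disables subject variation).
    """

    seed: int
    n_subjects: int = 13
    n_female: int = 5
    age_range: tuple[float, float] = (20.0, 32.0)
    regions: tuple[str, ...] = DEFAULT_REGIONS
    schedule: str = "default-24"
    snr: float | None = 20.0
    sigma: float | None = None
    spread_scale: float = 1.0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    calibration_mode: str = "per_subject"  # or "pooled"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.snr is None and self.sigma is None:
            raise ValueError("set either snr or sigma")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.sigma is not None and self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.spread_scale < 0:
            raise ValueError("spread_scale must be non-negative")
        if self.calibration_mode not in ("per_subject", "pooled"):
            raise ValueError("calibration_mode must be 'per_subject' or 'pooled'")
        if len(self.regions) == 0 or len(set(self.regions)) != len(self.regions):
            raise ValueError("regions must be a non-empty list of unique names")

    def noise_sigma(self, amplitude: float) -> float:
        if self.sigma is not None:
            return float(self.sigma)
        return float(amplitude) / float(self.snr)


@dataclass
class CohortDataset:
    """A simulated cohort: ROI curves, phantom curves, and their truths.

    ``curves`` is keyed by ``(subject_id, region)``; ``phantom_curves`` by
    ``(subject_id, tube_id)`` (calibration tubes are imaged in every exam;
    in pooled mode the single exam uses subject id ``"pooled"``).
    """

    subjects: list[SubjectProfile]
    curves: dict[tuple[str, str], DecayCurve]
    phantom_curves: dict[tuple[str, str], DecayCurve]
    truth: dict[str, dict]
    schedule: AcquisitionSchedule
    config: CohortConfig
    seed: int

    def curves_frame(self) -> pd.DataFrame:
        """Tidy ROI table: (subject_id, roi, run, te_ms, signal)."""
        rows = []
        for (sid, region), curve in self.curves.items():
            runs = curve.run_labels
            for k in range(len(curve)):
                rows.append(
                    (sid, region, int(runs[k]) if runs is not None else 1,
                     curve.echo_times[k], curve.signals[k])
                )
        return pd.DataFrame(
            rows, columns=["subject_id", "roi", "run", "te_ms", "signal"]
        )

    def phantom_frame(self) -> pd.DataFrame:
        """Tidy tube table: (subject_id, tube_id, concentration_mM, run, te_ms, signal)."""
        rows = []
        for (sid, tube), curve in self.phantom_curves.items():
            conc = curve.meta["truth"]["concentration_mM"]
            runs = curve.run_labels
            for k in range(len(curve)):
                rows.append(
                    (sid, tube, conc, int(runs[k]) if runs is not None else 1,
                     curve.echo_times[k], curve.signals[k])
                )
        return pd.DataFrame(
            rows,
            columns=["subject_id", "tube_id", "concentration_mM", "run",
                     "te_ms", "signal"],
        )

    def subjects_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.subject_id, s.sex, s.age) for s in self.subjects],
            columns=["subject_id", "sex", "age"],
        )

    def write(self, outdir: str | Path) -> None:
        """Write curves/phantom/subjects as CSV and truth as JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.curves_frame().to_csv(outdir / "curves.csv", index=False)
        self.phantom_frame().to_csv(outdir / "phantom_curves.csv", index=False)
        self.subjects_frame().to_csv(outdir / "subjects.csv", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump({"seed": self.seed, "truth": self.truth}, fh, indent=1)


def _draw_subject_spec(
    spec: TissueSpec, scale: float, rng: np.random.Generator
) -> TissueSpec:
    """Perturb a region spec for one subject, respecting parameter domains."""
    sp = spec.between_subject_sd.scaled(scale)
    a = spec.amplitude_A
    if sp.amplitude_cv > 0:
        a *= np.exp(rng.normal(0.0, np.log1p(sp.amplitude_cv)))
    f = spec.short_fraction_f
    if sp.f_sd > 0 and 0.0 < f < 1.0:
        # delta-method logit-scale sd reproduces the natural-scale sd
        logit_sd = sp.f_sd / (f * (1.0 - f))
        z = np.log(f / (1.0 - f)) + rng.normal(0.0, logit_sd)
        f = 1.0 / (1.0 + np.exp(-z))
    t2s = spec.t2star_short
    t2l = spec.t2star_long
    if sp.t2s_cv > 0:
        t2s *= np.exp(rng.normal(0.0, np.log1p(sp.t2s_cv)))
    if sp.t2l_cv > 0:
        t2l *= np.exp(rng.normal(0.0, np.log1p(sp.t2l_cv)))
    t2s = min(t2s, 0.99 * t2l)  # truncate to the ordering invariant
    return TissueSpec(
        region_name=spec.region_name,
        amplitude_A=float(a),
        short_fraction_f=float(f),
        t2star_short=float(t2s),
        t2star_long=float(t2l),
        between_subject_sd=spec.between_subject_sd,
    )


def simulate_cohort(
    config: CohortConfig,
    tissue_specs: dict[str, TissueSpec] | None = None,
) -> CohortDataset:
    """Simulate a complete cohort dataset, deterministic under the seed.

    Each subject's region parameters are drawn around the region means with
    the configured between-subject spread; every (subject, region) pair gets
    one Rician-noisy curve and every exam gets a set of reference tubes.
    """
    rng = np.random.default_rng(config.seed)
    schedule = make_schedule(config.schedule)
    specs = tissue_specs or default_tissue_specs(
        config.regions,
        signal_per_mM=config.phantom.signal_per_mM,
        intercept=config.phantom.intercept,
    )
    missing = [r for r in config.regions if r not in specs]
    if missing:
        raise ValueError(f"no tissue spec for regions: {missing}")

    subjects = make_subjects(
        config.n_subjects, config.n_female, config.age_range, rng
    )
    curves: dict[tuple[str, str], DecayCurve] = {}
    phantom_curves: dict[tuple[str, str], DecayCurve] = {}
    truth: dict[str, dict] = {}

    phantom_sigma_ref = config.noise_sigma(
        float(np.mean([config.phantom.m0(c) for c in config.phantom.tube_concentrations]))
    )
    if config.calibration_mode == "pooled":
        for tube_id, curve in simulate_phantom(
            config.phantom, schedule, phantom_sigma_ref, rng
        ).items():
            phantom_curves[("pooled", tube_id)] = curve
            truth[f"pooled/{tube_id}"] = curve.meta["truth"]

    for subject in subjects:
        sid = subject.subject_id
        if config.calibration_mode == "per_subject":
            for tube_id, curve in simulate_phantom(
                config.phantom, schedule, phantom_sigma_ref, rng
            ).items():
                phantom_curves[(sid, tube_id)] = curve
                truth[f"{sid}/{tube_id}"] = curve.meta["truth"]
        for region in config.regions:
            subj_spec = _draw_subject_spec(specs[region], config.spread_scale, rng)
            sigma = config.noise_sigma(subj_spec.amplitude_A)
            curve = simulate_roi_curve(
                subj_spec, schedule, sigma, rng, source_id=f"{sid}/{region}"
            )
            # concentrations implied by the phantom calibration line
            t = curve.meta["truth"]
            slope = config.phantom.signal_per_mM
            icpt = config.phantom.intercept
            t["na_sf"] = (subj_spec.amplitude_A * subj_spec.short_fraction_f - icpt) / slope
            t["na_lf"] = (subj_spec.amplitude_A * (1 - subj_spec.short_fraction_f) - icpt) / slope
            t["tsc"] = t["na_sf"] + t["na_lf"]
            curves[(sid, region)] = curve
            truth[f"{sid}/{region}"] = t

    return CohortDataset(
        subjects=subjects,
        curves=curves,
        phantom_curves=phantom_curves,
        truth=truth,
        schedule=schedule,
        config=config,
        seed=config.seed,
    )
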