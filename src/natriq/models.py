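"""Signal models and nonlinear least-squares fitting for sodium T2* decay.

The in-vivo sodium signal of a brain ROI decays biexponentially: a short
T2* component (weight ``f``, time constant ``t2star_short``) from sodium in
restricted environments, and a long component (weight ``1 - f``,
``t2star_long``). Because magnitude images carry Rician noise, the measured
signal does not decay to zero but to a noise floor, modelled by the ``ric``
parameter:

    S(TE) = sqrt( [A (f e^{-TE/T2*s} + (1-f) e^{-TE/T2*l})]^2 + Ric^2 )

Reference tubes are single-compartment agar gels and are fitted with the
monoexponential analogue. Fits are bounded, multi-start Levenberg/TRF
least squares; the biexponential solution is relabelled so that
``t2star_short <= t2star_long`` always holds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from typing import Union

import numpy as np
from scipy.optimize import least_squares

from .curves import DecayCurve

__all__ = [
    "BiexpParams",
    "MonoexpParams",
    "FitOptions",
    "FitResult",
    "MagnetizationPair",
    "biexp_signal",
    "monoexp_signal",
    "fit_biexp",
    "fit_monoexp",
    "magnetization_fractions",
    "r_squared",
]


@dataclass(frozen=True)
class BiexpParams:
    """Biexponential decay parameters.

    amplitude_A : TE=0 signal amplitude (arbitrary units), > 0
    short_fraction_f : weight of the short-T2* component, in [0, 1]
    t2star_short, t2star_long : time constants (ms), 0 < short <= long
    ric : Rician noise-floor scaling (arbitrary units), >= 0
    """

    amplitude_A: float
    short_fraction_f: float
    t2star_short: float
    t2star_long: float
    ric: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_A < 0:
            raise ValueError("amplitude_A must be non-negative")
        if not 0.0 <= self.short_fraction_f <= 1.0:
            raise ValueError("short_fraction_f must lie in [0, 1]")
        if not 0.0 < self.t2star_short <= self.t2star_long:
            raise ValueError("require 0 < t2star_short <= t2star_long")
        if self.ric < 0:
            raise ValueError("ric must be non-negative")


@dataclass(frozen=True)
class MonoexpParams:
    """Monoexponential decay parameters (reference tubes)."""

    m0: float
    t2star: float
    ric: float = 0.0

    def __post_init__(self) -> None:
        if self.m0 <= 0:
            raise ValueError("m0 must be positive")
        if self.t2star <= 0:
            raise ValueError("t2star must be positive")
        if self.ric < 0:
            raise ValueError("ric must be non-negative")


@dataclass(frozen=True)
class MagnetizationPair:
    """TE->0 magnetizations of the short and long fractions.

    By construction ``m0_sf + m0_lf`` equals the amplitude A of the fit the
    pair was derived from: m0_sf = A*f, m0_lf = A*(1-f).
    """

    m0_sf: float
    m0_lf: float


@dataclass(frozen=True)
class FitOptions:
    """Solver configuration shared by biexponential and tube fits.

    Bounds bracket the published range of brain sodium relaxation values
    (T2*_short well under 15 ms, T2*_long up to CSF-like ~50-65 ms).
    The multi-start grid covers both components' plausible basins; the best
    sum of squared errors wins, ties broken by the smaller t2star_long.
    """

    t2s_bounds: tuple[float, float] = (0.2, 15.0)
    t2l_bounds: tuple[float, float] = (10.0, 150.0)
    f_starts: tuple[float, ...] = (0.4, 0.6, 0.8)
    t2s_starts: tuple[float, ...] = (2.0, 5.0)
    t2l_starts: tuple[float, ...] = (25.0, 45.0)
    ftol: float = 1e-10
    max_nfev: int = 2000
    fit_ric: bool = True
    degenerate_f_tol: float = 1e-3
    degenerate_ratio: float = 1.5
    # tube-fit bounds
    tube_t2_bounds: tuple[float, float] = (0.2, 200.0)


_DEFAULT_OPTIONS = FitOptions()


@dataclass
class FitResult:
    """Outcome of one curve fit, with goodness-of-fit diagnostics.

    ``degenerate`` marks collapsed biexponential solutions: the short
    fraction pinned at 0 or 1, or the two time constants too close to be
    distinguishable (ratio below ``FitOptions.degenerate_ratio``).
    """

    params: Union[BiexpParams, MonoexpParams]
    r_squared: float
    residual_sum_squares: float
    converged: bool
    degenerate: bool = False
    n_starts_used: int = 1
    source_id: str = ""
    options: FitOptions = field(default_factory=FitOptions)

    @property
    def model(self) -> str:
        return "biexp" if isinstance(self.params, BiexpParams) else "monoexp"

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "source_id": self.source_id,
            "r_squared": self.r_squared,
            "residual_sum_squares": self.residual_sum_squares,
            "converged": self.converged,
            "degenerate": self.degenerate,
            "n_starts_used": self.n_starts_used,
            "params": asdict(self.params),
            "options": asdict(self.options),
        }
        return d


def fit_result_from_dict(d: dict) -> FitResult:
    """Rebuild a :class:`FitResult` from its JSON record."""
    p = d["params"]
    if d["model"] == "biexp":
        params: Union[BiexpParams, MonoexpParams] = BiexpParams(**p)
    else:
        params = MonoexpParams(**p)
    opts = d.get("options", {})
    for key in ("t2s_bounds", "t2l_bounds", "f_starts", "t2s_starts",
                "t2l_starts", "tube_t2_bounds"):
        if key in opts:
            opts[key] = tuple(opts[key])
    return FitResult(
        params=params,
        r_squared=d["r_squared"],
        residual_sum_squares=d["residual_sum_squares"],
        converged=d["converged"],
        degenerate=d["degenerate"],
        n_starts_used=d.get("n_starts_used", 1),
        source_id=d.get("source_id", ""),
        options=FitOptions(**opts) if opts else FitOptions(),
    )


def _check_te(te: np.ndarray) -> np.ndarray:
    te = np.asarray(te, dtype=float)
    if np.any(te < 0):
        raise ValueError("echo times cannot be negative")
    return te


def biexp_signal(params: BiexpParams, te) -> np.ndarray | float:
    """Magnitude signal of the Rician-floored biexponential model at ``te`` (ms)."""
    te_arr = _check_te(te)
    clean = params.amplitude_A * (
        params.short_fraction_f * np.exp(-te_arr / params.t2star_short)
        + (1.0 - params.short_fraction_f) * np.exp(-te_arr / params.t2star_long)
    )
    out = np.sqrt(clean**2 + params.ric**2)
    return out if np.ndim(te) else float(out)


def monoexp_signal(params: MonoexpParams, te) -> np.ndarray | float:
    """Magnitude signal of the Rician-floored monoexponential model at ``te`` (ms)."""
    te_arr = _check_te(te)
    clean = params.m0 * np.exp(-te_arr / params.t2star)
    out = np.sqrt(clean**2 + params.ric**2)
    return out if np.ndim(te) else float(out)


def r_squared(observed, fitted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot on the raw signals."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(fitted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("observed and fitted must be 1-D of equal length")
    if y.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed signal is constant; r^2 undefined")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# fitting internals

def _biexp_model_and_jac(theta: np.ndarray, te: np.ndarray):
    a, f, t2s, t2l, ric = theta
    e1 = np.exp(-te / t2s)
    e2 = np.exp(-te / t2l)
    g = f * e1 + (1.0 - f) * e2
    clean = a * g
    m = np.sqrt(clean**2 + ric**2)
    m_safe = np.where(m > 0, m, 1.0)
    jac = np.empty((te.size, 5))
    jac[:, 0] = clean * g / m_safe
    jac[:, 1] = clean * a * (e1 - e2) / m_safe
    jac[:, 2] = clean * a * f * e1 * te / (t2s**2 * m_safe)
    jac[:, 3] = clean * a * (1.0 - f) * e2 * te / (t2l**2 * m_safe)
    jac[:, 4] = np.where(m > 0, ric / m_safe, 0.0)
    return m, jac


def _mono_model_and_jac(theta: np.ndarray, te: np.ndarray, fit_ric: bool):
    if fit_ric:
        m0, t2, ric = theta
    else:
        m0, t2 = theta
        ric = 0.0
    clean = m0 * np.exp(-te / t2)
    m = np.sqrt(clean**2 + ric**2)
    m_safe = np.where(m > 0, m, 1.0)
    jac = np.empty((te.size, theta.size))
    jac[:, 0] = clean * np.exp(-te / t2) / m_safe
    jac[:, 1] = clean * clean * te / (t2**2 * m_safe)
    if fit_ric:
        jac[:, 2] = np.where(m > 0, ric / m_safe, 0.0)
    return m, jac


def _run_starts(residual, jacobian, starts, lower, upper, options: FitOptions):
    """Run bounded least squares from each start; return (best, n_ok)."""
    best = None
    n_ok = 0
    for x0 in starts:
        x0 = np.clip(x0, lower, upper)
        try:
            sol = least_squares(
                residual,
                x0,
                jac=jacobian,
                bounds=(lower, upper),
                method="trf",
                ftol=options.ftol,
                xtol=1e-12,
                gtol=1e-12,
                max_nfev=options.max_nfev,
            )
        except Exception:
            continue
        n_ok += 1
        if best is None or _better(sol, best):
            best = sol
    return best, n_ok


def _better(sol, incumbent) -> bool:
    tied = abs(sol.cost - incumbent.cost) <= 1e-9 * max(incumbent.cost, 1e-30)
    if tied and sol.x.size == 5:
        # tie on SSE: prefer the smaller long time constant
        return sol.x[3] < incumbent.x[3]
    return sol.cost < incumbent.cost


def fit_biexp(curve: DecayCurve, options: FitOptions | None = None) -> FitResult:
    """Fit the Rician-floored biexponential model to a decay curve.

    Requires at least 6 distinct echo times. Parameters are bounded
    (see :class:`FitOptions`); a grid of 12 starting points in
    (f, t2star_short, t2star_long) guards against local minima. The
    returned solution is canonical: ``t2star_short <= t2star_long``.
    """
    opts = options or _DEFAULT_OPTIONS
    if curve.n_distinct_echoes < 6:
        raise ValueError("biexponential fit requires >= 6 distinct echo times")
    te = curve.echo_times
    y = curve.signals
    smax = float(y.max())
    if smax <= 0:
        raise ValueError("all-zero signal cannot be fitted")
    smin = float(y.min())

    lower = np.array([1e-12, 0.0, opts.t2s_bounds[0], opts.t2l_bounds[0], 0.0])
    upper = np.array(
        [10.0 * smax, 1.0, opts.t2s_bounds[1], opts.t2l_bounds[1], smax]
    )

    def residual(theta):
        return _biexp_model_and_jac(theta, te)[0] - y

    def jacobian(theta):
        return _biexp_model_and_jac(theta, te)[1]

    starts = [
        np.array([smax, f0, t2s0, t2l0, smin])
        for f0, t2s0, t2l0 in itertools.product(
            opts.f_starts, opts.t2s_starts, opts.t2l_starts
        )
    ]
    best, n_ok = _run_starts(residual, jacobian, starts, lower, upper, opts)
    if best is None:
        raise RuntimeError("biexponential fit failed from every start")

    a, f, t2s, t2l, ric = best.x
    if t2s > t2l:  # canonical labelling
        t2s, t2l = t2l, t2s
        f = 1.0 - f
    params = BiexpParams(
        float(a), float(min(max(f, 0.0), 1.0)), float(t2s), float(t2l),
        float(max(ric, 0.0)),
    )
    fitted = biexp_signal(params, te)
    ssr = float(np.sum((y - fitted) ** 2))
    degenerate = (
        f <= opts.degenerate_f_tol
        or f >= 1.0 - opts.degenerate_f_tol
        or t2l / t2s < opts.degenerate_ratio
    )
    return FitResult(
        params=params,
        r_squared=r_squared(y, fitted),
        residual_sum_squares=ssr,
        converged=bool(best.status > 0) and n_ok > 0,
        degenerate=bool(degenerate),
        n_starts_used=n_ok,
        source_id=curve.source_id,
        options=opts,
    )


def fit_monoexp(curve: DecayCurve, options: FitOptions | None = None) -> FitResult:
    """Fit the (optionally Rician-floored) monoexponential model.

    Used for reference tubes; ``m0`` is the TE->0 extrapolation entering the
    concentration calibration. Requires >= 4 distinct echo times. Set
    ``FitOptions.fit_ric=False`` for a pure exponential.
    """
    opts = options or _DEFAULT_OPTIONS
    if curve.n_distinct_echoes < 4:
        raise ValueError("monoexponential fit requires >= 4 distinct echo times")
    te = curve.echo_times
    y = curve.signals
    smax = float(y.max())
    if smax <= 0:
        raise ValueError("all-zero signal cannot be fitted")
    smin = float(y.min())

    # log-linear slope over clearly positive samples seeds t2star
    pos = y > 0.05 * smax
    t2_guess = 12.0
    if pos.sum() >= 2:
        slope = np.polyfit(te[pos], np.log(y[pos]), 1)[0]
        if slope < 0:
            t2_guess = float(np.clip(-1.0 / slope, *opts.tube_t2_bounds))

    if opts.fit_ric:
        lower = np.array([1e-12, opts.tube_t2_bounds[0], 0.0])
        upper = np.array([10.0 * smax, opts.tube_t2_bounds[1], smax])
        starts = [
            np.array([smax, t2, smin]) for t2 in {t2_guess, 5.0, 12.0, 30.0}
        ]
    else:
        lower = np.array([1e-12, opts.tube_t2_bounds[0]])
        upper = np.array([10.0 * smax, opts.tube_t2_bounds[1]])
        starts = [np.array([smax, t2]) for t2 in {t2_guess, 5.0, 12.0, 30.0}]

    def residual(theta):
        return _mono_model_and_jac(theta, te, opts.fit_ric)[0] - y

    def jacobian(theta):
        return _mono_model_and_jac(theta, te, opts.fit_ric)[1]

    best, n_ok = _run_starts(residual, jacobian, starts, lower, upper, opts)
    if best is None:
        raise RuntimeError("monoexponential fit failed from every start")
    if opts.fit_ric:
        m0, t2, ric = best.x
    else:
        (m0, t2), ric = best.x, 0.0
    params = MonoexpParams(float(max(m0, 1e-12)), float(t2), float(max(ric, 0.0)))
    fitted = monoexp_signal(params, te)
    return FitResult(
        params=params,
        r_squared=r_squared(y, fitted),
        residual_sum_squares=float(np.sum((y - fitted) ** 2)),
        converged=bool(best.status > 0),
        degenerate=False,
        n_starts_used=n_ok,
        source_id=curve.source_id,
        options=opts,
    )


def magnetization_fractions(fit: FitResult) -> MagnetizationPair:
    """Split amplitude A into short/long magnetizations: A*f and A*(1-f)."""
    if not isinstance(fit.params, BiexpParams):
        raise TypeError("magnetization_fractions requires a biexponential fit")
    if not fit.converged:
        raise ValueError("fit did not converge; magnetizations unreliable")
    p = fit.params
    return MagnetizationPair(
        m0_sf=p.amplitude_A * p.short_fraction_f,
        m0_lf=p.amplitude_A * (1.0 - p.short_fraction_f),
    )
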