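import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from natriq.curves import DecayCurve
from natriq.models import (
    BiexpParams,
    FitOptions,
    MonoexpParams,
    biexp_signal,
    fit_biexp,
    fit_monoexp,
    magnetization_fractions,
    monoexp_signal,
    r_squared,
)


class TestSignalModels:
    @pytest.mark.parametrize(
        "params, te, expected",
        [
            # TE=0, no floor: amplitude
            (BiexpParams(100, 0.6, 5, 30, 0), 0.0, 100.0),
            # pure noise floor
            (BiexpParams(0.0, 0.6, 5, 30, 5), 50.0, 5.0),
            # hand evaluation: sqrt((100*(0.6 e^-2 + 0.4 e^-1/3))^2 + 16)
            (
                BiexpParams(100, 0.6, 5, 30, 4),
                10.0,
                math.sqrt(
                    (100 * (0.6 * math.exp(-2.0) + 0.4 * math.exp(-1 / 3.0))) ** 2
                    + 16.0
                ),
            ),
        ],
    )
    def test_biexp_values(self, params, te, expected):
        assert biexp_signal(params, te) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "params, te, expected",
        [
            (MonoexpParams(150, 12, 0), 12.0, 150.0 / math.e),
            (MonoexpParams(150, 12, 0), 0.0, 150.0),
            (MonoexpParams(150, 12, 3), 1e6, 3.0),
        ],
    )
    def test_monoexp_values(self, params, te, expected):
        assert monoexp_signal(params, te) == pytest.approx(expected, rel=1e-9)

    def test_negative_te_rejected(self):
        with pytest.raises(ValueError):
            biexp_signal(BiexpParams(1, 0.5, 2, 20, 0), -1.0)
        with pytest.raises(ValueError):
            monoexp_signal(MonoexpParams(1, 2, 0), -1.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        f=st.floats(0.0, 1.0),
        t2s=st.floats(0.5, 10.0),
        ratio=st.floats(2.0, 10.0),
        ric=st.floats(0.0, 10.0),
    )
    def test_decreasing_in_te_and_floor_limit(self, f, t2s, ratio, ric):
        params = BiexpParams(100.0, f, t2s, t2s * ratio, ric)
        te = np.linspace(0.0, 400.0, 200)
        sig = biexp_signal(params, te)
        assert np.all(np.diff(sig) <= 1e-12)
        if ric > 0:
            assert biexp_signal(params, 1e5) == pytest.approx(ric, rel=1e-6)


class TestRSquared:
    def test_perfect_null_and_hand_value(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == 1.0
        assert r_squared(y, np.full(3, y.mean())) == 0.0
        assert r_squared(y, np.array([1.0, 2.0, 4.0])) == pytest.approx(0.5)

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError):
            r_squared(np.ones(5), np.ones(5))


class TestBiexpFit:
    def test_noiseless_exact_recovery(self, noiseless_gm_curve, gm_params):
        fit = fit_biexp(noiseless_gm_curve)
        p = fit.params
        assert p.amplitude_A == pytest.approx(gm_params.amplitude_A, rel=1e-4)
        assert p.short_fraction_f == pytest.approx(gm_params.short_fraction_f, rel=1e-4)
        assert p.t2star_short == pytest.approx(gm_params.t2star_short, rel=1e-4)
        assert p.t2star_long == pytest.approx(gm_params.t2star_long, rel=1e-4)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit.converged and not fit.degenerate

    def test_canonical_labelling(self, te):
        # initial guesses put the "short" component on the long side; the
        # canonical solution must still have t2star_short <= t2star_long
        truth = BiexpParams(50.0, 0.3, 3.0, 40.0, 0.0)
        curve = DecayCurve(te, biexp_signal(truth, te))
        opts = FitOptions(f_starts=(0.7,), t2s_starts=(12.0,), t2l_starts=(12.0,))
        fit = fit_biexp(curve, opts)
        assert fit.params.t2star_short <= fit.params.t2star_long
        assert fit.params.t2star_short == pytest.approx(3.0, rel=1e-3)
        assert fit.params.short_fraction_f == pytest.approx(0.3, rel=1e-3)

    def test_monoexponential_curve_flagged_degenerate(self, te):
        mono = MonoexpParams(120.0, 12.0, 0.0)
        curve = DecayCurve(te, monoexp_signal(mono, te))
        fit = fit_biexp(curve)
        assert fit.degenerate

    def test_insufficient_echoes_rejected(self):
        curve = DecayCurve([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        with pytest.raises(ValueError):
            fit_biexp(curve)

    def test_noisy_gm_recovery_and_goodness(self, schedule, te, rng, gm_params):
        from natriq.simulate import rician_sample

        clean = biexp_signal(gm_params, te)
        sigma = gm_params.amplitude_A / 50.0
        t2s, r2s = [], []
        for _ in range(40):
            curve = DecayCurve(te, rician_sample(clean, sigma, rng))
            fit = fit_biexp(curve)
            t2s.append(fit.params.t2star_short)
            r2s.append(fit.r_squared)
        assert np.mean(t2s) == pytest.approx(gm_params.t2star_short, rel=0.10)
        assert np.mean(r2s) >= 0.95

    def test_recovery_error_shrinks_with_snr(self, te, gm_params, rng):
        from natriq.simulate import rician_sample

        clean = biexp_signal(gm_params, te)
        rmse = []
        for snr in (10, 25, 50, 100):
            errs = []
            for _ in range(25):
                curve = DecayCurve(
                    te, rician_sample(clean, gm_params.amplitude_A / snr, rng)
                )
                errs.append(
                    fit_biexp(curve).params.t2star_short - gm_params.t2star_short
                )
            rmse.append(float(np.sqrt(np.mean(np.square(errs)))))
        # monotone decrease within Monte-Carlo slack
        assert rmse[-1] < rmse[0]
        assert all(b <= a * 1.5 for a, b in zip(rmse, rmse[1:]))


class TestMonoexpFit:
    def test_noiseless_exact(self, te):
        truth = MonoexpParams(150.0, 12.0, 0.0)
        curve = DecayCurve(te, monoexp_signal(truth, te))
        fit = fit_monoexp(curve)
        assert fit.params.m0 == pytest.approx(150.0, rel=1e-6)
        assert fit.params.t2star == pytest.approx(12.0, rel=1e-6)

    def test_noisy_m0_bias_below_one_percent(self, te, rng):
        from natriq.simulate import rician_sample

        truth = MonoexpParams(150.0, 12.0, 0.0)
        clean = monoexp_signal(truth, te)
        m0s = [
            fit_monoexp(DecayCurve(te, rician_sample(clean, 1.5, rng))).params.m0
            for _ in range(100)
        ]
        assert abs(np.mean(m0s) / 150.0 - 1.0) < 0.01

    def test_all_zero_rejected(self, te):
        with pytest.raises(ValueError):
            fit_monoexp(DecayCurve(te, np.zeros_like(te)))

    def test_biexp_with_f_one_equals_monoexp(self, te):
        # with the short fraction saturated the two model classes coincide
        truth = MonoexpParams(150.0, 12.0, 0.0)
        curve = DecayCurve(te, monoexp_signal(truth, te))
        mono = fit_monoexp(curve)
        bi = fit_biexp(curve)
        assert bi.residual_sum_squares == pytest.approx(
            mono.residual_sum_squares, abs=1e-10
        )
        # the collapsed biexp fit describes the same signal: same TE=0
        # amplitude and the same fitted curve everywhere
        assert bi.params.amplitude_A == pytest.approx(mono.params.m0, rel=1e-4)
        np.testing.assert_allclose(
            biexp_signal(bi.params, te), monoexp_signal(mono.params, te), rtol=1e-5
        )
        assert bi.degenerate, "equal time constants must be flagged"


class TestMagnetizations:
    def test_split_and_identity(self, noiseless_gm_curve):
        fit = fit_biexp(noiseless_gm_curve)
        pair = magnetization_fractions(fit)
        p = fit.params
        assert pair.m0_sf == pytest.approx(p.amplitude_A * p.short_fraction_f)
        assert pair.m0_sf + pair.m0_lf == pytest.approx(p.amplitude_A)

    def test_worked_cohort_share(self):
        # f = 0.577 splits A=100 into 57.7 / 42.3
        from natriq.models import FitResult

        fit = FitResult(
            params=BiexpParams(100.0, 0.577, 4.0, 35.0, 0.0),
            r_squared=1.0,
            residual_sum_squares=0.0,
            converged=True,
        )
        pair = magnetization_fractions(fit)
        assert pair.m0_sf == pytest.approx(57.7)
        assert pair.m0_lf == pytest.approx(42.3)

    def test_mono_fit_rejected(self, te):
        mono = fit_monoexp(DecayCurve(te, monoexp_signal(MonoexpParams(10, 12), te)))
        with pytest.raises(TypeError):
            magnetization_fractions(mono)
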