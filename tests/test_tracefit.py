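"""Trace parameterization: deflection, plateaus, slope, permeability, laws."""

import numpy as np
import pytest

from osmoflux.core import DelayCalibration, MembraneMechanics, OsmoticCondition, pore_delay_time
from osmoflux.exceptions import InsufficientDataError, InvalidInputError
from osmoflux.shrinkage import OpticsMap, Trace
from osmoflux.tracefit import (
    HALF_RISE_SLOPE_FACTOR,
    DelayLaw,
    ShrinkageKinetics,
    correlate_delay_rigidity,
    detect_deflection,
    extract_plateaus,
    fit_delay_law,
    permeability_from_slope,
    stage2_slope,
    stage2_window_factor,
)

P_TRUE = 2e-5
GAMMA = 10.0


class TestDetectDeflection:
    def test_noiseless_within_one_grid_step(self, make_trace):
        trace = make_trace(delta_pi=15.0, t0=0.1333)
        est = detect_deflection(trace)
        assert est.resolvable and not est.no_deflection
        assert est.t0 == pytest.approx(0.1333, abs=1.01e-3)

    def test_isosmotic_control_has_no_deflection(self, make_trace):
        est = detect_deflection(make_trace(delta_pi=0.0, t0=0.1))
        assert est.no_deflection

    def test_noisy_flat_trace_has_no_deflection(self, make_trace):
        est = detect_deflection(make_trace(delta_pi=0.0, t0=0.1, noise_sd=0.02, seed=4))
        assert est.no_deflection

    def test_delay_below_dead_time_unresolvable(self, make_trace):
        # t0 = 5 ms vanishes inside the 10 ms dead time
        est = detect_deflection(make_trace(delta_pi=150.0, t0=0.005, dead_time=0.01))
        assert not est.resolvable and not est.no_deflection

    def test_translation_equivariance(self, make_trace):
        trace = make_trace(delta_pi=50.0, t0=0.04, noise_sd=0.02, seed=9)
        shifted = Trace(times=trace.times, intensities=trace.intensities + 100.0,
                        condition=trace.condition, composition=trace.composition,
                        dead_time=trace.dead_time, temperature=trace.temperature)
        assert detect_deflection(trace).t0 == pytest.approx(
            detect_deflection(shifted).t0, abs=1e-12)

    def test_window_validation(self, make_trace):
        with pytest.raises(InvalidInputError):
            detect_deflection(make_trace(), smooth_window=4)


class TestPlateaus:
    def test_generator_round_trip_deltas(self, make_trace):
        # drop = i_00 - i_0fin = 1; rise = gamma * delta_pi / k_mech = 1
        trace = make_trace(delta_pi=150.0, t0=0.1, dead_time=0.0)
        plat = extract_plateaus(trace, 0.1)
        assert plat.drop_stage1 == pytest.approx(1.0, abs=0.02)
        assert plat.rise_stage23 == pytest.approx(1.0, abs=0.02)
        assert plat.plateaued

    def test_doubling_gamma_doubles_rise_only(self, make_trace):
        big = OpticsMap(i_00=5.0, i_0fin=4.0, gamma=20.0)
        t1 = make_trace(delta_pi=150.0, t0=0.1, dead_time=0.0)
        t2 = make_trace(delta_pi=150.0, t0=0.1, dead_time=0.0, optics_map=big)
        p1, p2 = extract_plateaus(t1, 0.1), extract_plateaus(t2, 0.1)
        assert p2.rise_stage23 == pytest.approx(2.0 * p1.rise_stage23, rel=1e-3)
        # drop is estimator-level invariant only up to the smoothing bias at
        # the kink, which grows with the stage-II curvature
        assert p2.drop_stage1 == pytest.approx(p1.drop_stage1, rel=0.02)

    def test_isosmotic_rise_is_zero(self, make_trace):
        plat = extract_plateaus(make_trace(delta_pi=0.0, t0=0.1), 0.1)
        assert plat.rise_stage23 == pytest.approx(0.0, abs=1e-4)

    def test_unplateaued_trace_flagged(self, make_trace):
        # truncate mid-rise: the tail is still climbing
        times = np.arange(0.0, 0.13, 1e-3)
        trace = make_trace(delta_pi=150.0, t0=0.1, dead_time=0.0, times=times)
        plat = extract_plateaus(trace, 0.1)
        assert not plat.plateaued

    def test_t0_outside_span_rejected(self, make_trace):
        with pytest.raises(InvalidInputError):
            extract_plateaus(make_trace(), 5.0)


class TestStageTwoSlope:
    def test_slope_matches_flux_law_after_window_correction(self, vesicle, make_trace):
        """Corrected OLS slope equals gamma*A0*V_w*P*delta_pi/V0 within 5%."""
        for dpi, t0 in [(150.0, 0.1), (50.0, 0.04), (15.0, 0.1333)]:
            trace = make_trace(delta_pi=dpi, t0=t0, dead_time=0.0)
            slope = stage2_slope(trace, t0)
            analytic = GAMMA * vesicle.area * 1.8e-5 * P_TRUE * dpi / vesicle.volume
            factor = stage2_window_factor(round(dpi / 1500.0, 4))
            assert slope / factor == pytest.approx(analytic, rel=0.05)

    def test_isosmotic_slope_is_zero(self, make_trace):
        assert stage2_slope(make_trace(delta_pi=0.0, t0=0.1), 0.1) == 0.0

    def test_slope_increases_with_drive(self, make_trace):
        cal = DelayCalibration()
        mech = MembraneMechanics(kappa_b=25.0)
        slopes = []
        for dpi in (15.0, 25.0, 50.0, 100.0, 150.0):
            t0 = pore_delay_time(OsmoticCondition(delta_pi=dpi), mech, cal).t0
            trace = make_trace(delta_pi=dpi, t0=t0, dead_time=0.0)
            slopes.append(stage2_slope(trace, t0))
        assert all(a < b for a, b in zip(slopes, slopes[1:]))

    def test_too_few_samples_rejected(self, make_trace):
        trace = make_trace(delta_pi=150.0, t0=0.1, dead_time=0.0)
        with pytest.raises(InsufficientDataError):
            stage2_slope(trace, trace.times[-3])


class TestPermeability:
    def test_round_trip_on_noiseless_synthetic(self, vesicle, make_trace):
        trace = make_trace(delta_pi=150.0, t0=0.1)
        res = ShrinkageKinetics(trace, optics_gamma=GAMMA).fit()
        assert res.p_est == pytest.approx(P_TRUE, rel=0.05)
        assert not res.p_relative

    def test_halving_drive_doubles_permeability_at_fixed_slope(self, vesicle):
        p1 = permeability_from_slope(10.0, GAMMA, vesicle, 150.0).p
        p2 = permeability_from_slope(10.0, GAMMA, vesicle, 75.0).p
        assert p2 == pytest.approx(2.0 * p1)

    def test_unknown_gamma_flags_relative_units(self, vesicle):
        rel = permeability_from_slope(10.0, None, vesicle, 150.0)
        absu = permeability_from_slope(10.0, GAMMA, vesicle, 150.0)
        assert rel.relative_units and not absu.relative_units
        assert rel.p == pytest.approx(GAMMA * absu.p)

    def test_zero_drive_rejected(self, vesicle):
        with pytest.raises(InvalidInputError):
            permeability_from_slope(10.0, GAMMA, vesicle, 0.0)

    def test_window_factor_limits(self):
        # tiny equilibrium loss reduces to the frozen-area exponential constant
        assert stage2_window_factor(1e-6) == pytest.approx(HALF_RISE_SLOPE_FACTOR, rel=1e-3)
        assert stage2_window_factor(None) == HALF_RISE_SLOPE_FACTOR
        assert 0.69 < stage2_window_factor(0.1) < HALF_RISE_SLOPE_FACTOR


class TestDelayLawFit:
    def test_exact_inverse_law(self):
        dpis = np.array([15.0, 25.0, 50.0, 100.0, 150.0])
        fit = fit_delay_law(np.column_stack([dpis, 2.0 / dpis]))
        assert fit.slope_k == pytest.approx(2.0, rel=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == 1.0

    def test_constant_delay_gives_zero_slope(self):
        dpis = np.array([15.0, 50.0, 150.0])
        fit = fit_delay_law(np.column_stack([dpis, np.full(3, 0.05)]))
        assert fit.slope_k == pytest.approx(0.0, abs=1e-15)
        assert fit.r_squared == 1.0

    def test_ten_percent_noise_keeps_r_squared_high(self):
        """Monte-Carlo: 10% relative noise, 5 points, 100 seeds."""
        dpis = np.array([15.0, 25.0, 50.0, 100.0, 150.0])
        t0 = 2.0 / dpis
        r2 = []
        for s in range(100):
            rng = np.random.default_rng(s)
            noisy = t0 + rng.normal(0.0, 0.1 * t0)
            r2.append(fit_delay_law(np.column_stack([dpis, noisy])).r_squared)
        assert min(r2) >= 0.9

    def test_single_condition_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_delay_law([(50.0, 0.04), (50.0, 0.041)])

    def test_model_interface_predicts(self):
        import pandas as pd

        df = pd.DataFrame({"delta_pi_mosm": [15.0, 50.0, 150.0],
                           "t0_s": [2.0 / 15, 2.0 / 50, 2.0 / 150]})
        res = DelayLaw.from_dataframe(df).fit()
        assert res.predict(20.0) == pytest.approx(0.1, rel=1e-9)
        assert "R^2" in res.summary()


class TestRigidityCorrelation:
    def test_collinear_pairs(self):
        pairs = [(15.0, 0.07), (25.0, 0.10), (50.0, 0.175)]
        corr = correlate_delay_rigidity(pairs)
        assert corr.pearson_r == pytest.approx(1.0, abs=1e-9)
        flipped = [(k, -t) for k, t in pairs]
        assert correlate_delay_rigidity(flipped).pearson_r == pytest.approx(-1.0, abs=1e-9)

    def test_noisy_default_law_pairs_correlate(self):
        """5% noise on delay-law delays across the four mixtures at 20 mOsm."""
        cal = DelayCalibration()
        rng = np.random.default_rng(13)
        pairs = []
        for kappa in (25.0, 50.0, 15.0, 25.0):
            t0 = pore_delay_time(OsmoticCondition(delta_pi=20.0),
                                 MembraneMechanics(kappa_b=kappa), cal).t0
            for _ in range(3):
                pairs.append((kappa, t0 * (1.0 + rng.normal(0.0, 0.05))))
        assert correlate_delay_rigidity(pairs).pearson_r >= 0.9

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            correlate_delay_rigidity([(25.0, 0.1), (50.0, 0.2)])


class TestFullPipelineRecovery:
    def test_noiseless_recovery_across_parameter_box(self, make_trace):
        for dpi, t0 in [(150.0, 0.0133), (150.0, 0.1), (50.0, 0.04),
                        (25.0, 0.08), (15.0, 0.1333)]:
            res = ShrinkageKinetics(make_trace(delta_pi=dpi, t0=t0),
                                    optics_gamma=GAMMA).fit()
            assert res.t0_est == pytest.approx(t0, abs=1.01e-3)
            assert res.p_est == pytest.approx(P_TRUE, rel=0.05)

    @pytest.mark.parametrize("dpi,t0", [(50.0, 0.04), (15.0, 0.1333)])
    def test_noisy_recovery_at_snr20(self, make_trace, dpi, t0):
        """RMS relative error over 50 seeds stays within 15% at SNR 20."""
        rise = GAMMA * dpi / 1500.0
        errs_t0, errs_p = [], []
        for seed in range(50):
            trace = make_trace(delta_pi=dpi, t0=t0, noise_sd=rise / 20.0, seed=seed)
            res = ShrinkageKinetics(trace, optics_gamma=GAMMA).fit()
            errs_t0.append((res.t0_est - t0) / t0)
            errs_p.append((res.p_est - P_TRUE) / P_TRUE)
        assert np.sqrt(np.mean(np.square(errs_t0))) <= 0.15
        assert np.sqrt(np.mean(np.square(errs_p))) <= 0.15

    def test_refit_delay_law_recovers_generator_scale(self, make_trace):
        """Noiseless sweep refits the generator k_scale within 2%."""
        cal = DelayCalibration()
        mech = MembraneMechanics(kappa_b=25.0)
        points = []
        for dpi in (15.0, 25.0, 50.0, 100.0, 150.0):
            t0 = pore_delay_time(OsmoticCondition(delta_pi=dpi), mech, cal).t0
            res = ShrinkageKinetics(make_trace(delta_pi=dpi, t0=t0)).fit()
            points.append((dpi, res.t0_est))
        fit = fit_delay_law(points)
        assert fit.slope_k == pytest.approx(cal.k_scale, rel=0.02)
        assert fit.r_squared > 0.999
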