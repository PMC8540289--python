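"""Forward shrinkage model: geometry, ODE, optics map, instrument effects."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import euler_volume
from osmoflux.core import OsmoticCondition
from osmoflux.exceptions import InvalidInputError
from osmoflux.shrinkage import (
    OpticsMap,
    ShrinkagePhysics,
    VesicleState,
    apply_instrument,
    intensity_from_volume,
    simulate_volume,
    sphere_geometry,
)


class TestSphereGeometry:
    def test_mean_vesicle(self):
        # 110 nm mean diameter vesicle
        radius, area = sphere_geometry(6.9691e5 * 1e-27)
        assert radius == pytest.approx(55e-9, rel=1e-4)
        assert area == pytest.approx(3.8013e4 * 1e-18, rel=1e-4)

    def test_similarity_scaling(self):
        r1, a1 = sphere_geometry(1e-21)
        r2, a2 = sphere_geometry(8e-21)
        assert r2 == pytest.approx(2 * r1)
        assert a2 == pytest.approx(4 * a1)

    @given(v=st.floats(min_value=1e-24, max_value=1e-15))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, v):
        r, _ = sphere_geometry(v)
        assert 4.0 / 3.0 * np.pi * r**3 == pytest.approx(v, rel=1e-12)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(InvalidInputError):
            sphere_geometry(0.0)

    def test_vesicle_state_consistency_enforced(self):
        with pytest.raises(InvalidInputError):
            VesicleState(volume=1e-21, radius=1e-7, area=1.0)


class TestSimulateVolume:
    def test_constant_before_delay(self, vesicle):
        phys = ShrinkagePhysics(permeability=2e-5, t0=0.5)
        times = np.linspace(0, 0.4, 100)
        sol = simulate_volume(vesicle, phys, OsmoticCondition(delta_pi=150.0), times)
        assert np.all(sol.volumes == vesicle.volume)

    def test_zero_drive_is_flat(self, vesicle, grid):
        phys = ShrinkagePhysics(permeability=2e-5, t0=0.0)
        sol = simulate_volume(vesicle, phys, OsmoticCondition(delta_pi=0.0), grid)
        assert np.all(sol.volumes == vesicle.volume)

    def test_initial_slope_matches_flux_law(self, vesicle):
        # dV/dt(0) = -A0 V_w P delta_pi = -2.053e-21 m^3/s at 150 mOsm
        phys = ShrinkagePhysics(permeability=2e-5, t0=0.0)
        times = np.array([0.0, 1e-6])
        sol = simulate_volume(vesicle, phys, OsmoticCondition(delta_pi=150.0), times)
        secant = (sol.volumes[1] - sol.volumes[0]) / 1e-6
        assert secant == pytest.approx(-2.053e-21, rel=5e-3)

    def test_monotone_nonincreasing(self, vesicle, grid):
        phys = ShrinkagePhysics(permeability=2e-5, t0=0.05)
        sol = simulate_volume(vesicle, phys, OsmoticCondition(delta_pi=150.0), grid)
        assert np.all(np.diff(sol.volumes) <= 1e-30)

    def test_equilibrium_set_by_back_pressure(self, vesicle, grid):
        phys = ShrinkagePhysics(permeability=2e-5, t0=0.0, k_mech=1500.0)
        sol = simulate_volume(vesicle, phys, OsmoticCondition(delta_pi=150.0), grid)
        rel_loss = (vesicle.volume - sol.volumes[-1]) / vesicle.volume
        assert rel_loss == pytest.approx(150.0 / 1500.0, rel=1e-4)

    @pytest.mark.parametrize("delta_pi,permeability,t0", [
        (150.0, 2e-5, 0.0),
        (15.0, 2e-5, 0.1333),
        (150.0, 5e-5, 0.05),
        (50.0, 1e-5, 0.04),
    ])
    def test_euler_oracle_agreement(self, vesicle, grid, delta_pi, permeability, t0):
        """Adaptive integration within 0.1% of the fixed-step Euler oracle."""
        phys = ShrinkagePhysics(permeability=permeability, t0=t0)
        sol = simulate_volume(vesicle, phys, OsmoticCondition(delta_pi=delta_pi), grid)
        oracle = euler_volume(vesicle, phys, delta_pi, grid, dt=1e-5)
        assert np.max(np.abs(sol.volumes / oracle - 1.0)) < 1e-3

    def test_stiff_back_pressure_reduces_to_linear_flux(self, vesicle):
        """k_mech -> infinity recovers the constant-drive flux law early on."""
        phys = ShrinkagePhysics(permeability=2e-5, t0=0.0, k_mech=1e9)
        times = np.linspace(0.0, 1e-4, 50)
        sol = simulate_volume(vesicle, phys, OsmoticCondition(delta_pi=150.0), times)
        slope = np.polyfit(times, sol.volumes, 1)[0]
        assert slope == pytest.approx(-vesicle.area * 1.8e-5 * 2e-5 * 150.0, rel=1e-2)

    def test_delayed_model_is_time_shifted_plain_model(self, vesicle):
        """With t0 > 0 the piecewise law equals the t0 = 0 trajectory shifted."""
        base = np.arange(0.0, 0.5, 1e-3)
        plain = simulate_volume(vesicle, ShrinkagePhysics(permeability=2e-5, t0=0.0),
                                OsmoticCondition(delta_pi=150.0), base)
        delayed = simulate_volume(vesicle, ShrinkagePhysics(permeability=2e-5, t0=0.05),
                                  OsmoticCondition(delta_pi=150.0), base + 0.05)
        assert np.allclose(delayed.volumes, plain.volumes, rtol=1e-7)

    def test_full_collapse_flagged(self, vesicle, grid):
        phys = ShrinkagePhysics(permeability=2e-5, t0=0.0, k_mech=100.0)
        sol = simulate_volume(vesicle, phys, OsmoticCondition(delta_pi=150.0), grid)
        assert sol.full_collapse

    def test_frozen_area_matches_closed_form(self, vesicle, grid):
        """Frozen-area dynamics are an exact exponential relaxation."""
        phys = ShrinkagePhysics(permeability=2e-5, t0=0.0, k_mech=1500.0)
        sol = simulate_volume(vesicle, phys, OsmoticCondition(delta_pi=150.0), grid,
                              frozen_area=True)
        lam = vesicle.area * 1.8e-5 * 2e-5 * 1500.0 / vesicle.volume
        x_eq = 150.0 / 1500.0
        expected = vesicle.volume * (1.0 - x_eq * (1.0 - np.exp(-lam * grid)))
        assert np.allclose(sol.volumes, expected, rtol=1e-6)


class TestIntensityMap:
    def test_minimum_at_delay_time(self, vesicle, optics, grid):
        phys = ShrinkagePhysics(permeability=2e-5, t0=0.1)
        cond = OsmoticCondition(delta_pi=150.0)
        sol = simulate_volume(vesicle, phys, cond, grid)
        trace = intensity_from_volume(sol.volumes, optics, 0.1, grid, cond)
        i_min = np.argmin(trace.intensities)
        assert grid[i_min] == pytest.approx(0.1, abs=1.01e-3)
        assert np.interp(0.1, grid, trace.intensities) == pytest.approx(4.0, abs=1e-6)

    def test_final_plateau_level(self, vesicle, optics, grid):
        # I_fin,fin = i_0fin + gamma * delta_pi / k_mech = 4 + 10 * 0.1 = 5
        phys = ShrinkagePhysics(permeability=2e-5, t0=0.0, k_mech=1500.0)
        cond = OsmoticCondition(delta_pi=150.0)
        sol = simulate_volume(vesicle, phys, cond, grid)
        trace = intensity_from_volume(sol.volumes, optics, 0.0, grid, cond)
        assert trace.intensities[-1] == pytest.approx(5.0, rel=1e-3)

    def test_isosmotic_control_flat_after_stage_one(self, vesicle, optics, grid):
        phys = ShrinkagePhysics(permeability=2e-5, t0=0.1)
        cond = OsmoticCondition(delta_pi=0.0)
        sol = simulate_volume(vesicle, phys, cond, grid)
        trace = intensity_from_volume(sol.volumes, optics, 0.1, grid, cond)
        after = grid >= 0.1
        assert np.all(trace.intensities[after] == optics.i_0fin)

    def test_mismatched_grids_rejected(self, optics, grid):
        with pytest.raises(InvalidInputError):
            intensity_from_volume(np.ones(5), optics, 0.1, grid,
                                  OsmoticCondition(delta_pi=10.0))

    def test_optics_invariants(self):
        with pytest.raises(InvalidInputError):
            OpticsMap(i_00=4.0, i_0fin=4.0, gamma=10.0)
        with pytest.raises(InvalidInputError):
            OpticsMap(i_00=5.0, i_0fin=4.0, gamma=-1.0)


class TestInstrument:
    def test_identity_without_noise_or_dead_time(self, make_trace):
        trace = make_trace(noise_sd=0.0, dead_time=0.0)
        out = apply_instrument(trace, dead_time=0.0, noise_sd=0.0)
        assert np.array_equal(out.times, trace.times)
        assert np.array_equal(out.intensities, trace.intensities)

    def test_seeded_noise_is_reproducible(self, make_trace):
        a = make_trace(noise_sd=0.05, seed=11)
        b = make_trace(noise_sd=0.05, seed=11)
        c = make_trace(noise_sd=0.05, seed=12)
        assert np.array_equal(a.intensities, b.intensities)
        assert np.max(np.abs(a.intensities - c.intensities)) > 1e-12

    def test_dead_time_removes_exact_sample_count(self, make_trace, grid):
        full = make_trace(dead_time=0.0)
        cut = apply_instrument(full, dead_time=0.01)
        assert len(full) - len(cut) == 10  # 10 samples below 10 ms on a 1 ms grid
        assert cut.times[0] >= 0.01

    def test_dead_time_longer_than_trace_rejected(self, make_trace):
        with pytest.raises(InvalidInputError):
            apply_instrument(make_trace(), dead_time=10.0)
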