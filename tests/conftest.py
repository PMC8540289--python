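"""Shared fixtures and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from osmoflux.core import OsmoticCondition
from osmoflux.shrinkage import (
    OpticsMap,
    ShrinkagePhysics,
    VesicleState,
    simulate_trace,
)


@pytest.fixture(scope="session")
def vesicle() -> VesicleState:
    """The representative 110 nm-diameter extruded vesicle."""
    return VesicleState.from_radius(55e-9)


@pytest.fixture(scope="session")
def optics() -> OpticsMap:
    return OpticsMap(i_00=5.0, i_0fin=4.0, gamma=10.0)


@pytest.fixture(scope="session")
def grid() -> np.ndarray:
    """Default 1 ms acquisition grid over 1 s."""
    return np.arange(0.0, 1.0005, 1e-3)


@pytest.fixture(scope="session")
def make_trace(vesicle, optics, grid):
    """Factory for simulated shrinkage traces with sensible defaults."""

    def _make(delta_pi=150.0, t0=0.1, permeability=2e-5, k_mech=1500.0,
              dead_time=0.01, noise_sd=0.0, seed=None, times=None,
              optics_map=None):
        phys = ShrinkagePhysics(permeability=permeability, t0=t0, k_mech=k_mech)
        cond = OsmoticCondition(delta_pi=delta_pi)
        return simulate_trace(
            vesicle, phys, cond, optics_map or optics,
            grid if times is None else times,
            dead_time=dead_time, noise_sd=noise_sd, seed=seed)

    return _make


def euler_volume(initial: VesicleState, phys: ShrinkagePhysics,
                 delta_pi: float, times: np.ndarray, dt: float = 1e-5,
                 frozen_area: bool = False) -> np.ndarray:
    """Fixed-step explicit-Euler oracle for the shrinkage ODE.

    Deliberately naive and independent of the adaptive integrator: marches
    from t0 with constant step dt and linearly interpolates onto the grid.
    """
    v0 = initial.volume
    a0 = initial.area
    out = np.full(times.shape, v0, dtype=float)
    late = times >= phys.t0
    if not late.any() or delta_pi == 0 or phys.permeability == 0:
        return out
    t_end = float(times[-1])
    n_steps = int(np.ceil((t_end - phys.t0) / dt)) + 1
    ts = phys.t0 + dt * np.arange(n_steps + 1)
    vs = np.empty(n_steps + 1)
    v = v0
    vs[0] = v
    for i in range(n_steps):
        area = a0 if frozen_area else (36.0 * np.pi) ** (1 / 3) * v ** (2 / 3)
        drive = delta_pi - phys.k_mech * (v0 - v) / v0
        v = v - dt * area * phys.v_w * phys.permeability * drive
        vs[i + 1] = v
    out[late] = np.interp(times[late], ts, vs)
    return out
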