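"""Forward model of osmotically driven vesicle shrinkage and its optical readout.

A spherical vesicle of volume V exposed at t = 0 to an external osmotic
excess delta_pi loses water through spontaneously formed lipid pores.  No
flux occurs before the pore-opening delay t0; afterwards

    dV/dt = -A(V) * V_w * P * (delta_pi - k_mech * (V0 - V) / V0)

where A is the (volume-consistent spherical) surface area, V_w the molar
volume of water, P the osmotic water permeability and k_mech a linear
elastic back-pressure: the shrinkage saturates when the osmotic drive is
balanced by the membrane's resistance to deformation, at a relative
volume loss delta_pi / k_mech.

The stopped-flow instrument observes scattered light, not volume.  The
mapping has three stages: a smooth descent from the pre-mix level i_00 to
the minimum i_0fin while the outer interface reorganises (stage I, ending
at t0), then a rise affine in relative volume loss while water flows out
(stage II), flattening into the final equilibrium plateau (stage III).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .core import WATER_MOLAR_VOLUME, OsmoticCondition
from .exceptions import InvalidInputError

__all__ = [
    "VesicleState",
    "ShrinkagePhysics",
    "OpticsMap",
    "Trace",
    "sphere_geometry",
    "simulate_volume",
    "intensity_from_volume",
    "apply_instrument",
    "simulate_trace",
]


def sphere_geometry(volume: float) -> tuple[float, float]:
    """Radius and surface area of a sphere of given volume (SI units)."""
    if volume <= 0:
        raise InvalidInputError(f"volume must be > 0, got {volume}")
    radius = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    area = 4.0 * np.pi * radius**2
    return radius, area


@dataclass(frozen=True)
class VesicleState:
    """Spherical vesicle geometry plus internal osmolality.

    Constructed via :meth:`from_radius` or :meth:`from_volume` so the
    sphere-consistency invariant (A = (36 pi)^(1/3) V^(2/3)) holds by
    construction.
    """

    volume: float
    radius: float
    area: float
    internal_osmolality: float = 0.0

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise InvalidInputError("volume must be > 0")
        a_sphere = (36.0 * np.pi) ** (1.0 / 3.0) * self.volume ** (2.0 / 3.0)
        if abs(self.area - a_sphere) > 1e-9 * a_sphere:
            raise InvalidInputError("area inconsistent with spherical volume")

    @classmethod
    def from_volume(cls, volume: float, internal_osmolality: float = 0.0) -> "VesicleState":
        r, a = sphere_geometry(volume)
        return cls(volume=volume, radius=r, area=a, internal_osmolality=internal_osmolality)

    @classmethod
    def from_radius(cls, radius: float, internal_osmolality: float = 0.0) -> "VesicleState":
        if radius <= 0:
            raise InvalidInputError(f"radius must be > 0, got {radius}")
        v = 4.0 / 3.0 * np.pi * radius**3
        return cls(volume=v, radius=radius, area=4.0 * np.pi * radius**2,
                   internal_osmolality=internal_osmolality)


@dataclass(frozen=True)
class ShrinkagePhysics:
    """Transport and mechanical parameters of the shrinkage model.

    permeability : osmotic water permeability P, m/s.
    t0 : pore-opening delay, s (zero flux before t0).
    v_w : molar volume of water, fixed at 1.8e-5 m^3/mol.
    k_mech : elastic back-pressure scale, mOsm, defined as the osmotic
        pressure balanced at 100% relative volume loss; the default 1500
        mOsm makes a 150 mOsm drive shrink the vesicle by 10%.
    """

    permeability: float = 2e-5
    t0: float = 0.0
    v_w: float = WATER_MOLAR_VOLUME
    k_mech: float = 1500.0

    def __post_init__(self) -> None:
        if self.permeability < 0:
            raise InvalidInputError("permeability must be >= 0")
        if self.v_w != WATER_MOLAR_VOLUME:
            raise InvalidInputError(
                f"v_w is fixed at {WATER_MOLAR_VOLUME} m^3/mol in this model"
            )
        if self.k_mech <= 0:
            raise InvalidInputError("k_mech must be > 0")
        if self.t0 < 0:
            raise InvalidInputError("t0 must be >= 0")


@dataclass(frozen=True)
class OpticsMap:
    """Affine map from relative volume loss to scattered-light intensity.

    i_00 : pre-mix intensity level, a.u.
    i_0fin : intensity minimum at the end of stage I, a.u. (< i_00).
    gamma : intensity rise per unit relative volume loss, a.u.
    """

    i_00: float = 5.0
    i_0fin: float = 4.0
    gamma: float = 10.0

    def __post_init__(self) -> None:
        if not self.i_00 > self.i_0fin:
            raise InvalidInputError("stage-I drop requires i_00 > i_0fin")
        if self.gamma <= 0:
            raise InvalidInputError("gamma must be > 0 (shrinkage raises intensity)")


@dataclass(frozen=True)
class Trace:
    """A stopped-flow time/intensity series with instrument metadata.

    Times are seconds from flow stop (strictly increasing); intensities
    are arbitrary units.
    """

    times: np.ndarray
    intensities: np.ndarray
    condition: OsmoticCondition
    composition: str = "egg-PC"
    dead_time: float = 0.0
    temperature: float = 298.15
    seed: int | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intens = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intens)
        if times.shape != intens.shape or times.ndim != 1:
            raise InvalidInputError("times and intensities must be equal-length 1-D")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise InvalidInputError("times must be strictly increasing")
        if self.dead_time < 0:
            raise InvalidInputError("dead_time must be >= 0")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class VolumeSolution:
    """Volume trajectory plus model-validity flag."""

    times: np.ndarray
    volumes: np.ndarray
    full_collapse: bool


def simulate_volume(
    initial: VesicleState,
    phys: ShrinkagePhysics,
    cond: OsmoticCondition,
    times: np.ndarray,
    frozen_area: bool = False,
    rtol: float = 1e-8,
) -> VolumeSolution:
    """Integrate the delayed osmotic-shrinkage ODE on a time grid.

    V(t) = V0 for t < t0; afterwards dV/dt = -A V_w P (delta_pi - back
    pressure).  With ``frozen_area=True`` the surface area is pinned at
    A0, which makes the relative-volume dynamics exactly linear (used for
    closed-form checks).

    When delta_pi >= k_mech the predicted equilibrium lies outside the
    small-deformation validity of the elastic term; the trajectory is
    still integrated but flagged ``full_collapse``.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise InvalidInputError("times must be a non-empty 1-D grid")
    if times[0] < 0 or (times.size >= 2 and not np.all(np.diff(times) > 0)):
        raise InvalidInputError("times must start >= 0 and increase strictly")

    v0 = initial.volume
    a0 = initial.area
    dpi = cond.delta_pi
    full_collapse = dpi >= phys.k_mech

    volumes = np.full(times.shape, v0, dtype=float)
    late = times >= phys.t0
    if dpi == 0 or phys.permeability == 0 or not late.any():
        return VolumeSolution(times=times, volumes=volumes, full_collapse=full_collapse)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        v = y[0]
        area = a0 if frozen_area else (36.0 * np.pi) ** (1.0 / 3.0) * max(v, 1e-30) ** (2.0 / 3.0)
        drive = dpi - phys.k_mech * (v0 - v) / v0
        return np.array([-area * phys.v_w * phys.permeability * drive])

    t_late = times[late]
    t_end = t_late[-1]
    if t_end == phys.t0:
        return VolumeSolution(times=times, volumes=volumes, full_collapse=full_collapse)
    # integration starts exactly at flux onset t0
    sol = solve_ivp(
        rhs,
        (phys.t0, t_end),
        np.array([v0]),
        method="RK45",
        t_eval=t_late,
        rtol=rtol,
        atol=v0 * 1e-12,
        max_step=max((t_end - phys.t0) / 50.0, 1e-6),
    )
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"volume integration failed: {sol.message}")
    volumes[late] = sol.y[0]
    return VolumeSolution(times=times, volumes=volumes, full_collapse=full_collapse)


def _stage1_ease(t: np.ndarray, t0: float, i_00: float, i_0fin: float) -> np.ndarray:
    """Cubic ease from i_00 down to i_0fin over [0, t0]; zero slope at t0."""
    s = np.clip(t / t0, 0.0, 1.0)
    return i_00 - (i_00 - i_0fin) * (3.0 * s**2 - 2.0 * s**3)


def intensity_from_volume(
    volumes: np.ndarray,
    optics: OpticsMap,
    t0: float,
    times: np.ndarray,
    cond: OsmoticCondition,
    composition: str = "egg-PC",
    temperature: float = 298.15,
) -> Trace:
    """Map a volume trajectory to a noiseless scattered-light trace.

    Stage I (t < t0): smooth monotone descent i_00 -> i_0fin with zero
    slope at t0 (cubic ease), so the global minimum sits exactly at t0.
    Stage II/III (t >= t0): i_0fin + gamma * (V0 - V(t)) / V0.
    """
    times = np.asarray(times, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if times.shape != volumes.shape:
        raise InvalidInputError("times and volumes grids mismatch")
    v0 = volumes[0]
    intens = np.empty_like(times)
    pre = times < t0
    if t0 > 0:
        intens[pre] = _stage1_ease(times[pre], t0, optics.i_00, optics.i_0fin)
    intens[~pre] = optics.i_0fin + optics.gamma * (v0 - volumes[~pre]) / v0
    return Trace(
        times=times,
        intensities=intens,
        condition=cond,
        composition=composition,
        dead_time=0.0,
        temperature=temperature,
    )


def apply_instrument(
    trace: Trace,
    dead_time: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Trace:
    """Apply stopped-flow instrument effects: dead time and detector noise.

    Samples earlier than ``dead_time`` are unobservable (they overlap with
    mixing) and are removed; additive Gaussian noise of the given standard
    deviation is applied with a seeded generator.
    """
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    if dead_time < 0:
        raise InvalidInputError("dead_time must be >= 0")
    keep = trace.times >= dead_time
    if not keep.any():
        raise InvalidInputError("dead_time removes the entire trace")
    times = trace.times[keep]
    intens = trace.intensities[keep].copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intens = intens + rng.normal(0.0, noise_sd, size=intens.shape)
    return replace(trace, times=times, intensities=intens,
                   dead_time=dead_time, seed=seed)


def simulate_trace(
    initial: VesicleState,
    phys: ShrinkagePhysics,
    cond: OsmoticCondition,
    optics: OpticsMap,
    times: np.ndarray,
    dead_time: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    composition: str = "egg-PC",
    temperature: float = 298.15,
) -> Trace:
    """Convenience pipeline: volume ODE -> optics map -> instrument."""
    vol = simulate_volume(initial, phys, cond, times)
    ideal = intensity_from_volume(vol.volumes, optics, phys.t0, times, cond,
                                  composition=composition, temperature=temperature)
    return apply_instrument(ideal, dead_time=dead_time, noise_sd=noise_sd, seed=seed)
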