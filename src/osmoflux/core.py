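"""Membrane mechanics and the pore-opening delay law.

The lipid bilayer is treated as a soft elastic sheet in the Helfrich
continuum picture: a deformation with principal curvatures ``c1``, ``c2``
costs an energy per unit area

    e = 1/2 * kappa_b * (c1 + c2 - c0)**2 + kappa_G * c1 * c2

with bending rigidity ``kappa_b``, Gaussian modulus ``kappa_G`` and
spontaneous curvature ``c0``.  Opening a transient water-filled pore is a
topological change whose likelihood tracks the membrane mechanics, so a
vesicle exposed at t = 0 to an osmotic pressure difference does not start
losing water immediately: there is a delay ``t0`` during which the outer
interface reorganises and a pore nucleates.

The delay law implemented here encodes the three experimentally observed
trends — t0 proportional to 1/delta_pi, t0 increasing with kappa_b, t0
decreasing with temperature — as the simplest separable form consistent
with all three:

    t0 = [k_scale + rigidity_coeff * (kappa_b - kappa_ref)]
         * max(0, 1 - temp_coeff * (T - t_ref)) / delta_pi

Units: curvatures nm^-1, energies k_BT, osmolalities mOsm (numerically
equal to mol/m^3 for dilute aqueous solutions), times s, temperatures K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import InvalidInputError

__all__ = [
    "WATER_MOLAR_VOLUME",
    "WATER_MOLAR_MASS",
    "WATER_DENSITY",
    "DEFAULT_DEAD_TIME",
    "Composition",
    "MembraneMechanics",
    "DelayCalibration",
    "OsmoticCondition",
    "DelayPrediction",
    "helfrich_energy_density",
    "delta_pi_from_mixing",
    "pore_delay_time",
    "barrier_to_delay",
]

#: Molar volume of water, m^3/mol (0.018 L/mol), as used in the flux law.
WATER_MOLAR_VOLUME: float = 1.8e-5

#: Molar mass of water, kg/mol, and density at 25 degC, kg/m^3 — kept so the
#: molar volume can be recomputed from first principles rather than trusted.
WATER_MOLAR_MASS: float = 18.01528e-3
WATER_DENSITY: float = 997.047

#: Default stopped-flow instrument dead time, s.  Delays shorter than this
#: overlap with mixing and cannot be resolved.
DEFAULT_DEAD_TIME: float = 0.010


@dataclass(frozen=True)
class Composition:
    """A lipid mixture, e.g. egg-PC/cholesterol 70/30 mol%.

    Parameters
    ----------
    label : str
        Human-readable mixture name used in metadata and manifests.
    components : tuple of (str, float)
        (lipid name, mole fraction) pairs; fractions must sum to 1.
    """

    label: str
    components: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if len(self.components) == 0:
            raise InvalidInputError("composition needs at least one component")
        total = 0.0
        for name, frac in self.components:
            if not (0.0 <= frac <= 1.0):
                raise InvalidInputError(
                    f"mole fraction of {name!r} outside [0, 1]: {frac}"
                )
            total += frac
        if abs(total - 1.0) > 1e-9:
            raise InvalidInputError(f"mole fractions sum to {total}, not 1")


@dataclass(frozen=True)
class MembraneMechanics:
    """Helfrich elastic parameters of a bilayer.

    kappa_b and kappa_G are in k_BT units, c0 in nm^-1, temperature in K.
    kappa_G defaults to -0.8 * kappa_b, a common continuum estimate; it
    enters only the energy density, never the delay law.
    """

    kappa_b: float
    kappa_G: float | None = None
    c0: float = 0.0
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.kappa_b <= 0:
            raise InvalidInputError(f"kappa_b must be > 0, got {self.kappa_b}")
        if self.temperature <= 0:
            raise InvalidInputError(
                f"temperature must be > 0 K, got {self.temperature}"
            )
        if self.kappa_G is None:
            object.__setattr__(self, "kappa_G", -0.8 * self.kappa_b)


@dataclass(frozen=True)
class DelayCalibration:
    """Empirical calibration of the pore-opening delay law.

    Parameters
    ----------
    k_scale : float
        Product t0 * delta_pi at reference mechanics and temperature,
        mOsm*s.  The default 2.0 mOsm*s puts t0 below the 10 ms dead time
        whenever delta_pi exceeds 200 mOsm, where the delay becomes
        unresolvable and the kinetics reduce to the plain flux law.
    rigidity_coeff : float
        Linear sensitivity of k_scale to bending rigidity, s*mOsm per k_BT.
        Positive: stiffer membranes (cholesterol) open pores later.
    temp_coeff : float
        Fractional decrease of k_scale per kelvin above t_ref.
    t_ref, kappa_ref : float
        Reference temperature (K) and bending rigidity (k_BT) at which
        k_scale applies.
    """

    k_scale: float = 2.0
    rigidity_coeff: float = 0.06
    temp_coeff: float = 0.01
    t_ref: float = 298.15
    kappa_ref: float = 25.0

    def __post_init__(self) -> None:
        if self.k_scale <= 0:
            raise InvalidInputError(f"k_scale must be > 0, got {self.k_scale}")


@dataclass(frozen=True)
class OsmoticCondition:
    """Transmembrane driving forces for one experiment.

    delta_pi is external minus internal osmolality in mOsm (>= 0 in all
    shrinkage runs); delta_ph is external minus internal pH (signed).  The
    solute label is metadata only — the deflection position does not depend
    on the chemical identity of the osmolyte, so no computation may branch
    on it.
    """

    delta_pi: float
    delta_ph: float = 0.0
    solute: str = "KCl"

    def __post_init__(self) -> None:
        if self.delta_pi < 0:
            raise InvalidInputError(
                f"delta_pi must be >= 0 in shrinkage experiments, got {self.delta_pi}"
            )


@dataclass(frozen=True)
class DelayPrediction:
    """Predicted pore-opening delay with instrument-resolvability flags."""

    t0: float
    resolvable: bool
    infinite: bool = False


def helfrich_energy_density(c1: float, c2: float, mech: MembraneMechanics) -> float:
    """Helfrich bending energy per unit area, k_BT/nm^2.

    Total function on real curvatures; symmetric in (c1, c2).
    """
    bend = 0.5 * mech.kappa_b * (c1 + c2 - mech.c0) ** 2
    gauss = mech.kappa_G * c1 * c2
    return bend + gauss


def delta_pi_from_mixing(
    c_stock: float,
    c_suspension: float,
    mix_ratio: tuple[float, float] = (1.0, 1.0),
    convention: str = "nominal",
) -> float:
    """Osmotic pressure difference generated by mixing, mOsm.

    A vesicle suspension of osmolality ``c_suspension`` is mixed with an
    osmolyte stock of osmolality ``c_stock`` in volume ratio
    ``mix_ratio = (stock part, suspension part)``.

    convention="nominal" uses the protocol bookkeeping: the interior (and
    the suspension buffer) osmolality is treated as negligible, so
    delta_pi = c_stock * stock_part / total_parts.  A 1:1 mix of a
    300 mOsm stock with a dilute suspension gives 150 mOsm.

    convention="exact" returns the volume-weighted external osmolality
    minus the (unchanged) internal osmolality ``c_suspension``.
    """
    if c_stock < 0 or c_suspension < 0:
        raise InvalidInputError("osmolalities must be non-negative")
    stock_part, susp_part = mix_ratio
    if stock_part <= 0 or susp_part <= 0:
        raise InvalidInputError("mixing ratio parts must be > 0")
    total = stock_part + susp_part
    if convention == "nominal":
        return c_stock * stock_part / total
    if convention == "exact":
        external = (c_stock * stock_part + c_suspension * susp_part) / total
        return external - c_suspension
    raise InvalidInputError(f"unknown convention {convention!r}")


def pore_delay_time(
    cond: OsmoticCondition,
    mech: MembraneMechanics,
    cal: DelayCalibration = DelayCalibration(),
    dead_time: float = DEFAULT_DEAD_TIME,
) -> DelayPrediction:
    """Pore-opening delay t0 for a given drive, mechanics and calibration.

    t0 = [k_scale + rigidity_coeff*(kappa_b - kappa_ref)]
         * max(0, 1 - temp_coeff*(T - t_ref)) / delta_pi

    delta_pi = 0 is not an error: no osmotic drive means no pore-driven
    flux is predicted, reported as an infinite delay.  A finite t0 below
    the instrument dead time is flagged unresolvable.
    """
    if cond.delta_pi == 0:
        return DelayPrediction(t0=math.inf, resolvable=False, infinite=True)
    scale = cal.k_scale + cal.rigidity_coeff * (mech.kappa_b - cal.kappa_ref)
    if scale < 0:
        raise InvalidInputError(
            "calibration predicts a negative delay scale for these mechanics"
        )
    atten = max(0.0, 1.0 - cal.temp_coeff * (mech.temperature - cal.t_ref))
    t0 = scale * atten / cond.delta_pi
    return DelayPrediction(t0=t0, resolvable=t0 >= dead_time)


def barrier_to_delay(e_pore: float, tau_attempt: float = 1e-6) -> float:
    """Expected pore-opening waiting time from an energy barrier.

    Arrhenius/Kramers form tau_attempt * exp(e_pore) with e_pore in k_BT.
    Pore-opening barriers of a few tens of k_BT with microsecond attempt
    times put the waiting time in the experimentally observed window.
    """
    if tau_attempt <= 0:
        raise InvalidInputError(f"tau_attempt must be > 0, got {tau_attempt}")
    return tau_attempt * math.exp(e_pore)
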