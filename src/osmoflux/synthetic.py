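"""Fixture factory emulating the full experimental design.

Generates the three data families — stopped-flow shrinkage traces over a
(composition x delta_pi x temperature x solute x replicate) grid, GUV
flicker contour series (with optional rendered image stacks), and proton
flux fluorescence traces for the canonical six-condition set — together
with a manifest recording every file's ground-truth parameters, so every
estimator in the package can be scored against known inputs without
reading generator internals.

Composition effects are qualitative literature trends turned into default
multipliers (the manifest labels them "defaults, not measurements"):
cholesterol stiffens the membrane (raising the pore-opening delay) and
amplifies the stage-II/III optical rise by an order of magnitude; lysoPC
softens it; PE leaves the rigidity unchanged but raises the water
permeability by 1.2x.  The solute label (KCl / NaCl / sucrose) never
enters any computation — the deflection position does not depend on the
chemical identity of the osmolyte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import DelayCalibration, MembraneMechanics, OsmoticCondition, pore_delay_time
from .flicker import generate_contours, render_frames
from .proton import FluxCoupling, ProtonKinetics, simulate_fluorescence, slow_slope
from .shrinkage import OpticsMap, ShrinkagePhysics, VesicleState, simulate_trace

__all__ = [
    "CompositionDefaults",
    "StudyDesign",
    "make_shrinkage_dataset",
    "make_flicker_dataset",
    "make_proton_dataset",
    "make_all",
    "derive_seed",
]


@dataclass(frozen=True)
class CompositionDefaults:
    """Default physical parameters attached to a lipid mixture."""

    kappa_b: float
    p_multiplier: float = 1.0
    gamma_multiplier: float = 1.0


#: Default rigidity lookup (k_BT) and effect multipliers for the four
#: mixtures studied; ordering (chol stiffens, lyso softens, PE ~ PC) follows
#: the literature, the numbers are package defaults, not measurements.
DEFAULT_COMPOSITIONS: dict[str, CompositionDefaults] = {
    "PC": CompositionDefaults(kappa_b=25.0),
    "PC/chol 7:3": CompositionDefaults(kappa_b=50.0, gamma_multiplier=10.0),
    "PC/lysoPC 7:3": CompositionDefaults(kappa_b=15.0),
    "PC/PE 7:3": CompositionDefaults(kappa_b=25.0, p_multiplier=1.2),
}


@dataclass(frozen=True)
class StudyDesign:
    """The experimental grid plus base physics and noise conditions."""

    compositions: dict[str, CompositionDefaults] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITIONS))
    delta_pi_sweep: tuple[float, ...] = (15.0, 25.0, 50.0, 100.0, 150.0)
    temperatures: tuple[float, ...] = (298.15,)
    solutes: tuple[str, ...] = ("KCl",)
    replicates: int = 3
    master_seed: int = 0
    # base physics
    base_permeability: float = 2e-5   # m/s
    k_mech: float = 1500.0            # mOsm
    vesicle_radius: float = 55e-9     # m (110 nm mean diameter)
    optics: OpticsMap = OpticsMap()
    calibration: DelayCalibration = DelayCalibration()
    dead_time: float = 0.010          # s
    noise_sd: float = 0.02            # a.u.
    grid_step: float = 1e-3           # s
    grid_span: float = 1.0            # s
    # flicker
    guv_radius_um: float = 10.0
    sigma_bar: float = 5.0
    flicker_frames: int = 10000
    flicker_rendered_frames: int = 60
    flicker_n_angles: int = 128
    flicker_l_max: int = 30
    # proton
    proton_kinetics: ProtonKinetics = ProtonKinetics()
    proton_coupling: FluxCoupling = FluxCoupling()
    proton_noise_sd: float = 0.3      # a.u.

    @classmethod
    def ci(cls, master_seed: int = 0) -> "StudyDesign":
        """Reduced profile keeping a full-suite run fast on one CPU."""
        return cls(master_seed=master_seed,
                   delta_pi_sweep=(15.0, 50.0, 150.0),
                   replicates=1, flicker_frames=500)

    @classmethod
    def full(cls, master_seed: int = 0) -> "StudyDesign":
        return cls(master_seed=master_seed)


def derive_seed(master_seed: int, label: str) -> int:
    """Deterministic per-condition seed below 2^31."""
    crc = zlib.crc32(label.encode())
    return (master_seed * 1_000_003 + crc) % (2**31)


def _slug(label: str) -> str:
    return label.replace("/", "-").replace(" ", "_").replace(":", "")


def make_shrinkage_dataset(design: StudyDesign, out_dir) -> dict:
    """Write one trace file per grid cell plus a manifest; returns manifest."""
    from .io import write_trace

    out = Path(out_dir) / "shrinkage"
    out.mkdir(parents=True, exist_ok=True)
    vesicle = VesicleState.from_radius(design.vesicle_radius)
    times = np.arange(0.0, design.grid_span + design.grid_step / 2, design.grid_step)
    entries = []
    for label, comp in design.compositions.items():
        mech_by_t = {}
        for temp in design.temperatures:
            mech_by_t[temp] = MembraneMechanics(kappa_b=comp.kappa_b, temperature=temp)
        gamma = design.optics.gamma * comp.gamma_multiplier
        optics = OpticsMap(i_00=design.optics.i_00, i_0fin=design.optics.i_0fin,
                           gamma=gamma)
        p = design.base_permeability * comp.p_multiplier
        for dpi in design.delta_pi_sweep:
            for temp in design.temperatures:
                for solute in design.solutes:
                    for rep in range(design.replicates):
                        cond = OsmoticCondition(delta_pi=dpi, solute=solute)
                        delay = pore_delay_time(cond, mech_by_t[temp],
                                                design.calibration,
                                                dead_time=design.dead_time)
                        phys = ShrinkagePhysics(permeability=p, t0=delay.t0,
                                                k_mech=design.k_mech)
                        # the solute label must not perturb the draw
                        seed = derive_seed(design.master_seed,
                                           f"shrink|{label}|{dpi}|{temp}|{rep}")
                        trace = simulate_trace(
                            vesicle, phys, cond, optics, times,
                            dead_time=design.dead_time,
                            noise_sd=design.noise_sd, seed=seed,
                            composition=label, temperature=temp)
                        name = (f"{_slug(label)}_dpi{dpi:g}_T{temp:g}"
                                f"_{solute}_r{rep}.tsv")
                        write_trace(trace, out / name)
                        entries.append({
                            "file": f"shrinkage/{name}",
                            "composition": label,
                            "solute": solute,
                            "replicate": rep,
                            "delta_pi_mosm": float(dpi),
                            "temperature_k": float(temp),
                            "t0_s": float(delay.t0),
                            "t0_resolvable": bool(delay.resolvable),
                            "permeability_m_per_s": float(p),
                            "kappa_b_kbt": float(comp.kappa_b),
                            "gamma_au": float(gamma),
                            "k_mech_mosm": float(design.k_mech),
                            "noise_sd_au": float(design.noise_sd),
                            "seed": int(seed),
                        })
    manifest = {
        "note": "composition effects are defaults, not measurements",
        "kind": "shrinkage",
        "n_files": len(entries),
        "vesicle_radius_m": design.vesicle_radius,
        "dead_time_s": design.dead_time,
        "entries": entries,
    }
    _write_manifest(manifest, out / "manifest.yaml")
    return manifest


def make_flicker_dataset(design: StudyDesign, out_dir, render: bool = True) -> dict:
    """Contour tables (all frames) and short rendered TIFF stacks per mixture."""
    from .io import write_contour_table, write_frame_stack

    out = Path(out_dir) / "flicker"
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for label, comp in design.compositions.items():
        seed = derive_seed(design.master_seed, f"flicker|{label}")
        contours = generate_contours(
            mean_radius=design.guv_radius_um, mech=comp.kappa_b,
            sigma_bar=design.sigma_bar, n_frames=design.flicker_frames,
            n_angles=design.flicker_n_angles, l_max=design.flicker_l_max,
            seed=seed)
        table = f"{_slug(label)}_contours.tsv"
        write_contour_table(contours, out / table)
        entry = {
            "contour_table": f"flicker/{table}",
            "composition": label,
            "kappa_b_kbt": float(comp.kappa_b),
            "sigma_bar": float(design.sigma_bar),
            "mean_radius_um": float(design.guv_radius_um),
            "n_frames": int(design.flicker_frames),
            "seed": int(seed),
        }
        if render and design.flicker_rendered_frames > 0:
            n_r = min(design.flicker_rendered_frames, design.flicker_frames)
            sub = generate_contours(
                mean_radius=design.guv_radius_um, mech=comp.kappa_b,
                sigma_bar=design.sigma_bar, n_frames=n_r,
                n_angles=design.flicker_n_angles, l_max=design.flicker_l_max,
                seed=seed)
            stack = render_frames(sub, seed=derive_seed(design.master_seed,
                                                        f"render|{label}"))
            tif = f"{_slug(label)}_stack.tif"
            write_frame_stack(stack, out / tif)
            entry["image_stack"] = f"flicker/{tif}"
            entry["rendered_frames"] = int(n_r)
        entries.append(entry)
    manifest = {
        "note": "composition effects are defaults, not measurements",
        "kind": "flicker",
        "pixel_size_um": 0.102,
        "entries": entries,
    }
    _write_manifest(manifest, out / "manifest.yaml")
    return manifest


#: The canonical six proton-flux conditions: (delta_ph, delta_pi, solute).
PROTON_CONDITIONS: tuple[tuple[float, float, str], ...] = (
    (0.0, 0.0, "none"),
    (0.0, 15.0, "KCl"),
    (0.0, 15.0, "sucrose"),
    (1.4, 0.0, "KCl"),
    (1.4, 15.0, "KCl"),
    (1.4, 150.0, "KCl"),
)


def make_proton_dataset(design: StudyDesign, out_dir) -> dict:
    """Six fluorescence traces replicating the canonical condition set."""
    from .io import write_trace

    out = Path(out_dir) / "proton"
    out.mkdir(parents=True, exist_ok=True)
    times = np.arange(0.0, 160.0, 0.2)
    entries = []
    for idx, (dph, dpi, solute) in enumerate(PROTON_CONDITIONS, start=1):
        cond = OsmoticCondition(delta_pi=dpi, delta_ph=dph, solute=solute)
        seed = derive_seed(design.master_seed, f"proton|{idx}|{dph}|{dpi}")
        trace = simulate_fluorescence(design.proton_kinetics, cond,
                                      design.proton_coupling, times=times,
                                      noise_sd=design.proton_noise_sd, seed=seed)
        name = f"curve{idx}_dph{dph:g}_dpi{dpi:g}.tsv"
        write_trace(trace, out / name)
        entries.append({
            "file": f"proton/{name}",
            "curve": idx,
            "delta_ph": float(dph),
            "delta_pi_mosm": float(dpi),
            "solute": solute,
            "m_slow_au_per_s": float(slow_slope(design.proton_kinetics,
                                                design.proton_coupling, dph, dpi)),
            "noise_sd_au": float(design.proton_noise_sd),
            "seed": int(seed),
        })
    manifest = {
        "note": "composition effects are defaults, not measurements",
        "kind": "proton",
        "entries": entries,
    }
    _write_manifest(manifest, out / "manifest.yaml")
    return manifest


def make_all(design: StudyDesign, out_dir, render: bool = True) -> dict:
    """Generate the full bundle; returns the combined manifest."""
    combined = {
        "master_seed": design.master_seed,
        "shrinkage": make_shrinkage_dataset(design, out_dir),
        "flicker": make_flicker_dataset(design, out_dir, render=render),
        "proton": make_proton_dataset(design, out_dir),
    }
    _write_manifest(combined, Path(out_dir) / "manifest.yaml")
    return combined


def _write_manifest(manifest: dict, path: Path) -> None:
    path.write_text(yaml.safe_dump(manifest, sort_keys=True))
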