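"""Readers and writers for trace files, contour tables, image stacks, config.

Trace files are delimited text with '#'-prefixed metadata header lines and
two columns (time_s, intensity_au).  All numbers are written with 17
significant digits so that write -> read -> write is bit-exact — fixture
bundles are hashable.  Every physical quantity carries an explicit unit
suffix in its key name.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import OsmoticCondition
from .exceptions import FormatError, SchemaError
from .flicker import ContourSeries, FrameStack
from .proton import FluorescenceTrace
from .shrinkage import Trace

__all__ = [
    "read_trace",
    "write_trace",
    "read_fluorescence_trace",
    "write_contour_table",
    "read_contour_table",
    "write_frame_stack",
    "read_frame_stack",
    "RunConfig",
    "load_config",
]

_MAGIC = "# osmoflux-trace v1"
_FMT = "%.17g"

_SCATTER_KEYS = ("delta_pi_mosm", "delta_ph", "dead_time_s", "temperature_k",
                 "composition", "solute")
_FLUOR_KEYS = ("delta_pi_mosm", "delta_ph", "solute")


def _fmt(x: float) -> str:
    return _FMT % x


def write_trace(trace: Trace | FluorescenceTrace, path) -> None:
    """Write a scattering or fluorescence trace as delimited text."""
    buf = _io.StringIO()
    buf.write(_MAGIC + "\n")
    if isinstance(trace, Trace):
        buf.write("# kind: scattering\n")
        buf.write(f"# composition: {trace.composition}\n")
        buf.write(f"# solute: {trace.condition.solute}\n")
        buf.write(f"# delta_pi_mosm: {_fmt(trace.condition.delta_pi)}\n")
        buf.write(f"# delta_ph: {_fmt(trace.condition.delta_ph)}\n")
        buf.write(f"# dead_time_s: {_fmt(trace.dead_time)}\n")
        buf.write(f"# temperature_k: {_fmt(trace.temperature)}\n")
    elif isinstance(trace, FluorescenceTrace):
        buf.write("# kind: fluorescence\n")
        buf.write(f"# solute: {trace.solute}\n")
        buf.write(f"# delta_pi_mosm: {_fmt(trace.delta_pi)}\n")
        buf.write(f"# delta_ph: {_fmt(trace.delta_ph)}\n")
    else:
        raise FormatError(f"cannot serialise object of type {type(trace)!r}")
    buf.write(f"# seed: {'none' if trace.seed is None else trace.seed}\n")
    buf.write("# columns: time_s intensity_au\n")
    for t, y in zip(trace.times, trace.intensities):
        buf.write(f"{_fmt(t)}\t{_fmt(y)}\n")
    Path(path).write_text(buf.getvalue())


def _parse_header(lines: list[str], path) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in lines:
        body = line[1:].strip()
        if ":" not in body:
            continue
        key, _, value = body.partition(":")
        meta[key.strip()] = value.strip()
    return meta


def read_trace(path) -> Trace | FluorescenceTrace:
    """Read a trace file; the header's ``kind`` selects the return type."""
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines or lines[0].strip() != _MAGIC:
        raise FormatError(f"{path}: not an osmoflux trace file")
    header = [ln for ln in lines if ln.startswith("#")]
    data_lines = [ln for ln in lines if ln and not ln.startswith("#")]
    meta = _parse_header(header, path)
    kind = meta.get("kind", "scattering")
    required = _FLUOR_KEYS if kind == "fluorescence" else _SCATTER_KEYS
    for key in required:
        if key not in meta:
            raise SchemaError(f"{path}: missing metadata key {key!r}")
    try:
        data = np.array([[float(v) for v in ln.split()] for ln in data_lines])
    except ValueError as exc:
        raise FormatError(f"{path}: malformed data line: {exc}") from exc
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] == 0:
        raise FormatError(f"{path}: expected two data columns")
    times, intens = data[:, 0], data[:, 1]
    if times.size >= 2 and not np.all(np.diff(times) > 0):
        raise FormatError(f"{path}: time column not strictly increasing")
    seed_raw = meta.get("seed", "none")
    seed = None if seed_raw == "none" else int(seed_raw)
    if kind == "fluorescence":
        return FluorescenceTrace(
            times=times, intensities=intens,
            delta_ph=float(meta["delta_ph"]),
            delta_pi=float(meta["delta_pi_mosm"]),
            solute=meta["solute"], seed=seed,
        )
    cond = OsmoticCondition(delta_pi=float(meta["delta_pi_mosm"]),
                            delta_ph=float(meta["delta_ph"]),
                            solute=meta["solute"])
    return Trace(times=times, intensities=intens, condition=cond,
                 composition=meta["composition"],
                 dead_time=float(meta["dead_time_s"]),
                 temperature=float(meta["temperature_k"]), seed=seed)


def read_fluorescence_trace(path) -> FluorescenceTrace:
    trace = read_trace(path)
    if not isinstance(trace, FluorescenceTrace):
        raise FormatError(f"{path}: expected a fluorescence trace")
    return trace


def write_contour_table(contours: ContourSeries, path) -> None:
    """Contour table: one row per (frame, angle) with a per-frame flag."""
    buf = _io.StringIO()
    buf.write("# osmoflux-contours v1\n")
    buf.write(f"# mean_radius_um: {_fmt(contours.mean_radius)}\n")
    buf.write(f"# pixel_size_um: {_fmt(contours.pixel_size)}\n")
    buf.write(f"# n_frames: {contours.n_frames}\n")
    buf.write(f"# n_angles: {contours.angles.size}\n")
    buf.write("# columns: frame angle_rad radius_um flag\n")
    for k in range(contours.n_frames):
        flag = int(contours.mask[k])
        for a, r in zip(contours.angles, contours.radii[k]):
            buf.write(f"{k}\t{_fmt(a)}\t{_fmt(r)}\t{flag}\n")
    Path(path).write_text(buf.getvalue())


def read_contour_table(path) -> ContourSeries:
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines or lines[0].strip() != "# osmoflux-contours v1":
        raise FormatError(f"{path}: not an osmoflux contour table")
    meta = _parse_header([ln for ln in lines if ln.startswith("#")], path)
    for key in ("mean_radius_um", "pixel_size_um", "n_frames", "n_angles"):
        if key not in meta:
            raise SchemaError(f"{path}: missing metadata key {key!r}")
    n_frames, n_angles = int(meta["n_frames"]), int(meta["n_angles"])
    rows = [ln.split() for ln in lines if ln and not ln.startswith("#")]
    if len(rows) != n_frames * n_angles:
        raise FormatError(f"{path}: row count mismatch")
    angles = np.array([float(r[1]) for r in rows[:n_angles]])
    radii = np.array([float(r[2]) for r in rows]).reshape(n_frames, n_angles)
    flags = np.array([int(rows[k * n_angles][3]) for k in range(n_frames)], dtype=bool)
    return ContourSeries(mean_radius=float(meta["mean_radius_um"]), angles=angles,
                         radii=radii, pixel_size=float(meta["pixel_size_um"]),
                         flags=flags)


def write_frame_stack(stack: FrameStack, path) -> None:
    """Multi-page TIFF with the pixel size recorded in the resolution tag."""
    import tifffile

    res = 1.0 / stack.pixel_size  # pixels per micrometre
    tifffile.imwrite(
        Path(path),
        np.clip(stack.frames, 0, 65535).astype(np.uint16),
        resolution=(res, res),
        datetime=False,  # keep regenerated bundles byte-identical
        metadata={"unit": "um", "center_row": stack.center[0],
                  "center_col": stack.center[1]},
    )


def read_frame_stack(path, pixel_size: float | None = None) -> FrameStack:
    import tifffile

    with tifffile.TiffFile(Path(path)) as tif:
        frames = tif.asarray().astype(float)
        if frames.ndim == 2:
            frames = frames[None]
        if pixel_size is None:
            tags = tif.pages[0].tags
            xres = tags["XResolution"].value
            pixel_size = xres[1] / xres[0]
    center = ((frames.shape[1] - 1) / 2.0, (frames.shape[2] - 1) / 2.0)
    return FrameStack(frames=frames, pixel_size=float(pixel_size), center=center)


_TOP_KEYS = {"master_seed", "profile", "log_level", "paths", "design", "estimators"}
_ESTIMATOR_KEYS = {"smooth_window", "rise_fraction", "flicker_n_min",
                   "flicker_n_max", "flicker_l_max", "bootstrap_count",
                   "proton_window_start_s", "proton_window_end_s"}
_DESIGN_KEYS = {"delta_pi_sweep_mosm", "temperatures_k", "solutes",
                "replicates", "noise_sd_au", "flicker_frames",
                "flicker_rendered_frames", "compositions"}


@dataclass
class RunConfig:
    """Validated run configuration (unknown keys are rejected)."""

    master_seed: int = 0
    profile: str = "ci"
    log_level: str = "INFO"
    paths: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)
    estimators: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    for section, allowed in (("estimators", _ESTIMATOR_KEYS), ("design", _DESIGN_KEYS)):
        extra = set(raw.get(section, {}) or {}) - allowed
        if extra:
            raise SchemaError(f"{path}: unknown {section} keys {sorted(extra)}")
    return RunConfig(**raw)
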