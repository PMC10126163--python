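"""File I/O: multi-page float TIFF stacks, JSON sidecars, profile CSVs.

Knife-edge sets travel as 5-page 32-bit float TIFFs in the fixed page order
Ix+, Ix-, Iy+, Iy-, B with a JSON sidecar holding the acquisition metadata
(wavelength_um, pixel_um, gain, cf).  Reconstructed fields use 2-page TIFFs
(amplitude, phase).  ALS and correlation curves serialize to two-column CSV
with '#'-prefixed metadata header lines.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .exceptions import StructuralError
from .phase_field import ComplexField, KnifeEdgeSet
from .scattering import ALSProfile, CorrelationCurve

__all__ = [
    "save_knife_edge",
    "load_knife_edge",
    "save_field",
    "load_field",
    "save_profile_csv",
    "load_profile_csv",
]

_SIDECAR_DEFAULTS = {"wavelength_um": 1.064, "pixel_um": 0.2, "gain": 1.0, "cf": 1.0}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def save_knife_edge(path, ke: KnifeEdgeSet, meta: dict | None = None) -> None:
    path = Path(path)
    stack = np.stack(
        [ke.ix_plus, ke.ix_minus, ke.iy_plus, ke.iy_minus, ke.background]
    ).astype(np.float32)
    tifffile.imwrite(path, stack)
    sidecar = dict(_SIDECAR_DEFAULTS)
    sidecar.update(meta or {})
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_knife_edge(path) -> tuple[KnifeEdgeSet, dict]:
    path = Path(path)
    stack = np.asarray(tifffile.imread(path), dtype=float)
    if stack.ndim != 3 or stack.shape[0] != 5:
        raise StructuralError(
            f"{path}: expected a 5-page stack (Ix+, Ix-, Iy+, Iy-, B), got {stack.shape}"
        )
    ke = KnifeEdgeSet(
        ix_plus=stack[0], ix_minus=stack[1],
        iy_plus=stack[2], iy_minus=stack[3], background=stack[4],
    )
    sc = _sidecar_path(path)
    meta = dict(_SIDECAR_DEFAULTS)
    if sc.exists():
        meta.update(json.loads(sc.read_text()))
    return ke, meta


def save_field(path, field_: ComplexField) -> None:
    path = Path(path)
    stack = np.stack([field_.amplitude, field_.phase]).astype(np.float32)
    tifffile.imwrite(path, stack)
    meta = {
        "wavelength_um": field_.wavelength_um,
        "pixel_um": field_.pixel_um,
        "pages": ["amplitude", "phase"],
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_field(path) -> ComplexField:
    path = Path(path)
    stack = np.asarray(tifffile.imread(path), dtype=float)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise StructuralError(
            f"{path}: expected a 2-page stack (amplitude, phase), got {stack.shape}"
        )
    meta = dict(_SIDECAR_DEFAULTS)
    sc = _sidecar_path(path)
    if sc.exists():
        meta.update(json.loads(sc.read_text()))
    return ComplexField(
        amplitude=stack[0],
        phase=stack[1],
        wavelength_um=float(meta["wavelength_um"]),
        pixel_um=float(meta["pixel_um"]),
    )


def save_profile_csv(path, obj, meta: dict | None = None) -> None:
    """Write an ALSProfile (q, s) or CorrelationCurve (r, c) as CSV."""
    path = Path(path)
    lines = []
    header_meta = dict(meta or {})
    if isinstance(obj, ALSProfile):
        header_meta.setdefault("wavelength_um", obj.wavelength_um)
        header_meta.setdefault("bin_width", obj.meta.get("bin_width"))
        cols, a, b = ("q_rad_per_um", "s"), obj.q, obj.s
    elif isinstance(obj, CorrelationCurve):
        header_meta.setdefault("pixel_um", obj.pixel_um)
        cols, a, b = ("r_um", "c"), obj.r, obj.c
    else:
        raise StructuralError(f"cannot serialize {type(obj).__name__}")
    for k in sorted(header_meta):
        lines.append(f"# {k} = {header_meta[k]}")
    lines.append(",".join(cols))
    lines.extend(f"{x:.12g},{y:.12g}" for x, y in zip(a, b))
    path.write_text("\n".join(lines) + "\n")


def load_profile_csv(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a two-column profile CSV back: (x, y, metadata)."""
    meta: dict = {}
    xs, ys = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            k, _, v = line[1:].partition("=")
            meta[k.strip()] = v.strip()
        elif line[0].isalpha():
            continue  # column header
        else:
            x, y = line.split(",")
            xs.append(float(x))
            ys.append(float(y))
    return np.asarray(xs), np.asarray(ys), meta
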