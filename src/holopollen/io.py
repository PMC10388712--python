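"""File plumbing: TIFF images with metadata sidecars, measurement CSVs.

Holograms are stored as uint16 TIFF with a JSON sidecar recording the
intensity scale (physical = stored * scale) and acquisition metadata;
phase maps as float32 TIFF with wrapped/unwrapped state in the sidecar.
Measurements round-trip through a CSV with a fixed column order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .morphometry import PollenMeasurement
from .phase import PhaseMap, PhaseState
from .simulate import Hologram, OpticsMeta

__all__ = [
    "SchemaError",
    "read_hologram",
    "write_hologram",
    "read_phase",
    "write_phase",
    "read_measurements",
    "write_measurements",
]


class SchemaError(ValueError):
    """A CSV is missing required columns."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _read_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar: expected {sidecar}")
    return json.loads(sidecar.read_text())


def _meta_from_dict(d: dict) -> OpticsMeta:
    return OpticsMeta(**d)


def write_hologram(path: str | Path, hologram: Hologram) -> Path:
    """Write a hologram as scaled uint16 TIFF + JSON metadata sidecar."""
    path = Path(path)
    vmax = float(hologram.values.max())
    scale = vmax / 65535.0 if vmax > 0 else 1.0
    stored = np.round(hologram.values / scale).astype(np.uint16)
    tifffile.imwrite(path, stored)
    sidecar = {
        "kind": "hologram",
        "scale": scale,
        "noise_sd": hologram.noise_sd,
        "meta": hologram.meta.to_dict(),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_hologram(path: str | Path) -> Hologram:
    """Read a hologram written by :func:`write_hologram`."""
    path = Path(path)
    sidecar = _read_sidecar(path)
    stored = tifffile.imread(path).astype(np.float64)
    values = stored * float(sidecar.get("scale", 1.0))
    return Hologram(
        values=values,
        meta=_meta_from_dict(sidecar.get("meta", {})),
        noise_sd=float(sidecar.get("noise_sd", 0.0)),
    )


def write_phase(path: str | Path, phase: PhaseMap) -> Path:
    """Write a phase map as float32 TIFF + JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, phase.values.astype(np.float32))
    sidecar = {"kind": "phase", "state": phase.state.value, "meta": phase.meta.to_dict()}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_phase(path: str | Path) -> PhaseMap:
    """Read a phase map written by :func:`write_phase` (float32 values)."""
    path = Path(path)
    sidecar = _read_sidecar(path)
    values = tifffile.imread(path)
    return PhaseMap(
        values=values,
        state=PhaseState(sidecar["state"]),
        meta=_meta_from_dict(sidecar.get("meta", {})),
    )


def write_measurements(path: str | Path, measurements: Sequence[PollenMeasurement]) -> Path:
    """Write per-grain measurements as CSV in the canonical column order."""
    path = Path(path)
    cols = list(PollenMeasurement.CSV_COLUMNS)
    rows = [{c: getattr(m, c) for c in cols} for m in measurements]
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, index=False)
    return path


def read_measurements(path: str | Path) -> list[PollenMeasurement]:
    """Read a measurements CSV, validating the required columns."""
    df = pd.read_csv(Path(path))
    missing = [c for c in PollenMeasurement.CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"measurement CSV missing required columns: {missing}")
    out: list[PollenMeasurement] = []
    for _, row in df.iterrows():
        def _opt(v):
            return None if pd.isna(v) else str(v)

        out.append(
            PollenMeasurement(
                id=str(row["id"]),
                area_px2=float(row["area_px2"]),
                area_um2=float(row["area_um2"]),
                perimeter_px=float(row["perimeter_px"]),
                perimeter_um=float(row["perimeter_um"]),
                mean_phase=float(row["mean_phase"]),
                optical_volume=float(row["optical_volume"]),
                stain_label=_opt(row["stain_label"]),
                phase_label=_opt(row["phase_label"]),
                overlap_flag=bool(row["overlap_flag"]),
                discordant_flag=bool(row["discordant_flag"]),
            )
        )
    return out
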