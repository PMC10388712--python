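"""End-to-end pipeline: simulate → reconstruct → unwrap → measure → classify.

A single ``PipelineConfig`` (YAML-serializable, unknown keys rejected)
drives every stage; one master seed fans out to per-stage seeds through
``numpy.random.SeedSequence(master, spawn_key=(stage_index,))`` so each
stage is individually reproducible. All artifacts land under one run
directory together with a manifest recording the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .classify import classify_population
from .morphometry import PollenMeasurement, measure_pollen, segment_pollen
from .phase import remove_background, unwrap_tie, wrap_phase
from .reconstruct import OptimConfig, estimate_reference, fourier_reconstruct, sparse_reconstruct
from .simulate import Hologram, OpticsMeta, generate_population

__all__ = [
    "SimulationConfig",
    "ReconstructionConfig",
    "SegmentationConfig",
    "ClassifyConfig",
    "PipelineConfig",
    "run_pipeline",
    "stage_seed",
]

logger = logging.getLogger(__name__)

_STAGE_INDEX = {"simulate": 0, "reconstruct": 1, "phase": 2, "measure": 3, "classify": 4}


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive the per-stage integer seed from the master seed.

    Uses ``SeedSequence(master, spawn_key=(stage_index,))``; the returned
    value is below 2**31.
    """
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(_STAGE_INDEX[stage],))
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def _from_dict(cls, data: dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            v = _from_dict(f.type, v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass(frozen=True)
class SimulationConfig:
    n: int = 508
    viable_fraction: float = 0.5
    mean_phase_centers: tuple[float, float] = (8.72, 4.26)
    mean_phase_sd: float = 0.8
    radius_range: tuple[float, float] = (80.0, 100.0)
    image_size: int = 256
    noise_sd: float = 0.05
    tilt: tuple[float, float] = (0.125, 0.125)
    reference_amplitude: float = 1.0
    texture_sd: float = 0.0
    edge_sigma_px: float = 1.0


@dataclass(frozen=True)
class ReconstructionConfig:
    method: str = "sparse"  # or "fourier"
    filter_radius: float = 1.0 / 16.0
    estimate_reference: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("sparse", "fourier"):
            raise ValueError("reconstruction method must be 'sparse' or 'fourier'")


@dataclass(frozen=True)
class SegmentationConfig:
    # a low fixed threshold keeps the full grain footprint; Otsu on a
    # single-grain ROI bisects the dome and clips the low-phase skirt
    threshold_mode: str = "fixed"
    threshold_value: float = 0.5
    min_area_fraction: float = 0.01  # of the ROI pixel count


@dataclass(frozen=True)
class ClassifyConfig:
    band_halfwidth: float | None = None  # default: half the pooled class sd


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    optics: OpticsMeta = field(default_factory=OpticsMeta)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    optim: OptimConfig = field(default_factory=lambda: OptimConfig(max_iters=120))
    reconstruction: ReconstructionConfig = field(default_factory=ReconstructionConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    save_images: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        def _plain(obj):
            if isinstance(obj, dict):
                return {k: _plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_plain(v) for v in obj]
            return obj

        return yaml.safe_dump(_plain(self.to_dict()), sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sub = {
            "optics": OpticsMeta,
            "simulation": SimulationConfig,
            "optim": OptimConfig,
            "reconstruction": ReconstructionConfig,
            "segmentation": SegmentationConfig,
            "classify": ClassifyConfig,
        }
        kwargs: dict[str, Any] = {}
        for key, val in data.items():
            if key in sub and isinstance(val, dict):
                kwargs[key] = _from_dict(sub[key], val)
            else:
                kwargs[key] = val
        cfg = cls(**kwargs)
        # normalize list-vs-tuple from YAML
        return cfg

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def reconstruct_phase(
    hologram: Hologram,
    config: PipelineConfig,
):
    """Hologram → flattened unwrapped PhaseMap (one grain ROI)."""
    ref = estimate_reference(hologram)
    if config.reconstruction.method == "sparse":
        fld, _trace = sparse_reconstruct(hologram, ref, config.optim)
    else:
        fld = fourier_reconstruct(hologram, ref, config.reconstruction.filter_radius)
    wrapped = wrap_phase(fld, meta=hologram.meta)
    unwrapped = unwrap_tie(wrapped)
    return remove_background(unwrapped)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full simulated-population pipeline.

    Writes ``manifest.json``, ``population.csv`` (ground truth),
    ``measurements.csv``, ``class_stats.csv``, ``report.json`` and a
    mean-phase histogram under ``out_dir``; returns the report dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    sim = config.simulation
    shape = (sim.image_size, sim.image_size)
    logger.info("simulate: n=%d, ROI %s, seed %d", sim.n, shape, config.seed)
    population = generate_population(
        n=sim.n,
        viable_fraction=sim.viable_fraction,
        mean_phase_centers=tuple(sim.mean_phase_centers),
        mean_phase_sd=sim.mean_phase_sd,
        radius_range=tuple(sim.radius_range),
        image_shape=shape,
        noise_sd=sim.noise_sd,
        seed=stage_seed(config.seed, "simulate"),
        tilt=tuple(sim.tilt),
        reference_amplitude=sim.reference_amplitude,
        texture_sd=sim.texture_sd,
        edge_sigma_px=sim.edge_sigma_px,
        meta=config.optics,
    )

    manifest_rows = []
    measurements: list[PollenMeasurement] = []
    min_area = max(16, int(config.segmentation.min_area_fraction * shape[0] * shape[1]))
    for i, (holo, phantom) in enumerate(population):
        pid = f"pollen-{i:04d}"
        manifest_rows.append(
            {
                "id": pid,
                "label": phantom.label.value,
                "center_row": phantom.center[0],
                "center_col": phantom.center[1],
                "radius": phantom.radius,
                "peak_phase": phantom.peak_phase,
                "target_mean_phase": phantom.mask_mean_phase,
                "seed": config.seed,
            }
        )
        if config.save_images:
            hio.write_hologram(out / f"{pid}_hologram.tif", holo)
        flat = reconstruct_phase(holo, config)
        if config.save_images:
            hio.write_phase(out / f"{pid}_phase.tif", flat)
        masks = segment_pollen(
            flat,
            min_area=min_area,
            threshold_mode=config.segmentation.threshold_mode,
            threshold_value=config.segmentation.threshold_value,
        )
        if not masks:
            logger.warning("%s: no grain segmented", pid)
            continue
        # one grain per ROI: keep the largest component
        mask = max(masks, key=lambda m: m.sum())
        meas = measure_pollen(
            mask, flat, meta=config.optics, pollen_id=pid, stain_label=phantom.label
        )
        measurements.append(meas)
    logger.info("measured %d/%d grains in %.1f s", len(measurements), sim.n, time.time() - t0)

    annotated, (stats_v, stats_nv), test = classify_population(
        measurements,
        band_halfwidth=config.classify.band_halfwidth,
        random_state=stage_seed(config.seed, "classify") % (2**31),
    )

    pd.DataFrame(manifest_rows).to_csv(out / "population.csv", index=False)
    hio.write_measurements(out / "measurements.csv", annotated)
    stats_df = pd.DataFrame(
        [dataclasses.asdict(stats_v), dataclasses.asdict(stats_nv)],
        columns=["label", "n", "mean", "sd"],
    )
    stats_df.to_csv(out / "class_stats.csv", index=False)
    _histogram_png(out / "mean_phase_histogram.png", annotated, test.threshold)

    truth = {r["id"]: r["label"] for r in manifest_rows}
    agree = sum(1 for m in annotated if m.phase_label == truth[m.id])
    accuracy = agree / len(annotated) if annotated else float("nan")
    report = {
        "n_simulated": sim.n,
        "n_measured": len(annotated),
        "class_stats": [dataclasses.asdict(stats_v), dataclasses.asdict(stats_nv)],
        "threshold": test.threshold,
        "n_overlap": test.n_overlap,
        "t_statistic": test.t_statistic,
        "degrees_freedom": test.degrees_freedom,
        "p_value": test.p_value,
        "label_accuracy": accuracy,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    (out / "manifest.json").write_text(
        json.dumps({"config_hash": config.config_hash(), "seed": config.seed}, indent=2)
    )
    (out / "config.yaml").write_text(config.to_yaml())
    return report


def _histogram_png(path: Path, measurements, threshold: float | None) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = np.array([m.mean_phase for m in measurements])
    if vals.size == 0:
        return
    viable = np.array([m.phase_label == "viable" for m in measurements])
    # Freedman–Diaconis binning for display only
    iqr = np.subtract(*np.percentile(vals, [75, 25]))
    width = 2 * iqr / max(vals.size, 1) ** (1 / 3) if iqr > 0 else 0.5
    bins = max(int(np.ceil(np.ptp(vals) / max(width, 1e-6))), 5)
    edges = np.histogram_bin_edges(vals, bins=bins)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(vals[~viable], bins=edges, color="tab:blue", alpha=0.7, label="non-viable")
    ax.hist(vals[viable], bins=edges, color="tab:green", alpha=0.7, label="viable")
    if threshold is not None:
        ax.axvline(threshold, color="k", ls="--", lw=1, label="threshold")
    ax.set_xlabel("mean phase (rad)")
    ax.set_ylabel("count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
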