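"""End-to-end orchestration: configuration, run manifests, and the
detect -> register -> track -> segment -> calcium -> trace -> endpoint chain.

Every stage writes plain files (CSV/TIFF/JSON) so any stage can be rerun
independently, and every run writes a :class:`RunManifest` capturing the
config, software version, input checksums and QC counters.  Site-level
failures are collected into the QC report; they never abort the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortModel
from .imaging import (DetectionResult, calcium_series, detect_sensors,
                      register_drift, segment_aggregate, track_post)
from .mechanics import GENERATIONS, DeviceGeneration, PostGeometry
from .synthetic import FrameStack
from .traces import area_trace, endpoint_summary, fov_average

log = logging.getLogger("postforce.pipeline")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "run_cohort_analysis"]


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    generation: str = "gen2"
    custom_geometry: dict | None = None
    pixel_size: float | None = None       # um/px; overrides stack metadata
    frame_interval: float | None = None   # s
    rest_frame: int = 0
    window_factor: float = 3.0
    gaussian_fit: bool = False
    segmentation_channel: str = "calcium"
    endpoint_time: float = 120.0
    output_dir: str = "postforce_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.endpoint_time <= 0:
            raise ValueError("endpoint_time must be positive")
        if self.generation not in GENERATIONS and self.custom_geometry is None:
            raise ValueError(f"unknown device generation {self.generation!r}")
        if self.segmentation_channel not in ("calcium", "phase"):
            raise ValueError("segmentation_channel must be 'calcium' or 'phase'")

    @property
    def geometry(self) -> DeviceGeneration:
        if self.custom_geometry is not None:
            g = self.custom_geometry
            return DeviceGeneration(
                name=g.get("name", "custom"),
                post=PostGeometry(**g["post"]),
                block_footprint=tuple(g["block_footprint"]),
                block_height=g["block_height"],
                array_pitch=g["array_pitch"],
            )
        return GENERATIONS[self.generation]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    """Provenance record written once per run."""

    config: dict
    version: str
    input_checksums: dict[str, str]
    stage_seconds: dict[str, float] = field(default_factory=dict)
    qc: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1,
                                         default=float))


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _input_checksums(directory: Path) -> dict[str, str]:
    return {p.name: _checksum(p) for p in sorted(directory.glob("*"))
            if p.is_file()}


def run_pipeline(config: PipelineConfig, stack: FrameStack | str | Path,
                 output_dir: str | Path | None = None) -> dict:
    """Run the full measurement chain on one movie.

    Returns a result dict with the detection, tracks, masks, traces and the
    endpoint summary; all stage outputs and a manifest are persisted under
    ``output_dir``.
    """
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums = {}
    if not isinstance(stack, FrameStack):
        stack_dir = Path(stack)
        checksums = _input_checksums(stack_dir)
        stack = FrameStack.load(stack_dir)
    if config.pixel_size is not None:
        stack.pixel_size = config.pixel_size
    if config.segmentation_channel == "calcium" and stack.calcium is None:
        raise ValueError("config selects the calcium channel but the stack has none")

    geom = config.geometry
    manifest = RunManifest(config=config.to_dict(), version=__version__,
                           input_checksums=checksums)
    qc: dict = {"site_failures": []}

    t0 = time.perf_counter()
    detection: DetectionResult = detect_sensors(stack.structural[config.rest_frame],
                                                geom, stack.pixel_size)
    manifest.stage_seconds["detect"] = time.perf_counter() - t0
    qc["n_sites"] = len(detection.sites)
    qc["n_unpaired_blocks"] = len(detection.unpaired_blocks)
    qc["n_unpaired_posts"] = len(detection.unpaired_posts)
    if not detection.sites:
        raise ValueError("no sensor sites detected")

    t0 = time.perf_counter()
    offsets = register_drift(stack, detection.sites, geom)
    manifest.stage_seconds["register"] = time.perf_counter() - t0
    qc["residual_drift_px"] = float(np.abs(np.diff(offsets, axis=0)).mean())

    tracks, masks, calcium = [], [], {}
    t0 = time.perf_counter()
    for site in detection.sites:
        try:
            tr = track_post(stack, site, offsets, geom,
                            rest_frame=config.rest_frame,
                            window_factor=config.window_factor,
                            gaussian_fit=config.gaussian_fit)
            tracks.append(tr)
        except Exception as exc:  # isolate failures to sites
            log.exception("tracking failed for site %d", site.site_id)
            qc["site_failures"].append({"site": site.site_id, "stage": "track",
                                        "error": str(exc)})
    manifest.stage_seconds["track"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    has_seg_channel = getattr(stack, config.segmentation_channel, None) is not None
    if has_seg_channel:
        for site in detection.sites:
            try:
                m = segment_aggregate(stack, site, geom,
                                      source=config.segmentation_channel)
                masks.append(m)
                if stack.calcium is not None:
                    calcium[site.site_id] = calcium_series(stack, m)
            except Exception as exc:
                log.exception("segmentation failed for site %d", site.site_id)
                qc["site_failures"].append({"site": site.site_id,
                                            "stage": "segment",
                                            "error": str(exc)})
    manifest.stage_seconds["segment"] = time.perf_counter() - t0

    usable = [t for t in tracks if t.usable]
    qc["n_usable_tracks"] = len(usable)
    if not usable:
        raise ValueError("no usable post tracks")
    trace = fov_average(usable)
    areas = area_trace(masks, stack.timestamps) if masks else None
    t_end = min(config.endpoint_time, float(trace.times[-1]))
    endpoint = endpoint_summary(trace, t=t_end, area=areas)

    # ---- persist ---------------------------------------------------------
    for tr in tracks:
        pd.DataFrame({
            "frame": np.arange(len(tr.times)),
            "time_s": tr.times,
            "x_px": tr.positions[:, 0],
            "y_px": tr.positions[:, 1],
            "deflection_um": tr.deflections,
            "force_nN": tr.forces,
            "valid": tr.valid.astype(int),
        }).to_csv(out / f"track_site{tr.site_id:03d}.csv", index=False)
    trace.to_dataframe().to_csv(out / "force_trace.csv", index=False)
    if areas is not None:
        areas.to_dataframe().rename(
            columns={"mean_force_nN": "mean_area_um2", "sem_nN": "sem_um2"}
        ).to_csv(out / "area_trace.csv", index=False)
    if calcium:
        pd.DataFrame({"time_s": stack.timestamps,
                      **{f"site{k:03d}": v for k, v in calcium.items()}}
                     ).to_csv(out / "calcium.csv", index=False)
    np.savetxt(out / "drift_offsets.csv", offsets, delimiter=",",
               header="dx_px,dy_px", comments="")
    (out / "endpoint.json").write_text(json.dumps({
        "force_nN": endpoint.force_nN,
        "area_um2": endpoint.area_um2,
        "eval_time_s": endpoint.eval_time_s,
    }, default=float))
    manifest.qc = qc
    manifest.save(out / "manifest.json")

    return {"detection": detection, "offsets": offsets, "tracks": tracks,
            "masks": masks, "calcium": calcium, "trace": trace,
            "areas": areas, "endpoint": endpoint, "qc": qc}


def run_cohort_analysis(table: pd.DataFrame | str | Path,
                        outcome: str = "transfused",
                        predictor: str = "force_nN",
                        covariates: list[str] | None = None,
                        output_dir: str | Path | None = None) -> dict:
    """Cohort battery on a subject table; returns and optionally persists a
    JSON-able report plus the human-readable summary."""
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep=None, engine="python")
    model = CohortModel(table, outcome=outcome, predictor=predictor)
    results = model.fit(covariates=covariates)
    report = {
        "groups": results.group_summary.reset_index().to_dict(orient="records"),
        "anova": (None if results.anova is None else {
            "F": results.anova["F"], "p": results.anova["p"],
            "tukey": {f"{a} vs {b}": p
                      for (a, b), p in results.anova["tukey"].items()},
        }),
        "roc": (None if results.roc is None else {
            "auc": results.roc.auc,
            "slope_per_nN": results.roc.slope,
            "unit_odds_ratio": results.roc.unit_odds_ratio,
            "percent_odds_change": results.roc.percent_odds_change,
            "model_p": results.roc.model_p,
        }),
        "multivariate": results.multivariate and {
            "model_p": results.multivariate["model_p"],
            "effects": {k: v["p"] for k, v in
                        results.multivariate["effects"].items()},
        },
    }
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "cohort_report.json").write_text(json.dumps(report, indent=1,
                                                           default=float))
        (out / "cohort_report.txt").write_text(results.summary())
    return {"results": results, "report": report}
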