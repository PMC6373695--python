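"""Persistence of projection series, template banks, traces and reports.

Volumes go to MetaImage (see :mod:`priorphase.volume`); projection stacks to
multi-page float32 TIFF with a CSV sidecar (frame, angle_deg, time_s,
true_phase) and a JSON meta file (source intensity, geometry); template
banks to a directory of TIFFs named ``phase{01..10}_angle{+DDD}.tif`` with a
JSON manifest; traces, match results and assessments to CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import ConeBeamGeometry
from .phantom import RespiratoryTrace
from .projector import ProjectionSeries
from .recognition import ROISpec, TemplateBank

__all__ = [
    "write_projection_series",
    "read_projection_series",
    "write_template_bank",
    "read_template_bank",
    "write_trace_csv",
    "read_trace_csv",
    "write_matches_csv",
    "load_config_file",
    "geometry_to_dict",
    "geometry_from_dict",
]


def geometry_to_dict(geom: ConeBeamGeometry) -> dict:
    return {
        "sad": geom.sad,
        "sdd": geom.sdd,
        "detector_pixels": list(geom.detector_pixels),
        "pixel_pitch": list(geom.pixel_pitch),
        "detector_offset": list(geom.detector_offset),
    }


def geometry_from_dict(d: dict) -> ConeBeamGeometry:
    return ConeBeamGeometry(
        sad=d["sad"],
        sdd=d["sdd"],
        detector_pixels=tuple(d["detector_pixels"]),
        pixel_pitch=tuple(d["pixel_pitch"]),
        detector_offset=tuple(d.get("detector_offset", (0.0, 0.0))),
    )


def write_projection_series(series: ProjectionSeries, stem) -> None:
    """Write ``<stem>.tif``, ``<stem>.csv`` and ``<stem>.json``."""
    stem = Path(stem)
    tifffile.imwrite(stem.with_suffix(".tif"), series.frames.astype(np.float32))
    df = pd.DataFrame(
        {
            "frame": np.arange(len(series)),
            "angle_deg": series.angles,
            "time_s": series.times,
            "true_phase": (
                series.true_phases
                if series.true_phases is not None
                else np.full(len(series), -1)
            ),
        }
    )
    df.to_csv(stem.with_suffix(".csv"), index=False)
    meta = {
        "source_intensity": series.source_intensity,
        "is_log": series.is_log,
        "geometry": None if series.geometry is None else geometry_to_dict(series.geometry),
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_projection_series(stem) -> ProjectionSeries:
    stem = Path(stem)
    frames = tifffile.imread(stem.with_suffix(".tif")).astype(np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    df = pd.read_csv(stem.with_suffix(".csv"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    phases = df["true_phase"].to_numpy()
    return ProjectionSeries(
        frames=frames,
        angles=df["angle_deg"].to_numpy(float),
        times=df["time_s"].to_numpy(float),
        source_intensity=meta["source_intensity"],
        geometry=(
            None if meta["geometry"] is None else geometry_from_dict(meta["geometry"])
        ),
        true_phases=None if (phases < 0).all() else phases.astype(int),
        is_log=meta["is_log"],
    )


def write_template_bank(bank: TemplateBank, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for (phase, angle), img in bank.templates.items():
        name = f"phase{phase:02d}_angle{angle:+04d}.tif"
        tifffile.imwrite(directory / name, img.astype(np.float32))
    manifest = {
        "roi": dataclasses.asdict(bank.roi),
        "source": bank.source,
        "n_phases": bank.n_phases,
        "angles": [int(a) for a in bank.angles],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_template_bank(directory) -> TemplateBank:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    templates = {}
    for phase in range(1, manifest["n_phases"] + 1):
        for angle in manifest["angles"]:
            name = f"phase{phase:02d}_angle{angle:+04d}.tif"
            templates[(phase, int(angle))] = tifffile.imread(directory / name).astype(
                np.float64
            )
    return TemplateBank(
        templates=templates,
        roi=ROISpec(**manifest["roi"]),
        source=manifest["source"],
        n_phases=manifest["n_phases"],
    )


def write_trace_csv(trace: RespiratoryTrace, path, phases=None) -> None:
    df = pd.DataFrame({"time_s": trace.times, "displacement_mm": trace.displacement})
    if phases is not None:
        df["phase"] = np.asarray(phases, dtype=int)
    df.to_csv(path, index=False)


def read_trace_csv(path, period: float = float("nan")) -> RespiratoryTrace:
    df = pd.read_csv(path)
    return RespiratoryTrace(
        times=df["time_s"].to_numpy(float),
        displacement=df["displacement_mm"].to_numpy(float),
        period=period,
        model_name="csv",
    )


def write_matches_csv(results, assessments, path) -> None:
    """Per-frame match results + criteria outcomes as one CSV table."""
    rows = []
    for res, a in zip(results, assessments):
        row = {
            "frame": res.frame_index,
            "angle": res.angle,
            "template_angle": res.template_angle,
        }
        for k, cc in enumerate(res.cc_by_phase, start=1):
            row[f"cc_{k}"] = cc
        row.update(
            {
                "obtained_phase": res.obtained_phase,
                "reference_phase": a.reference_phase,
                "cyclic_distance": a.cyclic_distance,
                "two_phase_ok": a.two_phase_ok,
                "relative_ok": a.relative_ok,
                "final_matched": a.final_matched,
            }
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_config_file(path) -> dict:
    """Load a YAML or JSON run-configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
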