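"""File I/O: NIfTI velocity volumes with JSON sidecars, plane definitions,
and tidy CSV tables for waveforms and flow metrics.

A velocity volume is stored as four 4-dimensional NIfTI-1 files
(``vx.nii.gz``, ``vy.nii.gz``, ``vz.nii.gz``, ``magnitude.nii.gz``, each
``[x, y, z, t]``, velocities in cm/s) plus a JSON sidecar carrying the
acquisition metadata NIfTI has no standard slot for: ``venc_cm_s``,
``frame_duration_ms`` and ``voxel_size_mm``.  The affine lives in the NIfTI
header.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .geometry import FlowPlane
from .quantify import FlowMetrics, FlowWaveform
from .synth import VelocityVolume

__all__ = [
    "write_velocity_volume",
    "read_velocity_volume",
    "write_slice",
    "read_slice",
    "read_planes",
    "write_planes",
    "waveforms_to_frame",
    "metrics_to_frame",
]

_COMPONENTS = ("vx", "vy", "vz", "magnitude")
_SIDECAR = "pcmri.json"


def write_velocity_volume(volume: VelocityVolume, outdir: str | Path, prefix: str = "") -> Path:
    """Write the four NIfTI components and the JSON sidecar into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in _COMPONENTS:
        img = nib.Nifti1Image(np.asarray(getattr(volume, name), dtype=np.float32),
                              affine=volume.affine)
        img.header.set_xyzt_units("mm", "msec")
        nib.save(img, outdir / f"{prefix}{name}.nii.gz")
    sidecar = {
        "venc_cm_s": volume.venc,
        "frame_duration_ms": volume.frame_duration,
        "voxel_size_mm": list(volume.voxel_size),
    }
    (outdir / f"{prefix}{_SIDECAR}").write_text(json.dumps(sidecar, indent=2))
    return outdir


def read_velocity_volume(indir: str | Path, prefix: str = "") -> VelocityVolume:
    """Read a velocity volume written by :func:`write_velocity_volume`.

    Validates that the four components share one shape and affine and that
    the sidecar carries the required fields; the affine is taken from the
    ``vx`` header.
    """
    indir = Path(indir)
    sidecar_path = indir / f"{prefix}{_SIDECAR}"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    missing = [k for k in ("venc_cm_s", "frame_duration_ms", "voxel_size_mm")
               if k not in sidecar]
    if missing:
        raise ValueError(f"sidecar {sidecar_path} missing fields: {', '.join(missing)}")
    if not sidecar["venc_cm_s"] or sidecar["venc_cm_s"] <= 0:
        raise ValueError("sidecar venc_cm_s must be positive")

    arrays, affine, shape = {}, None, None
    for name in _COMPONENTS:
        path = indir / f"{prefix}{name}.nii.gz"
        if not path.exists():
            raise FileNotFoundError(f"missing component file {path}")
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"{path} is not a 4D [x,y,z,t] image")
        if shape is None:
            shape, affine = data.shape, img.affine
        elif data.shape != shape:
            raise ValueError(f"{path} shape {data.shape} does not match vx shape {shape}")
        elif not np.allclose(img.affine, affine, atol=1e-5):
            raise ValueError(f"{path} affine does not match vx affine")
        arrays[name] = data

    return VelocityVolume(
        vx=arrays["vx"], vy=arrays["vy"], vz=arrays["vz"], magnitude=arrays["magnitude"],
        voxel_size=tuple(float(v) for v in sidecar["voxel_size_mm"]),
        venc=float(sidecar["venc_cm_s"]),
        frame_duration=float(sidecar["frame_duration_ms"]),
        affine=np.asarray(affine, dtype=float),
    )


def write_slice(slc, outdir: str | Path, name: str) -> Path:
    """Write an extracted slice: through-plane velocity and magnitude as
    2D+t NIfTI, plane geometry and metadata as JSON."""
    from .geometry import project_velocity

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if slc.v_parallel is None:
        project_velocity(slc)
    eye = np.diag([slc.plane.pixel_size, slc.plane.pixel_size, 1.0, 1.0])
    nib.save(nib.Nifti1Image(slc.v_parallel[:, :, None, :].astype(np.float32), eye),
             outdir / f"{name}_vpar.nii.gz")
    nib.save(nib.Nifti1Image(slc.magnitude[:, :, None, :].astype(np.float32), eye),
             outdir / f"{name}_mag.nii.gz")
    meta = {
        "name": slc.plane.name or name,
        "origin_mm": [float(v) for v in slc.plane.origin],
        "direction": [float(v) for v in slc.plane.u],
        "e1": [float(v) for v in slc.plane.e1],
        "e2": [float(v) for v in slc.plane.e2],
        "fov_mm": [float(v) for v in slc.plane.fov],
        "pixel_mm": float(slc.plane.pixel_size),
        "frame_duration_ms": float(slc.frame_duration),
        "venc_cm_s": None if slc.venc is None else float(slc.venc),
    }
    (outdir / f"{name}_meta.json").write_text(json.dumps(meta, indent=2))
    return outdir


def read_slice(indir: str | Path, name: str):
    """Read a slice written by :func:`write_slice`.

    Only ``v_parallel`` and ``magnitude`` are stored, so the component arrays
    are zero-filled; quantification needs only the stored fields.
    """
    from .geometry import FlowPlane, ObliqueSlice

    indir = Path(indir)
    meta = json.loads((indir / f"{name}_meta.json").read_text())
    vpar = np.asarray(nib.load(str(indir / f"{name}_vpar.nii.gz")).dataobj,
                      dtype=float)[:, :, 0, :]
    mag = np.asarray(nib.load(str(indir / f"{name}_mag.nii.gz")).dataobj,
                     dtype=float)[:, :, 0, :]
    plane = FlowPlane(origin=meta["origin_mm"], u=meta["direction"], e1=meta["e1"],
                      e2=meta["e2"], fov=meta["fov_mm"], pixel_size=meta["pixel_mm"],
                      name=meta["name"])
    zeros = np.zeros_like(vpar)
    return ObliqueSlice(vx=zeros, vy=zeros.copy(), vz=zeros.copy(), magnitude=mag,
                        plane=plane, frame_duration=meta["frame_duration_ms"],
                        venc=meta["venc_cm_s"], v_parallel=vpar)


def write_planes(planes: Sequence[FlowPlane], path: str | Path) -> Path:
    """Write plane definitions to YAML (name, origin_mm, direction, fov_mm,
    pixel_mm)."""
    entries = [
        {
            "name": p.name,
            "origin_mm": [float(v) for v in p.origin],
            "direction": [float(v) for v in p.u],
            "fov_mm": [float(v) for v in p.fov],
            "pixel_mm": float(p.pixel_size),
        }
        for p in planes
    ]
    path = Path(path)
    path.write_text(yaml.safe_dump({"planes": entries}, sort_keys=False))
    return path


def read_planes(path: str | Path) -> list[FlowPlane]:
    """Read plane definitions from YAML or CSV.

    YAML: a ``planes`` list of mappings with name, origin_mm, direction,
    fov_mm, pixel_mm.  CSV: columns name, origin_x/y/z, dir_x/y/z and
    optional fov_mm, pixel_mm.
    """
    path = Path(path)
    planes: list[FlowPlane] = []
    if path.suffix.lower() in (".yaml", ".yml"):
        doc = yaml.safe_load(path.read_text())
        for e in doc["planes"]:
            planes.append(FlowPlane.from_direction(
                origin=e["origin_mm"], direction=e["direction"],
                fov=e.get("fov_mm", (12.0, 12.0)),
                pixel_size=e.get("pixel_mm", 0.5), name=e.get("name", "")))
    else:
        df = pd.read_csv(path)
        for _, row in df.iterrows():
            fov = (row.get("fov_mm", 12.0), row.get("fov_mm", 12.0))
            planes.append(FlowPlane.from_direction(
                origin=[row["origin_x"], row["origin_y"], row["origin_z"]],
                direction=[row["dir_x"], row["dir_y"], row["dir_z"]],
                fov=fov, pixel_size=row.get("pixel_mm", 0.5),
                name=str(row.get("name", ""))))
    return planes


def waveforms_to_frame(waveforms: Sequence[FlowWaveform]) -> pd.DataFrame:
    """Tidy table: vessel, timeframe, time_ms, flow_ml_s."""
    rows = []
    for w in waveforms:
        for k, (t, q) in enumerate(zip(w.times_ms, w.flow)):
            rows.append({"vessel": w.vessel_name, "timeframe": k,
                         "time_ms": float(t), "flow_ml_s": float(q)})
    return pd.DataFrame(rows, columns=["vessel", "timeframe", "time_ms", "flow_ml_s"])


def metrics_to_frame(metrics: Sequence[FlowMetrics]) -> pd.DataFrame:
    """Tidy table: vessel, mean_flow_ml_s, flow_max/min, pi, lumen_area_mm2."""
    rows = [
        {
            "vessel": m.vessel_name,
            "mean_flow_ml_s": m.mean_flow,
            "flow_max_ml_s": m.flow_max,
            "flow_min_ml_s": m.flow_min,
            "pi": m.pi,
            "lumen_area_mm2": m.lumen_area,
        }
        for m in metrics
    ]
    return pd.DataFrame(rows, columns=["vessel", "mean_flow_ml_s", "flow_max_ml_s",
                                       "flow_min_ml_s", "pi", "lumen_area_mm2"])
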