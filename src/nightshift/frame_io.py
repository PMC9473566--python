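"""On-disk frame exchange: TIFF counts/radiance + JSON metadata sidecar.

One acquisition is a pair ``<frame_id>.tif`` / ``<frame_id>.json``.  The
sidecar carries acquisition metadata, the grid definition, ground control
points, and (synthetic mode) the known reference-source fluxes needed for
photometric calibration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .calibration import Frame
from .raster import Affine, GridGeometry
from .scene import AcquisitionGeometry, RawFrame

__all__ = ["write_raw_frame", "read_raw_frame", "write_cal_frame", "read_cal_frame", "list_frames"]


def _geom_doc(geom: AcquisitionGeometry) -> dict:
    return {
        "angle_deg": geom.angle_deg,
        "focal_mm": geom.focal_mm,
        "center_rowcol": list(geom.center_rowcol),
        "timestamp": geom.timestamp,
        "exposure_s": geom.exposure_s,
        "iso": geom.iso,
        "frame_shape": list(geom.frame_shape),
        "frame_id": geom.frame_id,
    }


def _geom_from_doc(doc: dict) -> AcquisitionGeometry:
    return AcquisitionGeometry(
        angle_deg=doc["angle_deg"],
        focal_mm=doc["focal_mm"],
        center_rowcol=tuple(doc["center_rowcol"]),
        timestamp=doc["timestamp"],
        exposure_s=doc["exposure_s"],
        iso=doc["iso"],
        frame_shape=tuple(doc["frame_shape"]),
        frame_id=doc["frame_id"],
    )


def _grid_doc(grid: GridGeometry) -> dict:
    return {"crs": grid.crs, "transform": grid.transform.to_list(), "shape": list(grid.shape)}


def _grid_from_doc(doc: dict) -> GridGeometry:
    return GridGeometry(doc["crs"], Affine(*doc["transform"]), tuple(doc["shape"]))


def write_raw_frame(raw: RawFrame, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fid = raw.geometry.frame_id
    tifffile.imwrite(str(out_dir / f"{fid}.tif"), raw.counts.astype(np.float32), photometric="minisblack")
    sidecar = {
        "kind": "raw",
        "geometry": _geom_doc(raw.geometry),
        "window": list(raw.window),
        "grid": _grid_doc(raw.grid),
        "control_points": raw.control_points.tolist(),
        "sources": [
            [int(r), int(c), np.asarray(f).tolist()]
            for r, c, f in raw.truth.get("sources", [])
        ],
    }
    with open(out_dir / f"{fid}.json", "w") as fh:
        json.dump(sidecar, fh)
    return out_dir / f"{fid}.tif"


def read_raw_frame(out_dir, frame_id: str) -> RawFrame:
    out_dir = Path(out_dir)
    counts = tifffile.imread(str(out_dir / f"{frame_id}.tif")).astype(float)
    with open(out_dir / f"{frame_id}.json") as fh:
        doc = json.load(fh)
    if doc.get("kind") != "raw":
        raise ValueError(f"{frame_id}: not a raw frame")
    return RawFrame(
        counts=counts,
        geometry=_geom_from_doc(doc["geometry"]),
        window=tuple(doc["window"]),
        control_points=np.asarray(doc["control_points"], dtype=float),
        grid=_grid_from_doc(doc["grid"]),
        truth={"sources": [(r, c, np.asarray(f)) for r, c, f in doc["sources"]]},
    )


def write_cal_frame(frame: Frame, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fid = frame.geometry.frame_id
    stack = np.concatenate(
        [frame.values, frame.valid[None].astype(float), frame.reasons[None].astype(float)]
    )
    tifffile.imwrite(str(out_dir / f"{fid}.tif"), stack.astype(np.float32), photometric="minisblack")
    sidecar = {
        "kind": "calibrated",
        "units": frame.units,
        "geometry": _geom_doc(frame.geometry),
        "window": list(frame.window),
        "grid": _grid_doc(frame.grid),
        "control_points": frame.control_points.tolist(),
        "log": {k: v for k, v in frame.log.items() if _jsonable(v)},
    }
    with open(out_dir / f"{fid}.json", "w") as fh:
        json.dump(sidecar, fh)
    return out_dir / f"{fid}.tif"


def read_cal_frame(out_dir, frame_id: str) -> Frame:
    out_dir = Path(out_dir)
    stack = tifffile.imread(str(out_dir / f"{frame_id}.tif")).astype(float)
    with open(out_dir / f"{frame_id}.json") as fh:
        doc = json.load(fh)
    if doc.get("kind") != "calibrated":
        raise ValueError(f"{frame_id}: not a calibrated frame")
    return Frame(
        values=stack[:3],
        valid=stack[3].astype(bool),
        reasons=np.round(stack[4]).astype(np.uint8),
        geometry=_geom_from_doc(doc["geometry"]),
        window=tuple(doc["window"]),
        grid=_grid_from_doc(doc["grid"]),
        control_points=np.asarray(doc["control_points"], dtype=float),
        units=doc["units"],
        log=dict(doc.get("log", {})),
    )


def list_frames(out_dir) -> list[str]:
    return sorted(p.stem for p in Path(out_dir).glob("*.json"))


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
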