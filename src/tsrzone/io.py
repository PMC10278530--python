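"""Readers and writers for the pipeline's artifacts.

Rasters: TIFF (calibrated images, with resolution tags) and PNG (masks,
0/255).  Annotations: GeoJSON LineString features carrying ``role`` and
``tumor_side`` properties.  Tables: CSV.  Reports/config: JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core import (
    BoundaryCurve,
    CalibratedImage,
    CalibrationError,
    FieldMeasurement,
    PatientRecord,
    TumorMask,
)

_CM_PER_INCH = 2.54

#: column dictionary of the cohort CSV (one row per patient)
COHORT_COLUMNS = [
    "id", "sex", "age_group", "stage", "differentiation", "smoking",
    "poi", "wpoi", "doi", "pni",
    "tsr_inner", "tsr_itf", "group_inner", "group_itf",
    "os_time", "os_event", "dfs_time", "dfs_event",
    "mfs_time", "mfs_event", "rfs_time", "rfs_event",
]


def write_calibrated_image(path: str | Path, image: CalibratedImage) -> None:
    """TIFF with X/YResolution tags encoding microns per pixel."""
    px_per_cm = 10_000.0 / image.mpp
    tifffile.imwrite(
        path,
        image.pixels.astype(np.uint8),
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )


def read_calibrated_image(
    path: str | Path, mpp_override: float | None = None
) -> CalibratedImage:
    """Load a TIFF; mpp from resolution metadata unless overridden."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        pixels = tif.asarray()
        page = tif.pages[0]
        mpp = _mpp_from_tags(page)
    if mpp_override is not None:
        if mpp_override <= 0:
            raise CalibrationError("mpp_override must be > 0")
        mpp = mpp_override
    if mpp is None:
        raise CalibrationError(
            f"{path} carries no resolution metadata and no override was given"
        )
    return CalibratedImage(pixels, mpp)


def _mpp_from_tags(page) -> float | None:
    tags = page.tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    px_per_unit = num / den
    unit = tags["ResolutionUnit"].value
    unit = getattr(unit, "value", unit)
    if unit == 2:  # inch
        um_per_unit = _CM_PER_INCH * 10_000.0
    elif unit == 3:  # centimeter
        um_per_unit = 10_000.0
    else:
        return None
    return um_per_unit / px_per_unit


def write_mask(path: str | Path, mask: TumorMask) -> None:
    """Single-channel PNG, tumor = 255, stroma = 0."""
    iio.imwrite(path, (mask.values * 255).astype(np.uint8))


def read_mask(path: str | Path, mpp: float) -> TumorMask:
    values = np.asarray(iio.imread(path))
    if values.ndim == 3:
        values = values[..., 0]
    return TumorMask((values > 127).astype(np.uint8), mpp)


def write_curves(path: str | Path, curves: Iterable[BoundaryCurve]) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": np.asarray(c.vertices, float).tolist(),
            },
            "properties": {"role": c.role, "tumor_side": c.tumor_side},
        }
        for c in curves
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_curves(path: str | Path) -> dict[str, BoundaryCurve]:
    """Curves keyed by role, from GeoJSON LineString features."""
    with open(path) as fh:
        collection = json.load(fh)
    out: dict[str, BoundaryCurve] = {}
    for feat in collection.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "LineString":
            continue
        props = feat.get("properties", {})
        curve = BoundaryCurve(
            vertices=np.asarray(geom["coordinates"], float),
            role=props["role"],
            tumor_side=int(props["tumor_side"]),
        )
        out[curve.role] = curve
    return out


def write_fields_csv(path: str | Path, measurements: Iterable[FieldMeasurement]) -> None:
    frame = pd.DataFrame(
        [
            {
                "zone": m.box.zone,
                "x_um": m.box.origin[0],
                "y_um": m.box.origin[1],
                "width_um": m.box.width_um,
                "height_um": m.box.height_um,
                "tumor_fraction": m.tumor_fraction,
                "tsr_percent": round(m.tumor_fraction * 100.0, 2),
            }
            for m in measurements
        ]
    )
    frame.to_csv(path, index=False)


def write_cohort_csv(path: str | Path, records: Iterable[PatientRecord]) -> None:
    rows = [dataclasses.asdict(r) for r in records]
    pd.DataFrame(rows)[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[PatientRecord]:
    frame = pd.read_csv(path)
    records = []
    for _, row in frame.iterrows():
        kw = {col: row[col] for col in COHORT_COLUMNS if col in frame.columns}
        for ep in ("os", "dfs", "mfs", "rfs"):
            kw[f"{ep}_event"] = int(kw[f"{ep}_event"])
        records.append(PatientRecord(**kw))
    return records


def write_report(path: str | Path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
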