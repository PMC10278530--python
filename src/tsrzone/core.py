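"""Shared domain types for the zonal TSR pipeline.

Coordinate convention used throughout the package: physical coordinates are
in micrometres (um) with the origin at the *centre* of the top-left pixel,
x increasing rightward (columns) and y increasing downward (rows).  All
rasters are 0-based, row-major.  Pixel (r, c) therefore has physical centre
(c * mpp, r * mpp).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

Zone = Literal["inner_tumor", "itf"]
CurveRole = Literal["invasive_edge", "epithelial_origin"]


class CalibrationError(ValueError):
    """Raised when physical pixel size is missing or invalid."""


@dataclass
class CalibratedImage:
    """RGB raster with a known physical pixel size.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3)
        Intensities in [0, 255].
    mpp : float
        Microns per pixel, > 0.
    """

    pixels: np.ndarray
    mpp: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must have shape (H, W, 3)")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must contain at least one pixel")
        if not np.isfinite(self.mpp) or self.mpp <= 0:
            raise CalibrationError(f"mpp must be > 0, got {self.mpp!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class TumorMask:
    """Binary tumor (1) / stroma (0) raster aligned to a source image."""

    values: np.ndarray
    mpp: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")
        uniq = np.unique(self.values)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        self.values = self.values.astype(np.uint8)
        if not np.isfinite(self.mpp) or self.mpp <= 0:
            raise CalibrationError(f"mpp must be > 0, got {self.mpp!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class BoundaryCurve:
    """Open polyline annotation in physical (um) coordinates.

    ``tumor_side`` is the sign of the cross product z-component
    ``(b - a) x (p - a)`` for a point ``p`` on the tumor side of segment
    ``(a, b)``: +1 means tumor lies to the left of the travel direction in
    image coordinates (y down), i.e. below a left-to-right horizontal line.
    """

    vertices: np.ndarray
    role: CurveRole
    tumor_side: int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must have shape (N, 2)")
        if len(self.vertices) < 2:
            raise ValueError("a curve needs at least 2 vertices")
        if np.any(np.all(np.diff(self.vertices, axis=0) == 0, axis=1)):
            raise ValueError("consecutive vertices must be distinct")
        if self.tumor_side not in (-1, 1):
            raise ValueError("tumor_side must be +1 or -1")

    def reversed(self) -> "BoundaryCurve":
        """Same geometry traversed backwards (tumor side flag flips)."""
        return BoundaryCurve(self.vertices[::-1].copy(), self.role, -self.tumor_side)


@dataclass
class ZoneBand:
    """Binary raster of a fixed-width histological band."""

    values: np.ndarray
    zone: Zone
    width_um: float
    mpp: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 2:
            raise ValueError("band raster must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class FieldBox:
    """Axis-aligned rectangular image field, physical coordinates.

    ``origin`` is the (x, y) of the box's top-left pixel centre in um.
    """

    origin: tuple[float, float]
    width_um: float = 1150.0
    height_um: float = 680.0
    zone: Zone = "inner_tumor"

    def pixel_slices(self, mpp: float) -> tuple[slice, slice]:
        """(row_slice, col_slice) of the pixels covered by this box."""
        c0 = int(round(self.origin[0] / mpp))
        r0 = int(round(self.origin[1] / mpp))
        nc = int(round(self.width_um / mpp))
        nr = int(round(self.height_um / mpp))
        return slice(r0, r0 + nr), slice(c0, c0 + nc)

    @property
    def area_mm2(self) -> float:
        return self.width_um * self.height_um / 1e6


@dataclass
class FieldMeasurement:
    """A field box together with its measured tumor area fraction."""

    box: FieldBox
    tumor_fraction: float
    border_ok: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must lie in [0, 1]")


@dataclass
class RegionTSR:
    """Per-zone TSR: three field percentages, their mean, and the group."""

    zone: Zone
    field_tsrs: tuple[float, ...]
    mean_tsr: float
    group: Literal["tumor_high", "tumor_low"]
    complete: bool = True  # False when fewer than the requested fields existed


@dataclass
class SlidePattern:
    inner: RegionTSR
    itf: RegionTSR
    pattern: Literal["high_high", "high_low", "low_low", "low_high"]


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("need an r x c table with r, c >= 2")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.sum() == 0:
            raise ValueError("table total must be > 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class TestResult:
    statistic: float
    df: int | None
    p_value: float
    method: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class EffectEstimate:
    """One covariate's effect in a regression fit."""

    covariate: str
    effect: float  # hazard ratio or odds ratio
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.effect <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")
        if self.effect <= 0:
            raise ValueError("ratio effects must be positive")


@dataclass
class RegressionFit:
    model: Literal["cox", "logistic"]
    endpoint: str
    effects: dict[str, EffectEstimate]
    n: int
    n_events: int

    def __getitem__(self, covariate: str) -> EffectEstimate:
        return self.effects[covariate]


@dataclass
class PatientRecord:
    """One patient: covariates, zone TSRs/groups and four endpoints."""

    id: str
    sex: str = "male"                  # male | female
    age_group: str = "<60"             # <60 | >=60
    stage: str = "I"                   # I | II | III | IV
    differentiation: str = "well"      # well | moderate-poor
    smoking: str = "no"                # yes | no
    poi: str = "1-3"                   # 1-3 | 4-5
    wpoi: str = "1-3"                  # 1-3 | 4-5
    doi: str = "<5mm"                  # <5mm | >=5mm
    pni: str = "no"                    # yes | no
    tsr_inner: float | None = None
    tsr_itf: float | None = None
    group_inner: str | None = None     # tumor_high | tumor_low
    group_itf: str | None = None
    os_time: float = 0.0
    dfs_time: float = 0.0
    mfs_time: float = 0.0
    rfs_time: float = 0.0
    os_event: int = 0
    dfs_event: int = 0
    mfs_event: int = 0
    rfs_event: int = 0

    def __post_init__(self) -> None:
        for name in ("os_time", "dfs_time", "mfs_time", "rfs_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for tsr, grp in ((self.tsr_inner, self.group_inner), (self.tsr_itf, self.group_itf)):
            if tsr is not None and grp is not None:
                expected = "tumor_high" if tsr >= 50 else "tumor_low"
                if grp != expected:
                    raise ValueError("group inconsistent with TSR at the 50% rule")
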