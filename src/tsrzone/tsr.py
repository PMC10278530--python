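"""TSR computation, dichotomization at 50%, slide-pattern labeling, and
the end-to-end per-slide pipeline."""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np

from . import fields as _fields
from . import segmentation as _seg
from . import zonation as _zon
from .core import (
    BoundaryCurve,
    CalibratedImage,
    FieldMeasurement,
    PatientRecord,
    RegionTSR,
    SlidePattern,
    TumorMask,
)

TSR_THRESHOLD = 50.0


def field_tsr(measurement: FieldMeasurement) -> float:
    """Tumor area / field area x 100, in percent."""
    return measurement.tumor_fraction * 100.0


def region_tsr(field_tsrs, zone, n_expected: int = 3) -> RegionTSR:
    """Average the per-field TSR percentages and dichotomize at 50%.

    A mean of exactly 50 is classified tumor_high (threshold inclusive).
    Fewer than ``n_expected`` values are accepted but flagged via
    ``complete=False``.
    """
    values = tuple(float(v) for v in field_tsrs)
    if not values:
        raise ValueError("need at least one field TSR")
    for v in values:
        if not 0.0 <= v <= 100.0:
            raise ValueError("field TSRs must lie in [0, 100]")
    mean = float(np.mean(values))
    return RegionTSR(
        zone=zone,
        field_tsrs=values,
        mean_tsr=mean,
        group="tumor_high" if mean >= TSR_THRESHOLD else "tumor_low",
        complete=len(values) >= n_expected,
    )


def slide_pattern(inner: RegionTSR, itf: RegionTSR) -> SlidePattern:
    """Four-way inner/ITF group pattern (low_high included for totality)."""
    key = (inner.group == "tumor_high", itf.group == "tumor_high")
    pattern = {
        (True, True): "high_high",
        (True, False): "high_low",
        (False, False): "low_low",
        (False, True): "low_high",
    }[key]
    return SlidePattern(inner=inner, itf=itf, pattern=pattern)


class PipelineStageError(RuntimeError):
    """Wraps a failure with the name of the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def run_pipeline(
    image: CalibratedImage,
    curves: Mapping[str, BoundaryCurve],
    clinical_row: Mapping | None = None,
    config=None,
) -> tuple[PatientRecord, dict]:
    """Segmentation -> zonation -> field selection -> TSR for one slide.

    Parameters
    ----------
    image : calibrated RGB slide.
    curves : mapping with keys ``epithelial_origin`` and ``invasive_edge``.
    clinical_row : optional mapping of PatientRecord covariate/endpoint
        fields to merge into the returned record.
    config : :class:`tsrzone.config.PipelineConfig`, optional.

    Returns
    -------
    (record, report) where report carries full provenance: config values,
    per-field boxes and TSRs, region means, groups and the pattern.
    """
    from .config import PipelineConfig  # local import to avoid a cycle

    cfg = config or PipelineConfig()

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise PipelineStageError(name, exc) from exc

    def _calibrate():
        if image.mpp <= 0:
            raise ValueError("image mpp must be > 0")
        return image

    _stage("calibration", _calibrate)

    if cfg.segmentation_mode == "threshold":
        mask = _stage(
            "segmentation",
            lambda: _seg.segment_by_threshold(image, cfg.dab_threshold),
        )
    elif cfg.segmentation_mode == "trained":
        if cfg.classifier is None:
            raise PipelineStageError(
                "segmentation", ValueError("trained mode requires a classifier")
            )
        mask = _stage(
            "segmentation", lambda: _seg.predict_mask(cfg.classifier, image)
        )
    else:
        raise PipelineStageError(
            "segmentation",
            ValueError(f"unknown segmentation_mode {cfg.segmentation_mode!r}"),
        )

    tissue = TumorMask(np.ones(image.shape, dtype=np.uint8), image.mpp)
    report: dict = {
        "config": dataclasses.asdict(
            dataclasses.replace(cfg, classifier=None)
        ),
        "zones": {},
    }
    region_results: dict[str, RegionTSR] = {}
    for role in ("epithelial_origin", "invasive_edge"):
        if role not in curves:
            raise PipelineStageError(
                "zonation", KeyError(f"missing curve {role!r}")
            )
        band = _stage(
            "zonation",
            lambda role=role: _zon.extract_band(
                tissue, curves[role], cfg.band_width_um
            ),
        )
        measurements = _stage(
            "field_selection",
            lambda band=band: _fields.select_fields(
                mask,
                band,
                k=cfg.n_fields,
                field_dims_um=cfg.field_dims_um,
                stride_um=cfg.stride_um,
                border_margin_um=cfg.border_margin_um,
            ),
        )
        region = _stage(
            "tsr",
            lambda ms=measurements, z=band.zone: region_tsr(
                [field_tsr(m) for m in ms], z, n_expected=cfg.n_fields
            ),
        )
        region_results[band.zone] = region
        report["zones"][band.zone] = {
            "fields": [
                {
                    "origin_um": list(m.box.origin),
                    "width_um": m.box.width_um,
                    "height_um": m.box.height_um,
                    "tumor_fraction": m.tumor_fraction,
                    "tsr": field_tsr(m),
                }
                for m in measurements
            ],
            "mean_tsr": region.mean_tsr,
            "group": region.group,
            "complete": region.complete,
        }

    pattern = slide_pattern(region_results["inner_tumor"], region_results["itf"])
    report["pattern"] = pattern.pattern

    kw = dict(clinical_row or {})
    kw.setdefault("id", "slide")
    # full precision in the record; rounding happens only when writing outputs
    kw.update(
        tsr_inner=region_results["inner_tumor"].mean_tsr,
        tsr_itf=region_results["itf"].mean_tsr,
        group_inner=region_results["inner_tumor"].group,
        group_itf=region_results["itf"].group,
    )
    record = PatientRecord(**kw)
    return record, report
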