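"""Constrained sliding-window selection of low-tumor-density image fields.

Candidate fields are fixed-size axis-aligned boxes (default 1150 x 680 um,
0.782 mm^2) on a stride grid whose centre pixel falls inside the zone band.
A field is admissible when every border strip contains tumor; among
admissible fields the k with the lowest tumor area fraction are returned,
overlap permitted, ties broken by scan order (row-major within each
orientation, landscape orientation first).
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import FieldBox, FieldMeasurement, TumorMask, ZoneBand

DEFAULT_FIELD_DIMS_UM = (1150.0, 680.0)
DEFAULT_STRIDE_UM = 50.0
DEFAULT_BORDER_MARGIN_UM = 20.0


class FieldSelectionError(ValueError):
    """No candidate window satisfies the constraints."""


def enumerate_windows(
    band: ZoneBand,
    field_dims_um: tuple[float, float] = DEFAULT_FIELD_DIMS_UM,
    stride_um: float = DEFAULT_STRIDE_UM,
) -> list[FieldBox]:
    """All stride-grid boxes inside the frame whose centre pixel is in band.

    Both orientations (w x h and h x w) are generated unless the box is
    square.  Boxes are emitted in scan order: landscape orientation first,
    then portrait, row-major within each.
    """
    if stride_um <= 0:
        raise ValueError("stride_um must be > 0")
    if not band.values.any():
        raise ValueError("band is empty")
    h_px, w_px = band.shape
    mpp = band.mpp
    stride_px = max(1, int(round(stride_um / mpp)))

    dims = [field_dims_um]
    if field_dims_um[0] != field_dims_um[1]:
        dims.append((field_dims_um[1], field_dims_um[0]))

    boxes: list[FieldBox] = []
    for bw_um, bh_um in dims:
        nc = int(round(bw_um / mpp))
        nr = int(round(bh_um / mpp))
        if nc < 1 or nr < 1 or nc > w_px or nr > h_px:
            continue
        for r0 in range(0, h_px - nr + 1, stride_px):
            for c0 in range(0, w_px - nc + 1, stride_px):
                if band.values[r0 + nr // 2, c0 + nc // 2]:
                    boxes.append(
                        FieldBox(
                            origin=(c0 * mpp, r0 * mpp),
                            width_um=bw_um,
                            height_um=bh_um,
                            zone=band.zone,
                        )
                    )
    return boxes


def border_has_tumor(
    mask: TumorMask, box: FieldBox, margin_um: float = DEFAULT_BORDER_MARGIN_UM
) -> bool:
    """True iff each of the four border strips of depth ``margin_um``
    inside the box contains at least one tumor pixel."""
    rs, cs = box.pixel_slices(mask.mpp)
    sub = mask.values[rs, cs]
    nr, nc = sub.shape
    if nr == 0 or nc == 0:
        raise ValueError("box lies outside the mask frame")
    m = max(1, int(round(margin_um / mask.mpp)))
    if 2 * m > min(nr, nc):
        raise ValueError("border margin exceeds half the box extent")
    return bool(
        sub[:m, :].any()
        and sub[-m:, :].any()
        and sub[:, :m].any()
        and sub[:, -m:].any()
    )


def select_fields(
    mask: TumorMask,
    band: ZoneBand,
    k: int = 3,
    field_dims_um: tuple[float, float] = DEFAULT_FIELD_DIMS_UM,
    stride_um: float = DEFAULT_STRIDE_UM,
    border_margin_um: float = DEFAULT_BORDER_MARGIN_UM,
    allow_overlap: bool = True,
) -> list[FieldMeasurement]:
    """The k admissible windows with the smallest tumor area fraction.

    Returns measurements sorted ascending by fraction; ties keep scan
    order.  With ``allow_overlap=False`` a greedy pass discards windows
    overlapping an already accepted one.  Fewer than k admissible windows
    yields all of them with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    boxes = enumerate_windows(band, field_dims_um, stride_um)
    if not boxes:
        raise FieldSelectionError("no candidate window fits the band/frame")

    # integral image for O(1) box sums
    integ = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
    integ[1:, 1:] = np.cumsum(np.cumsum(mask.values, axis=0), axis=1)

    candidates: list[FieldMeasurement] = []
    for box in boxes:
        rs, cs = box.pixel_slices(mask.mpp)
        total = (rs.stop - rs.start) * (cs.stop - cs.start)
        tumor = int(
            integ[rs.stop, cs.stop]
            - integ[rs.start, cs.stop]
            - integ[rs.stop, cs.start]
            + integ[rs.start, cs.start]
        )
        if not border_has_tumor(mask, box, border_margin_um):
            continue
        candidates.append(
            FieldMeasurement(box=box, tumor_fraction=tumor / total, border_ok=True)
        )
    if not candidates:
        raise FieldSelectionError(
            "no window satisfies the tumor-at-all-borders constraint"
        )

    ordered = sorted(
        range(len(candidates)), key=lambda i: (candidates[i].tumor_fraction, i)
    )
    chosen: list[FieldMeasurement] = []
    for i in ordered:
        cand = candidates[i]
        if not allow_overlap and any(
            _boxes_overlap(cand.box, c.box, mask.mpp) for c in chosen
        ):
            continue
        chosen.append(cand)
        if len(chosen) == k:
            break
    if len(chosen) < k:
        warnings.warn(
            f"only {len(chosen)} of {k} requested fields available", stacklevel=2
        )
    return chosen


def _boxes_overlap(a: FieldBox, b: FieldBox, mpp: float) -> bool:
    ars, acs = a.pixel_slices(mpp)
    brs, bcs = b.pixel_slices(mpp)
    return (
        ars.start < brs.stop
        and brs.start < ars.stop
        and acs.start < bcs.stop
        and bcs.start < acs.stop
    )
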