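"""Ground-truthed phantoms and simulated cohorts.

The phantom is a two-class pseudo-IHC slide: brown (DAB-like) tumor nests
on a blue-gray (hematoxylin-like) stromal background, with a horizontal
epithelial-origin line near the top edge and a horizontal invasive-edge
line near the bottom.  Tumor density is controlled independently inside
the 1-mm inner band (below the origin line) and the 1-mm front band
(above the invasive edge); the space between is filled at the mean of the
two targets.  Nests are random rotated ellipses with lognormal radii,
placed by rejection until the per-zone area fraction reaches its target.

The cohort simulator draws exponential proportional-hazards event times
with binary covariates at configurable true hazard ratios, independent
exponential censoring, and a random event-type label (relapse /
metastasis / death) that splits the single event into the four survival
endpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse

from .core import (
    BoundaryCurve,
    CalibratedImage,
    ContingencyTable,
    PatientRecord,
    TumorMask,
    ZoneBand,
)

TUMOR_RGB = (105, 62, 35)     # DAB-like brown
STROMA_RGB = (168, 172, 200)  # hematoxylin-like blue-gray

#: distance (um) of the two boundary lines from the image edges
EDGE_MARGIN_UM = 100.0
BAND_WIDTH_UM = 1000.0


@dataclass
class PhantomConfig:
    image_size_px: tuple[int, int] = (700, 500)  # (height, width)
    mpp: float = 4.0
    inner_target_fraction: float = 0.9
    front_target_fraction: float = 0.3
    nest_radius_um: float = 40.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mpp <= 0:
            raise ValueError("mpp must be > 0")
        for frac in (self.inner_target_fraction, self.front_target_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("target fractions must lie in [0, 1]")
        h, w = self.image_size_px
        if h < 1 or w < 1:
            raise ValueError("image must have positive dimensions")
        if (h - 1) * self.mpp < 2 * (BAND_WIDTH_UM + EDGE_MARGIN_UM):
            raise ValueError(
                "image too small: both 1-mm bands plus margins must fit "
                f"(need height > {2 * (BAND_WIDTH_UM + EDGE_MARGIN_UM)} um)"
            )


@dataclass
class PhantomTruth:
    tumor_mask: TumorMask
    invasive_edge: BoundaryCurve
    epithelial_origin: BoundaryCurve
    true_inner_fraction: float
    true_front_fraction: float
    inner_band: ZoneBand = field(repr=False, default=None)
    itf_band: ZoneBand = field(repr=False, default=None)


def _band_rows(n_rows: int, mpp: float, y0_um: float, y1_um: float) -> np.ndarray:
    """Boolean row selector: pixel-centre y in the closed interval [y0, y1]."""
    y = np.arange(n_rows) * mpp
    return (y >= y0_um) & (y <= y1_um)


def _fill_zone(
    mask: np.ndarray,
    rows: np.ndarray,
    target: float,
    nest_radius_um: float,
    mpp: float,
    rng: np.random.Generator,
) -> None:
    """Add elliptical nests clipped to ``rows`` until the zone fraction
    reaches ``target``.  Mutates ``mask`` in place."""
    if target <= 0 or not rows.any():
        return
    zone_idx = np.where(rows)[0]
    r_lo, r_hi = zone_idx[0], zone_idx[-1]
    zone_px = rows.sum() * mask.shape[1]
    mean_r_px = max(nest_radius_um / mpp, 1.0)
    count = int(mask[rows].sum())
    max_iter = 200_000
    for _ in range(max_iter):
        frac = count / zone_px
        if frac >= target:
            return
        radius = rng.lognormal(np.log(mean_r_px), 0.35)
        # shrink nests near the target so the overshoot stays small
        if (target - frac) * zone_px < np.pi * radius**2:
            radius = max(1.0, np.sqrt((target - frac) * zone_px / np.pi) + 1.0)
        cy = rng.uniform(r_lo, r_hi + 1)
        cx = rng.uniform(0, mask.shape[1])
        rr, cc = ellipse(
            cy,
            cx,
            radius,
            radius * rng.uniform(0.6, 1.4),
            shape=mask.shape,
            rotation=rng.uniform(0, np.pi),
        )
        keep = (rr >= r_lo) & (rr <= r_hi)
        rr, cc = rr[keep], cc[keep]
        count += int((mask[rr, cc] == 0).sum())
        mask[rr, cc] = 1
    achieved = count / zone_px
    warnings.warn(
        f"zone target fraction {target:.3f} unreachable with this nest "
        f"geometry; achieved {achieved:.3f}",
        stacklevel=2,
    )


def generate_phantom(config: PhantomConfig) -> tuple[CalibratedImage, PhantomTruth]:
    """Render a calibrated phantom slide and its exact ground truth.

    Deterministic given ``config.seed``; the returned truth fractions are
    counted on the returned mask within the true band rows, so they match
    the mask exactly by construction.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size_px
    mpp = config.mpp
    mask = np.zeros((h, w), dtype=np.uint8)

    y_origin = round(EDGE_MARGIN_UM / mpp) * mpp          # snap to a pixel centre
    y_edge = round(((h - 1) * mpp - EDGE_MARGIN_UM) / mpp) * mpp
    inner_rows = _band_rows(h, mpp, y_origin, y_origin + BAND_WIDTH_UM)
    front_rows = _band_rows(h, mpp, y_edge - BAND_WIDTH_UM, y_edge)
    mid_rows = (
        _band_rows(h, mpp, y_origin, y_edge) & ~inner_rows & ~front_rows
    )

    _fill_zone(mask, inner_rows, config.inner_target_fraction,
               config.nest_radius_um, mpp, rng)
    _fill_zone(mask, front_rows, config.front_target_fraction,
               config.nest_radius_um, mpp, rng)
    mid_target = 0.5 * (config.inner_target_fraction + config.front_target_fraction)
    _fill_zone(mask, mid_rows, mid_target, config.nest_radius_um, mpp, rng)

    pixels = np.empty((h, w, 3), dtype=float)
    pixels[mask == 1] = TUMOR_RGB
    pixels[mask == 0] = STROMA_RGB
    if config.noise_sd > 0:
        pixels += rng.normal(0.0, config.noise_sd, size=pixels.shape)
    pixels = np.clip(pixels, 0, 255).astype(np.uint8)

    x_max = (w - 1) * mpp
    origin_curve = BoundaryCurve(
        vertices=np.array([[0.0, y_origin], [x_max, y_origin]]),
        role="epithelial_origin",
        tumor_side=+1,  # tumor extends downward (+y) from the origin line
    )
    edge_curve = BoundaryCurve(
        vertices=np.array([[0.0, y_edge], [x_max, y_edge]]),
        role="invasive_edge",
        tumor_side=-1,  # tumor extends upward (-y) from the invasive edge
    )

    inner_band = ZoneBand(
        np.broadcast_to(inner_rows[:, None], (h, w)).copy(),
        zone="inner_tumor", width_um=BAND_WIDTH_UM, mpp=mpp,
    )
    itf_band = ZoneBand(
        np.broadcast_to(front_rows[:, None], (h, w)).copy(),
        zone="itf", width_um=BAND_WIDTH_UM, mpp=mpp,
    )

    truth = PhantomTruth(
        tumor_mask=TumorMask(mask, mpp),
        invasive_edge=edge_curve,
        epithelial_origin=origin_curve,
        true_inner_fraction=float(mask[inner_rows].sum() / (inner_rows.sum() * w)),
        true_front_fraction=float(mask[front_rows].sum() / (front_rows.sum() * w)),
        inner_band=inner_band,
        itf_band=itf_band,
    )
    return CalibratedImage(pixels, mpp), truth


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

#: covariate indicator name -> (record field, value when indicator == 1,
#: value when 0)
INDICATOR_FIELDS = {
    "sex_female": ("sex", "female", "male"),
    "age_ge60": ("age_group", ">=60", "<60"),
    "differentiation_modpoor": ("differentiation", "moderate-poor", "well"),
    "smoking_yes": ("smoking", "yes", "no"),
    "poi_high": ("poi", "4-5", "1-3"),
    "wpoi_high": ("wpoi", "4-5", "1-3"),
    "doi_ge5": ("doi", ">=5mm", "<5mm"),
    "pni_yes": ("pni", "yes", "no"),
    "inner_group_low": ("group_inner", "tumor_low", "tumor_high"),
    "itf_group_low": ("group_itf", "tumor_low", "tumor_high"),
}

EVENT_TYPES = ("relapse", "metastasis", "death")


@dataclass
class CohortConfig:
    n: int = 114
    hr_map: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.02  # events per month
    censor_rate: float = 0.3
    group_prevalence: float = 0.45  # probability a patient is tumor-low
    event_type_probs: tuple[float, float, float] = (0.25, 0.25, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort needs n >= 2 patients")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")
        if not 0.0 < self.group_prevalence < 1.0:
            raise ValueError("group_prevalence must lie in (0, 1)")
        for name, hr in self.hr_map.items():
            if hr <= 0:
                raise ValueError(f"hazard ratio for {name!r} must be > 0")
            if name not in INDICATOR_FIELDS:
                raise ValueError(
                    f"unknown covariate {name!r}; known: {sorted(INDICATOR_FIELDS)}"
                )
        if abs(sum(self.event_type_probs) - 1.0) > 1e-9:
            raise ValueError("event_type_probs must sum to 1")


def simulate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Draw a proportional-hazards cohort; deterministic given seed.

    Event times are exponential with per-patient hazard
    ``baseline * exp(sum(indicator * log HR))``; censoring is an
    independent exponential whose rate yields roughly ``censor_rate``
    censored observations at the baseline hazard.  Each observed event
    carries one type label; DFS counts any event, OS counts death only
    (censoring at non-death events), MFS censors relapse and RFS censors
    metastasis, with death always an event.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n

    indicators: dict[str, np.ndarray] = {}
    for name in INDICATOR_FIELDS:
        if name in ("inner_group_low", "itf_group_low"):
            p = config.group_prevalence
        else:
            p = 0.5
        indicators[name] = rng.binomial(1, p, size=n)

    log_hr = np.zeros(n)
    for name, hr in config.hr_map.items():
        log_hr += indicators[name] * np.log(hr)
    hazard = config.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / hazard)

    if config.censor_rate > 0:
        # competing exponentials: P(censored | hazard h) = c / (c + h);
        # calibrate c against the cohort mean hazard so the marginal
        # censored fraction lands near censor_rate even when HRs != 1
        c_rate = float(hazard.mean()) * config.censor_rate / (1 - config.censor_rate)
        t_censor = rng.exponential(1.0 / c_rate, size=n)
    else:
        t_censor = np.full(n, np.inf)

    observed = t_event <= t_censor
    time = np.minimum(t_event, t_censor)
    etype = rng.choice(EVENT_TYPES, size=n, p=config.event_type_probs)

    records: list[PatientRecord] = []
    for i in range(n):
        kw: dict = {"id": f"sim{i:05d}"}
        for name, (fld, on, off) in INDICATOR_FIELDS.items():
            kw[fld] = on if indicators[name][i] else off
        # stage independent of hazard unless modeled explicitly
        kw["stage"] = rng.choice(["I", "II", "III", "IV"])
        kw["tsr_inner"] = (
            float(rng.uniform(10, 50)) if kw["group_inner"] == "tumor_low"
            else float(rng.uniform(50, 90))
        )
        kw["tsr_itf"] = (
            float(rng.uniform(10, 50)) if kw["group_itf"] == "tumor_low"
            else float(rng.uniform(50, 90))
        )
        t = float(time[i])
        ev = bool(observed[i])
        ty = etype[i]
        kw.update(
            os_time=t, os_event=int(ev and ty == "death"),
            dfs_time=t, dfs_event=int(ev),
            mfs_time=t, mfs_event=int(ev and ty in ("metastasis", "death")),
            rfs_time=t, rfs_event=int(ev and ty in ("relapse", "death")),
        )
        records.append(PatientRecord(**kw))
    return records


# ---------------------------------------------------------------------------
# printed baseline-characteristics fixtures (114-patient cohort)
# ---------------------------------------------------------------------------

_INNER_COLS = ("tumor_high", "tumor_low")
_TABLE1_COUNTS: dict[str, tuple[tuple[str, ...], list[list[int]]]] = {
    "sex_inner": (("male", "female"), [[51, 18], [34, 11]]),
    "sex_itf": (("male", "female"), [[40, 29], [23, 22]]),
    "age_inner": (("<60", ">=60"), [[35, 9], [50, 20]]),
    "age_itf": (("<60", ">=60"), [[26, 18], [37, 33]]),
    "stage_inner": (("I", "II", "III", "IV"),
                    [[7, 1], [17, 7], [16, 4], [45, 17]]),
    "stage_itf": (("I", "II", "III", "IV"),
                  [[5, 3], [13, 11], [12, 8], [33, 29]]),
    "differentiation_inner": (("well", "moderate-poor"), [[67, 18], [18, 11]]),
    "differentiation_itf": (("well", "moderate-poor"), [[47, 38], [16, 13]]),
    "smoking_inner": (("no", "yes"), [[50, 18], [35, 11]]),
    "smoking_itf": (("no", "yes"), [[37, 31], [26, 20]]),
    "poi_inner": (("1-3", "4-5"), [[53, 11], [32, 18]]),
    "poi_itf": (("1-3", "4-5"), [[44, 20], [19, 31]]),
    "wpoi_inner": (("1-3", "4-5"), [[24, 6], [61, 23]]),
    "wpoi_itf": (("1-3", "4-5"), [[22, 8], [41, 43]]),
    "doi_inner": (("<5mm", ">=5mm"), [[28, 6], [57, 23]]),
    "doi_itf": (("<5mm", ">=5mm"), [[22, 12], [41, 39]]),
    "pni_inner": (("no", "yes"), [[68, 12], [17, 17]]),
    "pni_itf": (("no", "yes"), [[53, 27], [10, 24]]),
}

COHORT_SIZE = 114
INNER_GROUP_SPLIT = (85, 29)  # tumor-high, tumor-low
ITF_GROUP_SPLIT = (63, 51)


def table1_fixtures() -> dict[str, ContingencyTable]:
    """Every covariate x TSR-group count table of the reference cohort.

    Keys are ``<covariate>_<zone>`` with zone in {inner, itf}; columns are
    always (tumor_high, tumor_low).
    """
    return {
        key: ContingencyTable(
            counts=np.array(counts),
            row_labels=rows,
            col_labels=_INNER_COLS,
        )
        for key, (rows, counts) in _TABLE1_COUNTS.items()
    }
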