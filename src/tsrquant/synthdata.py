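"""Synthetic whole-mount scenes, rosters, and survival cohorts.

Every downstream stage of the pipeline (tiling, segmentation, TSR scoring,
agreement statistics, cohort statistics) is exercised against data from
this module, so no scanned slides or patient records are required.  Three
generators are provided:

* :func:`generate_wholemount` renders an H&E-like RGB canvas with a known
  3-class ground-truth mask.  Tumor epithelium is drawn as clusters of
  random disks rendered in a hematoxylin-dominant color, the surrounding
  desmoplastic stroma in an eosin-dominant color, and necrosis as pale
  holes; the realized epithelium fraction is controlled to within one
  percentage point of the requested target.
* :func:`generate_agreement_roster` and :func:`generate_exclusion_roster`
  realize printed 2x2 agreement tables and patient-exclusion counts as
  patient-level rosters, so table-level statistics can be recomputed from
  case-level data.
* :func:`generate_cohort` simulates a surgical cohort with Bernoulli /
  multinomial covariates, a proportional-hazards event-time model
  (exponential baseline), independent exponential censoring, and an
  optional logistic model for the low-stromal-component label.

All generators are pure functions of their spec: one seeded
``numpy.random.Generator`` per call, no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .labels import HIGH_STROMAL, LABEL_EPITHELIUM, LABEL_STROMA, LOW_STROMAL
from .tiling import ROIMask, rasterize_roi

__all__ = [
    "StainParams",
    "ImageScene",
    "CohortSpec",
    "generate_wholemount",
    "generate_agreement_roster",
    "generate_exclusion_roster",
    "generate_cohort",
    "default_cohort_spec",
    "EXCLUSION_FLAGS",
]

MIN_CANVAS = 512
MIN_ROI_AREA = 512 * 512  # one full tile; smaller ROIs are degenerate

# Order matters: this is the reporting priority for multi-flag patients.
EXCLUSION_FLAGS = (
    "metastasis_or_r2",
    "neoadjuvant",
    "prior_malignancy",
    "death_within_90d",
    "lost_to_followup",
)


@dataclass(frozen=True)
class StainParams:
    """Mean rendering colors (8-bit RGB) per tissue class plus pixel noise.

    Defaults are Beer-Lambert transmissions of the standard H&E stain
    vectors: epithelium is hematoxylin-dominant (blue-purple), stroma is
    eosin-dominant (pink), necrosis and background are near-white.
    """

    epithelium_rgb: tuple[float, float, float] = (63.8, 41.5, 134.0)
    stroma_rgb: tuple[float, float, float] = (203.8, 77.1, 212.5)
    necrosis_rgb: tuple[float, float, float] = (240.0, 236.0, 232.0)
    background_rgb: tuple[float, float, float] = (246.0, 246.0, 246.0)
    noise_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ImageScene:
    """Specification of one synthetic whole-mount slide.

    ``target_epithelium_fraction`` is the requested proportion of tumor
    tissue (epithelium + stroma inside the ROI) occupied by epithelium;
    ``necrosis_fraction`` is the proportion of ROI pixels carved out as
    label-0 necrotic holes.  ``roi_polygon`` is a simple polygon in
    (row, col) canvas coordinates; by default an octagon inset from the
    canvas border.
    """

    canvas_height: int = 640
    canvas_width: int = 640
    target_epithelium_fraction: float = 0.5
    necrosis_fraction: float = 0.0
    roi_polygon: tuple[tuple[float, float], ...] | None = None
    stain_params: StainParams = field(default_factory=StainParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.canvas_height < MIN_CANVAS or self.canvas_width < MIN_CANVAS:
            raise ValueError(f"canvas must be at least {MIN_CANVAS} pixels per side")
        if not 0.0 <= self.target_epithelium_fraction <= 1.0:
            raise ValueError("target_epithelium_fraction must lie in [0, 1]")
        if not 0.0 <= self.necrosis_fraction <= 1.0:
            raise ValueError("necrosis_fraction must lie in [0, 1]")
        if self.target_epithelium_fraction + self.necrosis_fraction > 1.0:
            raise ValueError("epithelium + necrosis fractions must not exceed 1")

    def polygon(self) -> np.ndarray:
        if self.roi_polygon is not None:
            return np.asarray(self.roi_polygon, dtype=float)
        h, w = self.canvas_height, self.canvas_width
        mr, mc = 0.05 * h, 0.05 * w
        # Octagon inset from the border: corners cut at 25% of each side.
        return np.array(
            [
                (mr, 0.25 * w), (mr, 0.75 * w), (0.25 * h, w - mc),
                (0.75 * h, w - mc), (h - mr, 0.75 * w), (h - mr, 0.25 * w),
                (0.75 * h, mc), (0.25 * h, mc),
            ]
        )


def _disk_union(
    shape: tuple[int, int],
    allowed: np.ndarray,
    target_pixels: int,
    rng: np.random.Generator,
    mean_radius: float,
) -> np.ndarray:
    """Union of random disks inside ``allowed``, covering ~``target_pixels``.

    The disk count is chosen by inverting the Poisson coverage formula
    ``covered = A(1 - exp(-n pi r^2 / A))`` and corrected multiplicatively
    for up to 50 rounds; a final boundary trim (flipping pixels on the blob
    boundary) makes the realized count exact.  Blob geometry is preserved:
    only single-pixel-deep boundary layers are ever flipped.
    """
    total = int(allowed.sum())
    out = np.zeros(shape, dtype=bool)
    if target_pixels <= 0 or total == 0:
        return out
    frac = min(target_pixels / total, 1.0)
    if frac >= 1.0:
        return allowed.copy()

    coords = np.argwhere(allowed)
    disk_area = math.pi * mean_radius**2
    n = max(1, int(round(-total * math.log(1.0 - frac) / disk_area)))
    rr_full, cc_full = np.indices(shape, sparse=True)

    best = None
    for _ in range(50):
        cand = np.zeros(shape, dtype=bool)
        centers = coords[rng.integers(0, len(coords), size=n)]
        radii = mean_radius * rng.lognormal(mean=0.0, sigma=0.25, size=n)
        for (r, c), rad in zip(centers, radii):
            r0, r1 = max(0, int(r - rad)), min(shape[0], int(r + rad) + 1)
            c0, c1 = max(0, int(c - rad)), min(shape[1], int(c + rad) + 1)
            sub_r = rr_full[r0:r1, :] - r
            sub_c = cc_full[:, c0:c1] - c
            cand[r0:r1, c0:c1] |= (sub_r**2 + sub_c**2) <= rad**2
        cand &= allowed
        realized = cand.sum() / total
        best = cand
        if abs(realized - frac) <= 0.01:
            break
        # Poisson-coverage multiplicative correction on the disk count.
        if 0.0 < realized < 1.0:
            scale = math.log(1.0 - frac) / math.log(1.0 - realized)
            n = max(1, int(round(n * scale)))
        else:
            n = max(1, n * 2 if realized == 0.0 else n // 2)

    return _trim_to_count(best, allowed, target_pixels, rng)


def _trim_to_count(
    region: np.ndarray, allowed: np.ndarray, want: int, rng: np.random.Generator
) -> np.ndarray:
    """Flip boundary pixels of ``region`` until its count equals ``want``."""
    region = region.copy()
    struct = ndimage.generate_binary_structure(2, 1)
    for _ in range(10_000):  # each pass flips >= 1 pixel; bounded in practice
        count = int(region.sum())
        if count == want:
            return region
        if count > want:
            boundary = region & ~ndimage.binary_erosion(region, struct)
            idx = np.flatnonzero(boundary.ravel())
            if idx.size == 0:  # region is a set of isolated pixels
                idx = np.flatnonzero(region.ravel())
            drop = rng.permutation(idx)[: count - want]
            region.ravel()[drop] = False
        else:
            grow = allowed & ~region & ndimage.binary_dilation(region, struct)
            idx = np.flatnonzero(grow.ravel())
            if idx.size == 0:  # region empty or saturated: seed anywhere allowed
                idx = np.flatnonzero((allowed & ~region).ravel())
                if idx.size == 0:
                    return region
            add = rng.permutation(idx)[: want - count]
            region.ravel()[add] = True
    return region


def generate_wholemount(scene: ImageScene) -> tuple[np.ndarray, np.ndarray, ROIMask]:
    """Render a synthetic whole-mount slide with ground truth.

    Returns ``(rgb_image, truth_mask, roi)`` where ``rgb_image`` is an
    8-bit ``(H, W, 3)`` array, ``truth_mask`` a ``uint8`` label map
    (0 background/necrosis, 1 epithelium, 2 stroma, 0 outside the ROI)
    and ``roi`` the rasterized region of interest.  The realized
    epithelium fraction among ROI tissue pixels matches the scene target
    to within one percentage point (exactly, up to integer rounding, for
    the default trim).  Identical scenes produce bit-identical output.

    Raises
    ------
    ValueError
        If the ROI polygon rasterizes to fewer pixels than one tile.
    """
    rng = np.random.default_rng(scene.seed)
    shape = (scene.canvas_height, scene.canvas_width)
    roi = rasterize_roi(scene.polygon(), shape)
    if roi.area < MIN_ROI_AREA:
        raise ValueError(
            f"ROI area {roi.area} px is smaller than one {MIN_ROI_AREA} px tile"
        )

    mean_radius = max(8.0, min(shape) / 24.0)
    necrosis = _disk_union(
        shape, roi.mask, int(round(scene.necrosis_fraction * roi.area)), rng, mean_radius
    )
    tissue = roi.mask & ~necrosis
    n_tissue = int(tissue.sum())
    epi = _disk_union(
        shape, tissue, int(round(scene.target_epithelium_fraction * n_tissue)), rng,
        mean_radius,
    )

    truth = np.zeros(shape, dtype=np.uint8)
    truth[tissue] = LABEL_STROMA
    truth[epi] = LABEL_EPITHELIUM

    sp = scene.stain_params
    rgb = np.empty(shape + (3,), dtype=np.float64)
    rgb[:] = sp.background_rgb
    rgb[necrosis] = sp.necrosis_rgb
    rgb[truth == LABEL_STROMA] = sp.stroma_rgb
    rgb[truth == LABEL_EPITHELIUM] = sp.epithelium_rgb
    if sp.noise_sd > 0:
        rgb += rng.normal(0.0, sp.noise_sd, size=rgb.shape)
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    return rgb, truth, roi


def generate_agreement_roster(a: int, b: int, c: int, d: int) -> pd.DataFrame:
    """Realize a 2x2 computer-vs-pathologist table as paired categories.

    Cell meanings follow the agreement table convention: ``a`` computer-high
    & pathologist-high, ``b`` computer-high & pathologist-low, ``c``
    computer-low & pathologist-high, ``d`` computer-low & pathologist-low.
    Cross-tabulating the returned pairs reproduces ``(a, b, c, d)`` exactly.
    """
    counts = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in counts):
        raise ValueError("cell counts must be non-negative integers")
    if sum(counts) < 1:
        raise ValueError("at least one pair is required")
    cells = [
        (HIGH_STROMAL, HIGH_STROMAL, a),
        (HIGH_STROMAL, LOW_STROMAL, b),
        (LOW_STROMAL, HIGH_STROMAL, c),
        (LOW_STROMAL, LOW_STROMAL, d),
    ]
    rows = [
        {"computer_category": comp, "pathologist_category": path}
        for comp, path, k in cells
        for _ in range(int(k))
    ]
    roster = pd.DataFrame(rows)
    roster.insert(0, "patient_id", [f"P{i:03d}" for i in range(1, len(roster) + 1)])
    return roster


def generate_exclusion_roster(
    included: int,
    category_counts: Sequence[int] = (20, 4, 4, 8, 4),
    seed: int | None = None,
) -> pd.DataFrame:
    """Build a patient roster with mutually exclusive exclusion flags.

    ``category_counts`` follows :data:`EXCLUSION_FLAGS` order (intraoperative
    metastasis or R2 resection, neoadjuvant therapy, prior malignancy, death
    within 90 days, lost to follow-up).  The roster has
    ``included + sum(category_counts)`` rows; each excluded patient carries
    exactly one flag.  If ``seed`` is given, row order is shuffled.
    """
    if included < 0 or any(int(k) != k or k < 0 for k in category_counts):
        raise ValueError("included and category counts must be non-negative integers")
    if len(category_counts) != len(EXCLUSION_FLAGS):
        raise ValueError(f"expected {len(EXCLUSION_FLAGS)} category counts")
    flags = np.zeros((included + int(sum(category_counts)), len(EXCLUSION_FLAGS)), dtype=bool)
    row = included
    for j, k in enumerate(category_counts):
        flags[row : row + int(k), j] = True
        row += int(k)
    roster = pd.DataFrame(flags, columns=list(EXCLUSION_FLAGS))
    roster.insert(0, "patient_id", [f"P{i:04d}" for i in range(1, len(roster) + 1)])
    if seed is not None and len(roster) > 1:
        rng = np.random.default_rng(seed)
        roster = roster.iloc[rng.permutation(len(roster))].reset_index(drop=True)
    return roster


@dataclass(frozen=True)
class CohortSpec:
    """Generative model of a surgical cohort.

    Binary covariates are independent Bernoulli draws at the stated
    prevalences; categorical covariates are multinomial with the first
    level as reference (dummy columns ``{name}_{level}`` are emitted for
    the others).  Event times are exponential with per-patient hazard
    ``baseline_hazard * exp(sum(beta * x))`` (proportional hazards on the
    listed ``log_hazard_effects`` columns), censoring is an independent
    exponential at ``censor_rate``; rates are per month.  If
    ``logistic_effects`` is given, a ``low_stromal`` indicator is drawn
    from a logistic model on the covariates and a ``tsr_category`` column
    is derived from it.
    """

    n: int
    binary_covariates: Mapping[str, float] = field(default_factory=dict)
    categorical_covariates: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    log_hazard_effects: Mapping[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.02
    censor_rate: float = 0.025
    logistic_effects: Mapping[str, float] | None = None
    logistic_intercept: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size n must be >= 1")
        if self.baseline_hazard <= 0 or self.censor_rate <= 0:
            raise ValueError("hazard rates must be > 0")
        for name, p in self.binary_covariates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {name!r} must lie in [0, 1]")
        for name, levels in self.categorical_covariates.items():
            probs = np.asarray(list(levels.values()), dtype=float)
            if (probs < 0).any() or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
                raise ValueError(f"level probabilities of {name!r} must sum to 1")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a cohort table from a :class:`CohortSpec`.

    Columns: ``patient_id``, one 0/1 column per binary covariate, a label
    column plus dummy columns per categorical covariate, optionally
    ``low_stromal``/``tsr_category``, and ``os_months`` (observed time,
    min of event and censoring) with ``event`` (1 = death observed,
    0 = censored).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    cols: dict[str, np.ndarray] = {}
    for name, p in spec.binary_covariates.items():
        cols[name] = (rng.random(n) < p).astype(np.int64)
    labels: dict[str, np.ndarray] = {}
    for name, levels in spec.categorical_covariates.items():
        names = list(levels.keys())
        draw = rng.choice(len(names), size=n, p=list(levels.values()))
        labels[name] = np.asarray(names, dtype=object)[draw]
        for j, level in enumerate(names[1:], start=1):
            cols[f"{name}_{level}"] = (draw == j).astype(np.int64)

    if spec.logistic_effects is not None:
        logit = np.full(n, spec.logistic_intercept, dtype=float)
        for name, beta in spec.logistic_effects.items():
            if name not in cols:
                raise KeyError(f"logistic effect references unknown covariate {name!r}")
            logit += beta * cols[name]
        cols["low_stromal"] = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(np.int64)

    log_hr = np.zeros(n, dtype=float)
    for name, beta in spec.log_hazard_effects.items():
        if name not in cols:
            raise KeyError(f"hazard effect references unknown covariate {name!r}")
        log_hr += beta * cols[name]
    hazard = spec.baseline_hazard * np.exp(log_hr)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.exponential(1.0 / spec.censor_rate, size=n)

    frame = pd.DataFrame({"patient_id": [f"P{i:05d}" for i in range(1, n + 1)]})
    for name, values in labels.items():
        frame[name] = values
    for name, values in cols.items():
        frame[name] = values
    if "low_stromal" in frame:
        frame["tsr_category"] = np.where(frame["low_stromal"] == 1, LOW_STROMAL, HIGH_STROMAL)
    frame["os_months"] = np.minimum(event_time, censor_time)
    frame["event"] = (event_time <= censor_time).astype(np.int64)
    return frame


def default_cohort_spec(n: int = 400, seed: int = 0) -> CohortSpec:
    """A cohort spec emulating a resected-PDAC study population.

    Covariate prevalences follow the marginal distribution of a surgical
    PDAC cohort (about half with intratumoral necrosis, ~30% grade G3,
    ~80% perineural invasion, ~35% R1 margins, TNM stages I/II/III at
    roughly 25/54/21%).  Hazard effects use the multivariate hazard
    ratios reported for such cohorts (stage II 2.584, stage III 4.384
    vs. stage I; low vs. high stromal component 1.876; G3 2.124;
    perineural invasion 2.147); the low-stromal label follows a logistic
    model with odds ratios 3.530 for necrosis and 2.281 for R1 margins.
    Baseline hazard 0.02/month and censoring 0.025/month give a median
    observed follow-up comparable to a ~2.5-year accrual window.
    """
    return CohortSpec(
        n=n,
        binary_covariates={
            "necrosis": 0.51,
            "grade_g3": 0.30,
            "perineural_invasion": 0.82,
            "lymphovascular_invasion": 0.36,
            "r1_status": 0.34,
        },
        categorical_covariates={
            "tnm_stage": {"I": 0.25, "II": 0.54, "III": 0.21},
        },
        log_hazard_effects={
            "tnm_stage_II": math.log(2.584),
            "tnm_stage_III": math.log(4.384),
            "low_stromal": math.log(1.876),
            "grade_g3": math.log(2.124),
            "perineural_invasion": math.log(2.147),
        },
        baseline_hazard=0.02,
        censor_rate=0.025,
        logistic_effects={
            "necrosis": math.log(3.530),
            "r1_status": math.log(2.281),
        },
        logistic_intercept=-0.60,
        seed=seed,
    )
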