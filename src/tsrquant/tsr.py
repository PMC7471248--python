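"""Tumor-stroma ratio computation and categorization.

Two evaluation paths are supported, mirroring how TSR is obtained in
practice:

* the *pixel* path counts epithelium and stroma pixel areas inside the ROI
  of a segmented slide and takes their ratio;
* the *semi-quantitative* path emulates pathologist scoring: per-field
  epithelium percentages are averaged over medium-power fields, rounded to
  the nearest decile, and expressed as a ratio like 6/4.

In both paths TSR > 1 denotes a low stromal component and TSR <= 1 a high
stromal component (the cutoff that best separates prognostic groups in
pancreatic ductal adenocarcinoma); the cutoff is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .labels import (
    HIGH_STROMAL,
    LABEL_BACKGROUND,
    LABEL_EPITHELIUM,
    LABEL_STROMA,
    LOW_STROMAL,
)
from .tiling import ROIMask

__all__ = [
    "AreaSummary",
    "TSRResult",
    "SemiQuantScore",
    "compute_areas",
    "compute_tsr",
    "semiquant_score",
    "aggregate_patient",
    "DEFAULT_CUTOFF",
]

DEFAULT_CUTOFF = 1.0


@dataclass(frozen=True)
class AreaSummary:
    """Pixel areas per class inside an ROI; areas are conserved."""

    area_epithelium: int
    area_stroma: int
    area_other: int = 0

    def __post_init__(self) -> None:
        if min(self.area_epithelium, self.area_stroma, self.area_other) < 0:
            raise ValueError("areas must be non-negative")

    @property
    def roi_area(self) -> int:
        return self.area_epithelium + self.area_stroma + self.area_other


@dataclass(frozen=True)
class TSRResult:
    """A TSR value with its stromal-component category.

    ``tsr`` is epithelium area over stroma area (``inf`` when stroma is
    absent but epithelium is present); ``epithelium_fraction`` is the
    epithelium share of tumor tissue (epithelium + stroma).
    """

    tsr: float
    epithelium_fraction: float
    category: str
    method: Literal["pixel", "semiquant"] = "pixel"


@dataclass(frozen=True)
class SemiQuantScore:
    """Pathologist-style decile score over medium-power fields."""

    field_fractions: tuple[float, ...]
    mean_fraction: float
    decile_ratio: tuple[int, int]  # (epithelium, stroma) out of 10
    result: TSRResult


def _categorize(tsr: float, cutoff: float) -> str:
    return LOW_STROMAL if tsr > cutoff else HIGH_STROMAL


def compute_areas(mask: np.ndarray, roi: ROIMask | np.ndarray) -> AreaSummary:
    """Count per-class pixel areas of a label mask restricted to the ROI."""
    mask = np.asarray(mask)
    roi_mask = roi.mask if isinstance(roi, ROIMask) else np.asarray(roi, dtype=bool)
    if mask.shape != roi_mask.shape:
        raise ValueError(f"mask shape {mask.shape} does not match ROI {roi_mask.shape}")
    if not roi_mask.any():
        raise ValueError("empty ROI")
    inside = mask[roi_mask]
    return AreaSummary(
        area_epithelium=int((inside == LABEL_EPITHELIUM).sum()),
        area_stroma=int((inside == LABEL_STROMA).sum()),
        area_other=int((inside == LABEL_BACKGROUND).sum()),
    )


def compute_tsr(areas: AreaSummary, cutoff: float = DEFAULT_CUTOFF) -> TSRResult:
    """TSR = epithelium area / stroma area, categorized at the cutoff.

    Zero stroma with nonzero epithelium yields an ``inf`` TSR (still a
    well-defined low-stromal category); no tumor tissue at all is an
    error because the ratio is undefined.
    """
    epi, stroma = areas.area_epithelium, areas.area_stroma
    if epi + stroma == 0:
        raise ValueError("TSR undefined: no epithelium or stroma in ROI")
    tsr = math.inf if stroma == 0 else epi / stroma
    return TSRResult(
        tsr=tsr,
        epithelium_fraction=epi / (epi + stroma),
        category=_categorize(tsr, cutoff),
        method="pixel",
    )


def semiquant_score(
    field_fractions: Sequence[float], cutoff: float = DEFAULT_CUTOFF
) -> SemiQuantScore:
    """Pathologist-style semi-quantitative TSR from per-field fractions.

    The mean epithelium fraction over medium-power fields is rounded
    half-up to the nearest decile, giving a ratio like 6/4 (epithelium
    deciles / stroma deciles out of 10); TSR is their quotient.
    """
    fracs = tuple(float(f) for f in field_fractions)
    if not fracs:
        raise ValueError("at least one field fraction is required")
    if any(not 0.0 <= f <= 1.0 for f in fracs):
        raise ValueError("field fractions must lie in [0, 1]")
    mean = sum(fracs) / len(fracs)
    # Half-up on the decile scale; epsilon guards binary representation of
    # exact ties like 0.45 -> 4.5 deciles -> 5.
    epi_deciles = int(math.floor(mean * 10.0 + 0.5 + 1e-9))
    stroma_deciles = 10 - epi_deciles
    tsr = math.inf if stroma_deciles == 0 else epi_deciles / stroma_deciles
    result = TSRResult(
        tsr=tsr,
        epithelium_fraction=epi_deciles / 10.0,
        category=_categorize(tsr, cutoff),
        method="semiquant",
    )
    return SemiQuantScore(
        field_fractions=fracs,
        mean_fraction=mean,
        decile_ratio=(epi_deciles, stroma_deciles),
        result=result,
    )


def aggregate_patient(
    slide_areas: Sequence[AreaSummary], cutoff: float = DEFAULT_CUTOFF
) -> TSRResult:
    """Pool pixel areas over a patient's slides (typically 2-3) and score.

    Pooling is area-weighted by construction: summing pixel counts across
    slides is identical to counting over the concatenated masks.
    """
    if not slide_areas:
        raise ValueError("at least one slide is required")
    pooled = AreaSummary(
        area_epithelium=sum(a.area_epithelium for a in slide_areas),
        area_stroma=sum(a.area_stroma for a in slide_areas),
        area_other=sum(a.area_other for a in slide_areas),
    )
    return compute_tsr(pooled, cutoff=cutoff)
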