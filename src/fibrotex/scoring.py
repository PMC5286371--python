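"""Invasion-assay arithmetic and the weighted IHC histoscore.

Organotypic collagen invasion assays are scored by the area of invading cells
relative to the analysed matrix region, normalised to a matched control to
give the invasion index.  Proliferation is summarised as the Ki67-positive
fraction of counted cells.  Immunohistochemistry staining is summarised by
the weighted histoscore,

    H = 1·(% weak) + 2·(% moderate) + 3·(% strong),   H ∈ [0, 300],

with multiple blinded raters combined by their mean.

This module works from cell/region masks and tabulated counts or class
fractions; it does not perform segmentation or stain classification itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .imaging_core import BinaryMask

__all__ = [
    "ScoringError",
    "InvasionMeasurement",
    "CellCounts",
    "ClassFractions",
    "invasion_percentage",
    "invasion_index",
    "ki67_fraction",
    "histoscore",
    "consensus_histoscore",
    "region_area_from_mask",
]

#: default microscope field area for surface cell counts, mm²
DEFAULT_FIELD_AREA_MM2 = 0.046

#: tolerated drift of the class-fraction sum from 100 before it is an error
_SUM_TOL = 0.01


class ScoringError(ValueError):
    """Raised for invalid measurements, counts or class fractions."""


@dataclass(frozen=True)
class InvasionMeasurement:
    """Invading-cell area within a total analysed region (same units)."""

    invading_cell_area: float
    total_region_area: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.total_region_area > 0):
            raise ScoringError("total_region_area must be positive")
        if not (0 <= self.invading_cell_area <= self.total_region_area):
            raise ScoringError("invading area must lie in [0, total area]")


@dataclass(frozen=True)
class CellCounts:
    """Marker-positive and total cell counts for one microscope field."""

    total_cells: int
    positive_cells: int
    field_area_mm2: float = DEFAULT_FIELD_AREA_MM2

    def __post_init__(self) -> None:
        if self.total_cells < 0 or self.positive_cells < 0:
            raise ScoringError("cell counts must be non-negative")
        if self.positive_cells > self.total_cells:
            raise ScoringError("positive_cells cannot exceed total_cells")
        if not (self.field_area_mm2 > 0):
            raise ScoringError("field_area_mm2 must be positive")


@dataclass(frozen=True)
class ClassFractions:
    """Percent area per staining-intensity class; must sum to 100.

    A sum within ±0.01 of 100 is renormalized exactly; a larger deviation is
    rejected, guarding against silent double counting of area.
    """

    pct_negative: float
    pct_weak: float
    pct_moderate: float
    pct_strong: float

    def __post_init__(self) -> None:
        vals = (self.pct_negative, self.pct_weak, self.pct_moderate, self.pct_strong)
        for v in vals:
            if not (0 <= v <= 100):
                raise ScoringError(f"class percentage {v} outside [0, 100]")
        total = sum(vals)
        if abs(total - 100.0) > _SUM_TOL:
            raise ScoringError(f"class percentages sum to {total}, expected 100")
        if total != 100.0:
            scale = 100.0 / total
            object.__setattr__(self, "pct_negative", self.pct_negative * scale)
            object.__setattr__(self, "pct_weak", self.pct_weak * scale)
            object.__setattr__(self, "pct_moderate", self.pct_moderate * scale)
            object.__setattr__(self, "pct_strong", self.pct_strong * scale)


def invasion_percentage(m: InvasionMeasurement) -> float:
    """Invading-cell area as a percentage of the total analysed region."""
    return 100.0 * m.invading_cell_area / m.total_region_area


def invasion_index(sample_pct: float, control_pct: float) -> float:
    """Sample invasion percentage relative to its matched control's."""
    if control_pct == 0:
        raise ScoringError("undefined index: control percentage is zero")
    return sample_pct / control_pct


def ki67_fraction(c: CellCounts) -> float:
    """Ki67-positive cells as a percentage of all counted cells."""
    if c.total_cells == 0:
        raise ScoringError("cannot compute a fraction of zero cells")
    return 100.0 * c.positive_cells / c.total_cells


def histoscore(f: ClassFractions) -> float:
    """Weighted histoscore: 1·%weak + 2·%moderate + 3·%strong, in [0, 300]."""
    return 1.0 * f.pct_weak + 2.0 * f.pct_moderate + 3.0 * f.pct_strong


def consensus_histoscore(scores: Sequence[float]) -> float:
    """Mean histoscore over blinded raters."""
    if len(scores) == 0:
        raise ScoringError("need at least one rater score")
    for s in scores:
        if not (0 <= s <= 300):
            raise ScoringError(f"score {s} outside [0, 300]")
    return float(np.mean(scores))


def region_area_from_mask(
    cell_mask: BinaryMask,
    region_mask: BinaryMask,
    pixel_size_um: float = 1.0,
) -> InvasionMeasurement:
    """Invading and total areas (µm²) from a cell mask clipped to a region mask."""
    if cell_mask.shape != region_mask.shape:
        raise ScoringError(
            f"mask shapes differ: {cell_mask.shape} vs {region_mask.shape}"
        )
    region_px = int(region_mask.pixels.sum())
    if region_px == 0:
        raise ScoringError("empty analysis region")
    invading_px = int((cell_mask.pixels & region_mask.pixels).sum())
    area = pixel_size_um**2
    return InvasionMeasurement(invading_px * area, region_px * area)
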