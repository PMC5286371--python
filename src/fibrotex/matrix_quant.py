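"""Depth-resolved fibrillar-collagen area profiles and degradation area.

Two assay read-outs live here:

* Depth profiling of an SHG z-stack paired with a cell-channel stack: the
  cell/collagen interface plane is located first, then the fibrillar collagen
  area fraction is reported at fixed depth increments (default 2.5 µm) below
  it.  One global SHG threshold is fixed from the interface plane and reused
  at every depth, so per-plane threshold drift cannot masquerade as decay.

* Degradation area of a fluorescent (FITC) collagen film: degraded regions
  appear as dark holes in an otherwise uniformly bright film and are reported
  as a percentage of the analysed area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_core import (
    DegenerateHistogramError,
    ImageGrid,
    ImageStack,
    ImagingError,
    auto_threshold,
)

__all__ = [
    "DepthProfile",
    "DegradationResult",
    "detect_interface",
    "fibrillar_area_profile",
    "degradation_area",
]


@dataclass(frozen=True)
class DepthProfile:
    """Area fractions at depth increments below the cell/collagen interface.

    ``depths_um[k]`` is a non-negative multiple of the configured step;
    ``area_fractions[k]`` pools the thresholded foreground over every plane
    mapped to that depth; ``plane_indices[k]`` lists those planes.
    Increments with no plane are simply absent, never interpolated.
    """

    depths_um: tuple[float, ...]
    area_fractions: tuple[float, ...]
    plane_indices: tuple[tuple[int, ...], ...]
    threshold_value: float
    step_um: float


@dataclass(frozen=True)
class DegradationResult:
    """Degraded-area percentage of a collagen film plus threshold provenance."""

    degraded_fraction: float  # percent, 0..100
    threshold_used: float
    method: str


def _plane_threshold(stack: ImageStack, plane_index: int) -> float:
    """SHG foreground threshold fixed from one plane, with fallbacks.

    Otsu on the stated plane; if that plane is constant, Otsu over the pooled
    stack histogram; if the whole stack is constant the threshold equals that
    constant, so nothing is foreground (strictly-above rule).
    """
    try:
        return auto_threshold(stack.planes[plane_index]).threshold_value
    except DegenerateHistogramError:
        pass
    pooled = ImageGrid(
        stack.as_array().reshape(len(stack) * stack.shape[0], stack.shape[1]),
        stack.bit_depth,
        stack.pixel_size_um,
    )
    try:
        return auto_threshold(pooled).threshold_value
    except DegenerateHistogramError:
        return float(stack.planes[plane_index].pixels.flat[0])


def detect_interface(cell_stack: ImageStack, min_cell_fraction: float = 0.05) -> tuple[int, bool]:
    """Locate the cell/collagen interface plane in a surface-first cell stack.

    Returns ``(index, found)`` where ``index`` is the deepest plane whose
    thresholded cell-channel area fraction is at least ``min_cell_fraction``.
    The cell threshold is fixed once, from the plane of maximal signal
    (the stack's maximum projection).  When no plane qualifies the interface
    defaults to plane 0 and ``found`` is False.
    """
    if len(cell_stack) < 1:
        raise ImagingError("empty stack")
    thr = _plane_threshold(cell_stack, int(np.argmax([p.pixels.max() for p in cell_stack.planes])))
    interface = None
    for idx, plane in enumerate(cell_stack.planes):
        if float((plane.pixels > thr).mean()) >= min_cell_fraction:
            interface = idx
    if interface is None:
        return 0, False
    return interface, True


def fibrillar_area_profile(
    shg_stack: ImageStack,
    interface_index: int,
    step_um: float = 2.5,
) -> DepthProfile:
    """Fibrillar collagen area fraction at depth increments below the interface.

    Each plane at or below the interface is assigned to the nearest multiple
    of ``step_um`` by its depth ``(i − interface) · z_step``; the fraction for
    an increment pools foreground pixels over all planes mapped to it.  The
    threshold comes once from the interface plane (see
    :func:`_plane_threshold`) and is reused at every depth.
    """
    if not (0 <= interface_index < len(shg_stack)):
        raise ImagingError(
            f"interface index {interface_index} outside stack of {len(shg_stack)} planes"
        )
    if not (step_um > 0):
        raise ImagingError(f"step_um must be positive, got {step_um}")
    thr = _plane_threshold(shg_stack, interface_index)

    bins: dict[int, list[int]] = {}
    for idx in range(interface_index, len(shg_stack)):
        depth = (idx - interface_index) * shg_stack.z_step_um
        k = int(np.floor(depth / step_um + 0.5))  # nearest increment, half rounds deeper
        bins.setdefault(k, []).append(idx)

    depths, fracs, members = [], [], []
    for k in sorted(bins):
        planes = bins[k]
        fg = sum(int((shg_stack.planes[i].pixels > thr).sum()) for i in planes)
        total = len(planes) * shg_stack.shape[0] * shg_stack.shape[1]
        depths.append(k * step_um)
        fracs.append(fg / total)
        members.append(tuple(planes))
    return DepthProfile(tuple(depths), tuple(fracs), tuple(members), float(thr), float(step_um))


def degradation_area(
    fitc_image: ImageGrid,
    method: str = "mode-fraction",
    fraction: float = 0.5,
) -> DegradationResult:
    """Percentage of a fluorescent collagen film lost to degradation.

    ``mode-fraction`` (default): the intact film dominates the intensity
    histogram, so the threshold is ``fraction`` × the modal intensity and
    degraded pixels are those at or below it.  ``otsu``: the inverted Otsu
    partition — degraded pixels are the Otsu background (at or below the Otsu
    cut), which makes the result invariant to a constant intensity shift.
    """
    px = fitc_image.pixels
    if method == "mode-fraction":
        mode = int(np.bincount(px.ravel(), minlength=fitc_image.max_intensity + 1).argmax())
        thr = fraction * mode
    elif method == "otsu":
        thr = auto_threshold(fitc_image, "otsu").threshold_value
    else:
        raise ImagingError(f"unknown degradation method {method!r}")
    degraded = float((px <= thr).mean()) * 100.0
    return DegradationResult(degraded, float(thr), method)
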