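"""Gray-level co-occurrence matrices swept over distance and direction.

Quantifies collagen fiber texture by accumulating, for every pixel-comparison
distance ``d = 1..max_distance`` and each of four directions (0°, 45°, 90°,
135°), a symmetric normalized co-occurrence matrix over the masked image, and
summarising each matrix with five texture parameters: angular second moment
(ASM / energy), contrast, correlation, inverse difference moment
(IDM / homogeneity) and entropy (natural log).

A pixel pair is counted only when *both* endpoints are valid under the mask —
this is what removes the background bias when the mask selects only the
collagen signal.  Offsets with no valid pair yield a flagged-empty matrix
which downstream consumers record as missing, never as zero.

Offset vectors in (row, col) with the origin at the top-left:
0° → (0, +d), 45° → (−d, +d), 90° → (−d, 0), 135° → (−d, −d).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging_core import MaskedImage

__all__ = [
    "DIRECTION_OFFSETS",
    "FEATURE_NAMES",
    "GLCMError",
    "QuantizedImage",
    "GLCMatrix",
    "TextureFeatureSet",
    "TextureProfile",
    "quantize",
    "cooccurrence",
    "features",
    "texture_profile",
]

#: unit offset vectors (row, col) per direction, scaled by the distance
DIRECTION_OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}

FEATURE_NAMES = ("asm", "contrast", "correlation", "idm", "entropy")


class GLCMError(ValueError):
    """Raised for invalid quantization or co-occurrence inputs."""


@dataclass(frozen=True)
class QuantizedImage:
    """Gray levels 0..n_levels−1 on valid pixels; invalid pixels are ignored."""

    levels: np.ndarray
    valid: np.ndarray
    n_levels: int


@dataclass(frozen=True)
class GLCMatrix:
    """Normalized symmetric co-occurrence matrix for one (distance, direction).

    ``pair_count`` is the number of ordered pixel pairs accumulated; each pair
    contributes to both (i, j) and (j, i), and the matrix is normalized to
    total mass 1.  ``pair_count == 0`` flags an empty offset.
    """

    p: np.ndarray
    distance_px: int
    direction_deg: int
    pair_count: int
    n_levels: int

    @property
    def is_empty(self) -> bool:
        return self.pair_count == 0


@dataclass(frozen=True)
class TextureFeatureSet:
    """The five per-offset texture parameters.

    ``correlation`` is NaN when the marginal variance is zero (all mass on a
    single gray level), in which case :attr:`correlation_defined` is False.
    """

    asm: float
    contrast: float
    correlation: float
    idm: float
    entropy: float

    @property
    def correlation_defined(self) -> bool:
        return not math.isnan(self.correlation)

    def as_dict(self) -> dict[str, float]:
        return {
            "asm": self.asm,
            "contrast": self.contrast,
            "correlation": self.correlation,
            "idm": self.idm,
            "entropy": self.entropy,
        }


@dataclass(frozen=True)
class TextureProfile:
    """Long-format table of texture parameters over distances and directions.

    Columns: ``distance_px, direction_deg, feature, value, pair_count``.
    Offsets with no valid pixel pair carry no rows (missing, not zero).
    """

    df: pd.DataFrame
    n_levels: int
    max_distance: int
    directions: tuple[int, ...]

    @property
    def n_values(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_levels: int = 0, max_distance: int = 0,
                 directions: tuple[int, ...] = ()) -> "TextureProfile":
        df = pd.read_csv(path)
        required = {"distance_px", "direction_deg", "feature", "value"}
        if not required.issubset(df.columns):
            raise GLCMError(f"profile file missing columns {required - set(df.columns)}")
        if not max_distance and len(df):
            max_distance = int(df["distance_px"].max())
        if not directions and len(df):
            directions = tuple(sorted(int(d) for d in df["direction_deg"].unique()))
        return cls(df, n_levels, max_distance, directions)


def quantize(masked: MaskedImage, n_levels: int = 64) -> QuantizedImage:
    """Linearly bin valid-pixel intensities into ``n_levels`` gray levels.

    The valid range [min, max] maps through
    ``level = floor((n_levels − 1) · (v − min) / (max − min))`` so the minimum
    lands on level 0 and the maximum on ``n_levels − 1``; a constant valid
    region maps entirely to level 0.
    """
    if n_levels < 2:
        raise GLCMError(f"n_levels must be >= 2, got {n_levels}")
    if masked.n_valid == 0:
        raise GLCMError("no valid pixels to quantize")
    px = masked.image.pixels.astype(np.int64)
    vals = px[masked.valid]
    vmin, vmax = int(vals.min()), int(vals.max())
    if vmin == vmax:
        levels = np.zeros(px.shape, dtype=np.int64)
    else:
        levels = (px - vmin) * (n_levels - 1) // (vmax - vmin)
        np.clip(levels, 0, n_levels - 1, out=levels)  # out-of-range only off-mask
    return QuantizedImage(levels, masked.valid, n_levels)


def cooccurrence(q: QuantizedImage, distance_px: int, direction_deg: int) -> GLCMatrix:
    """Symmetric normalized GLCM at one offset, skipping masked pixel pairs."""
    if distance_px < 1:
        raise GLCMError(f"distance_px must be >= 1, got {distance_px}")
    if direction_deg not in DIRECTION_OFFSETS:
        raise GLCMError(f"direction must be one of {sorted(DIRECTION_OFFSETS)}, got {direction_deg}")
    dr, dc = (distance_px * o for o in DIRECTION_OFFSETS[direction_deg])
    rows, cols = q.levels.shape
    n = q.n_levels

    def span(delta: int, size: int) -> tuple[slice, slice]:
        if delta >= 0:
            return slice(0, size - delta), slice(delta, size)
        return slice(-delta, size), slice(0, size + delta)

    src_r, dst_r = span(dr, rows)
    src_c, dst_c = span(dc, cols)
    if src_r.start >= src_r.stop or src_c.start >= src_c.stop:
        return GLCMatrix(np.zeros((n, n)), distance_px, direction_deg, 0, n)

    both = q.valid[src_r, src_c] & q.valid[dst_r, dst_c]
    i = q.levels[src_r, src_c][both]
    j = q.levels[dst_r, dst_c][both]
    count = i.size
    if count == 0:
        return GLCMatrix(np.zeros((n, n)), distance_px, direction_deg, 0, n)
    c = np.bincount(i * n + j, minlength=n * n).reshape(n, n).astype(np.float64)
    p = (c + c.T) / (2.0 * count)
    return GLCMatrix(p, distance_px, direction_deg, count, n)


def features(glcm: GLCMatrix) -> TextureFeatureSet:
    """The five texture parameters of one co-occurrence matrix.

    ASM = Σ p²; contrast = Σ (i−j)² p; IDM = Σ p / (1 + (i−j)²);
    entropy = −Σ p ln p (0·ln 0 = 0); correlation = Σ (i−μ)(j−μ) p / σ² with
    μ, σ² the marginal mean/variance (identical across axes by symmetry).
    Zero marginal variance makes correlation undefined (NaN).
    """
    if glcm.is_empty:
        raise GLCMError("empty GLCM: no valid pixel pair at this offset")
    p = glcm.p
    n = glcm.n_levels
    idx = np.arange(n, dtype=np.float64)
    diff2 = (idx[:, None] - idx[None, :]) ** 2

    asm = float((p * p).sum())
    contrast = float((diff2 * p).sum())
    idm = float((p / (1.0 + diff2)).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())

    marginal = p.sum(axis=1)
    mu = float(idx @ marginal)
    var = float(((idx - mu) ** 2) @ marginal)
    if var == 0.0:
        correlation = math.nan
    else:
        correlation = float(((idx[:, None] - mu) * (idx[None, :] - mu) * p).sum() / var)
    return TextureFeatureSet(asm, contrast, correlation, idm, entropy)


def texture_profile(
    masked: MaskedImage,
    n_levels: int = 64,
    max_distance: int = 100,
    directions: tuple[int, ...] = (0, 45, 90, 135),
) -> TextureProfile:
    """Full texture sweep: five parameters per (distance, direction) offset.

    With the default configuration of 100 distances and four directions a
    fully valid image produces 2,000 parameter values.
    """
    q = quantize(masked, n_levels)
    records: list[tuple[int, int, str, float, int]] = []
    for d in range(1, max_distance + 1):
        for ang in directions:
            g = cooccurrence(q, d, ang)
            if g.is_empty:
                continue
            fs = features(g)
            for name, value in fs.as_dict().items():
                records.append((d, ang, name, value, g.pair_count))
    df = pd.DataFrame.from_records(
        records, columns=["distance_px", "direction_deg", "feature", "value", "pair_count"]
    )
    return TextureProfile(df, n_levels, max_distance, tuple(directions))
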