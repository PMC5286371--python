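"""Seeded synthetic inputs with the statistical structure each stage assumes.

Every generator is a pure function of its spec plus an integer seed (one
`numpy.random.Generator` per call, no global state), so reruns are
byte-identical.  The generators plant known ground truth — a correlation
length, per-plane bright-area fractions, a degraded fraction, an invading
fraction, a target histoscore — which the corresponding analysis stage must
recover, closing the verification loop for the whole pipeline without any
external image data.

Generators
----------
gen_correlated_field
    Stationary Gaussian random field with isotropic exponential
    autocorrelation exp(−r/ℓ), synthesised by circulant embedding on a 2×
    padded torus; a stand-in for SHG collagen texture.  The exponential form
    is deliberate: it makes the GLCM correlation-vs-distance curve itself
    near-exponential, so decay-distance recovery is a meaningful oracle.
gen_fiber_image
    Random anti-aliased line segments with Gaussian blur and noise.
gen_depth_stack
    SHG z-stack with exact per-plane bright fractions, paired with a
    cell-channel stack defining the interface plane.
gen_degradation_image
    Bright film with dark discs covering an exact target fraction.
gen_invasion_masks
    Full-rectangle region mask plus a scattered-blob cell mask of exact
    coverage.
gen_class_fractions
    Random staining class fractions realising a target histoscore.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .imaging_core import BinaryMask, ImageGrid, ImageStack
from .scoring import ClassFractions

__all__ = [
    "FieldSpec",
    "FiberSpec",
    "gen_correlated_field",
    "gen_fiber_image",
    "gen_depth_stack",
    "gen_degradation_image",
    "gen_invasion_masks",
    "gen_class_fractions",
    "baseline_cell_mask",
]


@dataclass(frozen=True)
class FieldSpec:
    """Spec for a correlated random field.

    ``correlation_length_px`` must stay below a quarter of the smaller image
    side so the decay is observable within the texture sweep.
    """

    size_px: tuple[int, int] = (512, 512)
    correlation_length_px: float = 10.0
    mean: float = 128.0
    sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        r, c = self.size_px
        if r < 8 or c < 8:
            raise ValueError(f"field too small: {self.size_px}")
        if not (0 < self.correlation_length_px < min(r, c) / 4):
            raise ValueError(
                "correlation_length_px must be in (0, min(size)/4) "
                f"= (0, {min(r, c) / 4}), got {self.correlation_length_px}"
            )
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass(frozen=True)
class FiberSpec:
    """Spec for a fibrous line-segment image."""

    size_px: tuple[int, int] = (256, 256)
    n_fibers: int = 40
    length_px: float = 60.0
    length_jitter: float = 20.0
    blur_sigma: float = 1.0
    noise_sd: float = 8.0
    background: float = 20.0
    intensity: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be non-negative")
        if self.length_px <= 0 or self.blur_sigma < 0 or self.noise_sd < 0:
            raise ValueError("length_px must be positive; blur/noise non-negative")


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def gen_correlated_field(spec: FieldSpec, pixel_size_um: float = 1.0) -> ImageGrid:
    """Gaussian random field with autocorrelation exp(−r/ℓ), mapped to 8-bit.

    Circulant embedding: the target covariance is laid out on a torus twice
    the requested size, its FFT gives the spectral eigenvalues (clipped at
    zero against embedding leakage), and filtering white noise through their
    square root yields a field with the exact prescribed covariance, from
    which the requested sub-block is cut.  Intensities are the affine map
    ``mean + sd·z`` rounded and clipped to [0, 255].
    """
    rng = np.random.default_rng(spec.seed)
    n_r, n_c = spec.size_px
    m_r, m_c = 2 * n_r, 2 * n_c
    dr = np.minimum(np.arange(m_r), m_r - np.arange(m_r))
    dc = np.minimum(np.arange(m_c), m_c - np.arange(m_c))
    r = np.hypot(dr[:, None], dc[None, :])
    cov = np.exp(-r / spec.correlation_length_px)
    lam = np.fft.fft2(cov).real
    np.clip(lam, 0.0, None, out=lam)
    white = rng.standard_normal((m_r, m_c))
    z = np.fft.ifft2(np.sqrt(lam) * np.fft.fft2(white)).real[:n_r, :n_c]
    return ImageGrid(_to_uint8(spec.mean + spec.sd * z), 8, pixel_size_um)


def gen_fiber_image(spec: FiberSpec, pixel_size_um: float = 1.0) -> ImageGrid:
    """Random blurred line segments over a noisy background, 8-bit."""
    from skimage.draw import line_aa

    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.size_px
    canvas = np.zeros((rows, cols), dtype=np.float64)
    for _ in range(spec.n_fibers):
        r0 = rng.uniform(0, rows - 1)
        c0 = rng.uniform(0, cols - 1)
        theta = rng.uniform(0, np.pi)
        length = max(2.0, spec.length_px + rng.normal(0, spec.length_jitter))
        r1 = np.clip(r0 + length * np.sin(theta), 0, rows - 1)
        c1 = np.clip(c0 + length * np.cos(theta), 0, cols - 1)
        rr, cc, val = line_aa(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
        np.maximum.at(canvas, (rr, cc), val)
    img = spec.background + spec.intensity * gaussian_filter(canvas, spec.blur_sigma)
    img += rng.normal(0, spec.noise_sd, size=img.shape)
    return ImageGrid(_to_uint8(img), 8, pixel_size_um)


def _exact_random_mask(rng: np.random.Generator, size: tuple[int, int],
                       target_count: int, radius_range: tuple[int, int]) -> np.ndarray:
    """Union of random discs trimmed/padded to exactly ``target_count`` pixels."""
    rows, cols = size
    mask = np.zeros((rows, cols), dtype=bool)
    if target_count <= 0:
        return mask
    yy, xx = np.ogrid[:rows, :cols]
    guard = 0
    while mask.sum() < target_count:
        guard += 1
        if guard > 100_000:
            break
        rad = rng.integers(radius_range[0], radius_range[1] + 1)
        cy = rng.integers(0, rows)
        cx = rng.integers(0, cols)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2
    excess = int(mask.sum()) - target_count
    if excess > 0:
        on = np.flatnonzero(mask.ravel())
        off = rng.choice(on, size=excess, replace=False)
        mask.ravel()[off] = False
    elif excess < 0:  # guard tripped: pad with random free pixels
        free = np.flatnonzero(~mask.ravel())
        add = rng.choice(free, size=-excess, replace=False)
        mask.ravel()[add] = True
    return mask


def gen_depth_stack(
    fractions: tuple[float, ...],
    size: tuple[int, int] = (128, 128),
    seed: int = 0,
    z_step_um: float = 2.5,
    pixel_size_um: float = 1.0,
    interface_index: int = 0,
    cell_fraction: float = 0.5,
) -> tuple[ImageStack, ImageStack]:
    """(SHG stack, cell stack) with planted per-plane bright fractions.

    The SHG stack has ``interface_index + len(fractions)`` planes; plane
    ``interface_index + k`` carries exactly ``round(fractions[k] · n_pixels)``
    bright pixels (planes above the interface repeat ``fractions[0]``).  The
    cell channel covers planes 0..``interface_index`` at ``cell_fraction``
    and is empty below, so interface detection recovers the construction.
    """
    for f in fractions:
        if not (0 <= f <= 1):
            raise ValueError(f"fraction {f} outside [0, 1]")
    rng = np.random.default_rng(seed)
    rows, cols = size
    npix = rows * cols

    def shg_plane(frac: float) -> ImageGrid:
        base = rng.integers(5, 26, size=(rows, cols))
        k = int(round(frac * npix))
        flat = base.ravel()
        if k:
            idx = rng.choice(npix, size=k, replace=False)
            flat[idx] = rng.integers(200, 241, size=k)
        return ImageGrid(flat.reshape(rows, cols).astype(np.uint8), 8, pixel_size_um)

    plane_fracs = [fractions[0]] * interface_index + list(fractions)
    shg = ImageStack(tuple(shg_plane(f) for f in plane_fracs), z_step_um)

    def cell_plane(frac: float) -> ImageGrid:
        base = rng.integers(0, 11, size=(rows, cols))
        k = int(round(frac * npix))
        flat = base.ravel()
        if k:
            idx = rng.choice(npix, size=k, replace=False)
            flat[idx] = rng.integers(180, 221, size=k)
        return ImageGrid(flat.reshape(rows, cols).astype(np.uint8), 8, pixel_size_um)

    cells = ImageStack(
        tuple(
            cell_plane(cell_fraction if i <= interface_index else 0.0)
            for i in range(len(plane_fracs))
        ),
        z_step_um,
    )
    return shg, cells


def gen_degradation_image(
    fraction: float,
    size: tuple[int, int] = (256, 256),
    seed: int = 0,
    pixel_size_um: float = 1.0,
    film_intensity: float = 200.0,
    hole_intensity: float = 30.0,
    noise_sd: float = 4.0,
) -> ImageGrid:
    """Bright collagen film with dark discs covering exactly ``fraction``.

    The dark-hole union is trimmed pixel-exactly to the target count before
    mild Gaussian noise is added, so the planted degraded fraction is exact
    up to the noise never crossing the mode-fraction threshold.
    """
    if not (0 <= fraction <= 1):
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    rng = np.random.default_rng(seed)
    rows, cols = size
    holes = _exact_random_mask(rng, size, int(round(fraction * rows * cols)), (4, 12))
    img = np.where(holes, hole_intensity, film_intensity).astype(np.float64)
    img += rng.normal(0, noise_sd, size=img.shape)
    return ImageGrid(_to_uint8(img), 8, pixel_size_um)


def gen_invasion_masks(
    invading_fraction: float,
    size: tuple[int, int] = (256, 256),
    seed: int = 0,
) -> tuple[BinaryMask, BinaryMask]:
    """(cell mask, region mask): scattered blobs of exact coverage in a full rectangle."""
    if not (0 <= invading_fraction <= 1):
        raise ValueError(f"invading_fraction {invading_fraction} outside [0, 1]")
    rng = np.random.default_rng(seed)
    rows, cols = size
    cells = _exact_random_mask(rng, size, int(round(invading_fraction * rows * cols)), (2, 8))
    region = np.ones((rows, cols), dtype=bool)
    return (
        BinaryMask(cells, "synthetic-blobs", 0.0),
        BinaryMask(region, "synthetic-rectangle", 0.0),
    )


def gen_class_fractions(target_histoscore: float, seed: int = 0) -> ClassFractions:
    """Random valid staining class fractions whose histoscore hits the target.

    Rejection sampling over random weight mixtures scaled to the target, with
    a deterministic piecewise two-class construction as fallback.  Targets 0
    and 300 force the unique all-negative / all-strong solutions.
    """
    if not (0 <= target_histoscore <= 300):
        raise ValueError(f"target histoscore {target_histoscore} outside [0, 300]")
    if target_histoscore == 0:
        return ClassFractions(100.0, 0.0, 0.0, 0.0)
    if target_histoscore == 300:
        return ClassFractions(0.0, 0.0, 0.0, 100.0)
    rng = np.random.default_rng(seed)
    for _ in range(10_000):
        raw = rng.uniform(0.05, 1.0, size=3)  # weak, moderate, strong weights
        scale = target_histoscore / (raw[0] + 2 * raw[1] + 3 * raw[2])
        w, m, s = raw * scale
        total = w + m + s
        if total <= 100.0 and max(w, m, s) <= 100.0:
            return ClassFractions(100.0 - total, w, m, s)
    t = target_histoscore
    if t <= 100:
        return ClassFractions(100.0 - t, t, 0.0, 0.0)
    if t <= 200:
        return ClassFractions(0.0, 200.0 - t, t - 100.0, 0.0)
    return ClassFractions(0.0, 0.0, 300.0 - t, t - 200.0)


def baseline_cell_mask(
    image: ImageGrid,
    threshold: float | None = None,
    min_size_px: int = 20,
) -> BinaryMask:
    """Baseline cell segmentation: intensity threshold + small-object removal.

    A deliberately simple reference segmentation (Otsu threshold on the
    cell-dominant channel followed by a connected-component size filter) used
    to drive end-to-end invasion-scoring tests; it makes no claim to match
    any production cell detector.
    """
    from skimage.morphology import remove_small_objects

    from .imaging_core import auto_threshold

    if threshold is None:
        mask = auto_threshold(image, "otsu")
        fg, thr = mask.pixels, mask.threshold_value
    else:
        fg, thr = image.pixels > threshold, float(threshold)
    cleaned = remove_small_objects(fg, max_size=min_size_px - 1)
    return BinaryMask(cleaned, "baseline-threshold-sizefilter", thr)
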