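"""Peripheral texture features over the contracted-border annulus.

The region between the original lesion border and the border contracted by
L = 2r is tiled with overlapping circular patches of radius r whose centers
sit on the mid-curve (offset r inside the original border) at arc-length
spacing r, so each patch is tangent to both borders and consecutive patches
overlap by at least half a radius.

Inside each patch, per color channel, three statistics are computed: GLCM
homogeneity (on quantized values), and the mean and population standard
deviation of the raw values.  Aggregating each over all patches by mean and
by min yields six features per channel — 18 for RGB or HSV, 36 combined.
Low minimum homogeneity along the periphery flags a sharp pigment cutoff,
the dermoscopic malignancy cue this pipeline quantifies.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hsv

from ._geometry import as_closed, polyline_length, resample_closed
from .levelset import ContractionResult
from skimage import measure

__all__ = [
    "GLCMParams",
    "GLCMatrix",
    "PatchSet",
    "FeatureVector",
    "NoPairsError",
    "quantize_channel",
    "compute_glcm",
    "homogeneity",
    "patch_statistics",
    "build_patch_layer",
    "extract_features",
    "COLOR_SPACES",
]

COLOR_SPACES = {
    "RGB": ("R", "G", "B"),
    "HSV": ("H", "S", "V"),
    "RGB+HSV": ("R", "G", "B", "H", "S", "V"),
}

#: aggregate order per channel, fixed across the package and the CSV layout
STAT_NAMES = (
    "hom_mean", "hom_min", "mean_mean", "mean_min", "std_mean", "std_min",
)


class NoPairsError(ValueError):
    """A patch contains no valid co-occurrence pair at the given offset."""


@dataclass(frozen=True)
class GLCMParams:
    """Co-occurrence settings: quantization levels, pixel offset, value range.

    ``offset`` is ``(dx, dy)`` with x = col and y = row; the default (1, 0)
    pairs each pixel with its right-hand neighbor.  A single offset is used
    (no direction averaging); the matrix is symmetrized and normalized.
    """

    levels: int = 32
    offset: tuple[int, int] = (1, 0)
    value_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.offset == (0, 0):
            raise ValueError("offset must be non-zero")


@dataclass
class GLCMatrix:
    """A levels x levels co-occurrence matrix for one patch and offset."""

    counts: np.ndarray
    levels: int
    offset: tuple[int, int]
    normalized: bool


@dataclass
class PatchSet:
    """Overlapping circular patches tiling the peripheral annulus.

    ``centers`` are sub-pixel ``(row, col)`` points ordered along the
    mid-curve; ``patch_pixel_sets`` holds, per patch, the ``(rows, cols)``
    index arrays of its pixels clipped to the annulus.
    """

    centers: np.ndarray
    radius_r: float
    spacing: float
    patch_pixel_sets: list[tuple[np.ndarray, np.ndarray]] = field(repr=False)

    def __len__(self) -> int:
        return len(self.patch_pixel_sets)


def quantize_channel(
    channel: np.ndarray,
    levels: int,
    value_range: tuple[float, float] = (0.0, 255.0),
) -> np.ndarray:
    """Uniformly bin a channel over its full nominal range.

    Monotone by construction; out-of-range values are clipped into
    ``[0, levels)``.  A constant channel maps to a single level.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    lo, hi = value_range
    if hi <= lo:
        raise ValueError("invalid value_range")
    scaled = (np.asarray(channel, dtype=float) - lo) / (hi - lo)
    q = np.floor(scaled * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def compute_glcm(
    quantized: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    offset: tuple[int, int] = (1, 0),
    levels: int = 32,
) -> GLCMatrix:
    """Co-occurrence matrix over an arbitrary (masked) pixel set.

    Counts pairs ``(p, p + offset)`` with both pixels inside the patch pixel
    set, symmetrizes (each pair counted in both directions), and normalizes
    to sum 1.

    Raises
    ------
    NoPairsError
        When no valid pair exists; the caller drops the patch.
    """
    q = np.asarray(quantized)
    rows = np.asarray(rows, dtype=np.intp)
    cols = np.asarray(cols, dtype=np.intp)
    if rows.size == 0:
        raise NoPairsError("empty patch")
    h, w = q.shape
    member = np.zeros((h, w), dtype=bool)
    member[rows, cols] = True
    dx, dy = offset
    r2 = rows + dy
    c2 = cols + dx
    ok = (r2 >= 0) & (r2 < h) & (c2 >= 0) & (c2 < w)
    rr, cc, rr2, cc2 = rows[ok], cols[ok], r2[ok], c2[ok]
    pair = member[rr2, cc2]
    if not pair.any():
        raise NoPairsError("no valid co-occurrence pairs at this offset")
    i = q[rr[pair], cc[pair]]
    j = q[rr2[pair], cc2[pair]]
    counts = np.zeros((levels, levels), dtype=float)
    np.add.at(counts, (i, j), 1.0)
    counts = counts + counts.T
    counts /= counts.sum()
    return GLCMatrix(counts=counts, levels=levels, offset=(dx, dy), normalized=True)


def homogeneity(glcm: GLCMatrix | np.ndarray) -> float:
    """Inverse-difference homogeneity  Σ_ij P(i,j) / (1 + |i - j|).

    Equals 1 iff all probability mass lies on the diagonal (every paired
    pixel shares one gray level); sharp local transitions push it down.
    """
    if isinstance(glcm, GLCMatrix):
        if not glcm.normalized:
            raise ValueError("GLCM must be normalized")
        p = glcm.counts
    else:
        p = np.asarray(glcm, dtype=float)
        if abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("GLCM must be normalized (entries summing to 1)")
    n = p.shape[0]
    idx = np.arange(n)
    weights = 1.0 / (1.0 + np.abs(idx[:, None] - idx[None, :]))
    return float((p * weights).sum())


def patch_statistics(
    channel: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    params: GLCMParams = GLCMParams(),
    quantized: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """(homogeneity, mean, std) of one channel over one patch.

    Homogeneity is computed on quantized values; mean and standard deviation
    (population, ddof=0) on the raw values.
    """
    if quantized is None:
        quantized = quantize_channel(channel, params.levels, params.value_range)
    glcm = compute_glcm(quantized, rows, cols, params.offset, params.levels)
    values = np.asarray(channel, dtype=float)[rows, cols]
    return homogeneity(glcm), float(values.mean()), float(values.std(ddof=0))


def _mid_curve(result: ContractionResult, radius_r: float) -> np.ndarray:
    contours = measure.find_contours(result.phi0, -float(radius_r))
    loops = [as_closed(c) for c in contours if len(c) >= 3 and np.allclose(c[0], c[-1])]
    if not loops:
        raise ValueError(
            f"no mid-curve at depth {radius_r} px: lesion too small for this radius"
        )
    return max(loops, key=polyline_length)


def build_patch_layer(
    result: ContractionResult,
    radius_r: float,
    spacing_factor: float = 1.0,
    min_pixels: int = 9,
) -> PatchSet:
    """Tile the annulus with overlapping circular patches of radius r.

    Requires the contraction to have been run with L = 2r so a radius-r
    circle centered on the mid-curve spans the layer exactly, tangent to
    both borders.  Centers are placed along the mid-curve at arc-length
    spacing ``spacing_factor * r`` (default r, i.e. >= 50% overlap).
    """
    if abs(result.distance_L - 2.0 * radius_r) > 1e-9:
        raise ValueError(
            f"patch layer of radius {radius_r} requires contraction distance "
            f"L = {2 * radius_r}, got L = {result.distance_L}"
        )
    annulus = result.annulus_mask.astype(bool)
    if not annulus.any():
        raise ValueError("empty annulus: nothing to tile")
    mid = _mid_curve(result, radius_r)
    total = polyline_length(mid)
    spacing_target = spacing_factor * radius_r
    n = max(int(round(total / spacing_target)), 1)
    centers = resample_closed(mid, n)
    spacing = total / n

    h, w = annulus.shape
    # A pixel belongs to a patch when its unit cell overlaps the circle
    # (center distance <= r + 1/2); this closes the rasterization gap at the
    # annulus edges so the patch union covers the full peripheral layer.
    r_eff = radius_r + 0.5
    rad = int(np.ceil(r_eff))
    dr, dc = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    pixel_sets: list[tuple[np.ndarray, np.ndarray]] = []
    kept_centers = []
    n_dropped = 0
    for cr, cc in centers:
        rr = int(round(cr)) + dr
        ccs = int(round(cc)) + dc
        inb = (rr >= 0) & (rr < h) & (ccs >= 0) & (ccs < w)
        rr_f, cc_f = rr[inb], ccs[inb]
        within = (rr_f - cr) ** 2 + (cc_f - cc) ** 2 <= r_eff**2 + 1e-9
        rr_f, cc_f = rr_f[within], cc_f[within]
        keep = annulus[rr_f, cc_f]
        rr_f, cc_f = rr_f[keep], cc_f[keep]
        if rr_f.size < min_pixels:
            n_dropped += 1
            continue
        kept_centers.append((cr, cc))
        pixel_sets.append((rr_f, cc_f))
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} patches with fewer than {min_pixels} usable "
            "pixels",
            stacklevel=2,
        )
    if len(pixel_sets) < 4:
        raise ValueError(
            f"only {len(pixel_sets)} usable patches: lesion too small for "
            f"radius {radius_r}"
        )
    return PatchSet(
        centers=np.asarray(kept_centers, dtype=float),
        radius_r=float(radius_r),
        spacing=float(spacing),
        patch_pixel_sets=pixel_sets,
    )


@dataclass
class FeatureVector:
    """Ordered peripheral features for one lesion at one radius.

    Per channel, in order: mean homogeneity, min homogeneity, mean of patch
    color means, min of patch color means, mean of patch color stds, min of
    patch color stds.  Channels follow :data:`COLOR_SPACES` order; RGB+HSV
    is the concatenation RGB then HSV (length 36).
    """

    radius_r: float
    color_space: str
    values: np.ndarray
    names: list[str]
    label: str = "unknown"

    def __len__(self) -> int:
        return len(self.values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


def _channel_images(image: np.ndarray, channels: tuple[str, ...]) -> dict[str, np.ndarray]:
    rgb = np.asarray(image, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError("image must be an RGB raster (h, w, 3)")
    out: dict[str, np.ndarray] = {}
    for ch, k in zip("RGB", range(3)):
        if ch in channels:
            out[ch] = rgb[:, :, k]
    if any(ch in channels for ch in "HSV"):
        # H scaled to [0, 255] so all channels share one quantizer; circular
        # hue statistics are not used.
        hsv = rgb2hsv(np.clip(rgb, 0, 255).astype(np.uint8)) * 255.0
        for ch, k in zip("HSV", range(3)):
            if ch in channels:
                out[ch] = hsv[:, :, k]
    return out


def extract_features(
    image: np.ndarray,
    result: ContractionResult,
    radius_r: float,
    color_space: str = "RGB",
    params: GLCMParams = GLCMParams(),
    patch_set: PatchSet | None = None,
    label: str = "unknown",
) -> FeatureVector:
    """Six per-channel peripheral statistics aggregated over the patch layer.

    Feature order per channel: (mean-homogeneity, min-homogeneity,
    mean-of-patch-means, min-of-patch-means, mean-of-patch-stds,
    min-of-patch-stds); 18 values for RGB or HSV, 36 for RGB+HSV.
    """
    if color_space not in COLOR_SPACES:
        raise ValueError(f"color_space must be one of {sorted(COLOR_SPACES)}")
    if np.asarray(image).shape[:2] != result.annulus_mask.shape:
        raise ValueError("image and mask dimensions do not match")
    if patch_set is None:
        patch_set = build_patch_layer(result, radius_r)
    channels = COLOR_SPACES[color_space]
    channel_imgs = _channel_images(image, channels)
    values: list[float] = []
    names: list[str] = []
    for ch in channels:
        arr = channel_imgs[ch]
        q = quantize_channel(arr, params.levels, params.value_range)
        homs, means, stds = [], [], []
        for rows, cols in patch_set.patch_pixel_sets:
            try:
                h, m, s = patch_statistics(arr, rows, cols, params, quantized=q)
            except NoPairsError:
                warnings.warn("patch without co-occurrence pairs dropped", stacklevel=2)
                continue
            homs.append(h)
            means.append(m)
            stds.append(s)
        if not homs:
            raise ValueError(f"no usable patches for channel {ch}")
        homs, means, stds = map(np.asarray, (homs, means, stds))
        stats = (
            homs.mean(), homs.min(),
            means.mean(), means.min(),
            stds.mean(), stds.min(),
        )
        values.extend(float(v) for v in stats)
        names.extend(f"{ch}_{s}" for s in STAT_NAMES)
    return FeatureVector(
        radius_r=float(radius_r),
        color_space=color_space,
        values=np.asarray(values),
        names=names,
        label=label,
    )
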