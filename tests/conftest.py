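"""Shared fixtures: simple shapes, random blobs, and the default cohort."""
from __future__ import annotations

import warnings

import numpy as np
import pytest

from abruptcut.pipeline import PipelineConfig, extract_cohort_features
from abruptcut.synth import LesionSpec, generate_cohort, generate_lesion


def disk_mask(radius: float, size: int | None = None, center=None) -> np.ndarray:
    """Filled disk: pixels whose centers lie within *radius* of the center."""
    n = size if size is not None else 2 * int(radius) + 21
    yy, xx = np.mgrid[0:n, 0:n]
    cy, cx = center if center is not None else ((n - 1) / 2.0, (n - 1) / 2.0)
    return ((yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2).astype(np.uint8)


def star_mask(
    base_radius: float = 60.0,
    amplitude: float = 0.3,
    n_points: int = 6,
    size: int = 201,
) -> np.ndarray:
    """Star-shaped blob whose concavities have small curvature radius."""
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    d = np.hypot(yy - c, xx - c)
    theta = np.arctan2(yy - c, xx - c)
    rho = base_radius * (1.0 + amplitude * np.cos(n_points * theta))
    return (d <= rho).astype(np.uint8)


def random_blob(seed: int, size: int = 160, base_radius: float = 50.0) -> np.ndarray:
    """Random smooth star-convex blob mask (single component, hole-free)."""
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    d = np.hypot(yy - c, xx - c)
    theta = np.arctan2(yy - c, xx - c)
    k = np.arange(2, 8)
    amp = rng.uniform(0.3, 1.0, k.size)
    amp *= rng.uniform(0.05, 0.25) / amp.sum()
    phases = rng.uniform(0, 2 * np.pi, k.size)
    rho = base_radius * (
        1 + sum(a * np.cos(kk * theta + p) for a, kk, p in zip(amp, k, phases))
    )
    return (d <= rho).astype(np.uint8)


def brute_force_boundary(mask: np.ndarray) -> set[tuple[int, int]]:
    """Foreground pixels with at least one background 8-neighbor (oracle)."""
    arr = np.asarray(mask).astype(bool)
    h, w = arr.shape
    out = set()
    for r in range(h):
        for c in range(w):
            if not arr[r, c]:
                continue
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w) or not arr[rr, cc]:
                        out.add((r, c))
                        break
                else:
                    continue
                break
    return out


@pytest.fixture(scope="session")
def default_cohort():
    """The default 100 benign / 100 malignant synthetic cohort."""
    return generate_cohort(100, 100, seed=11)


@pytest.fixture(scope="session")
def cohort_features_r10_rgb(default_cohort):
    """Radius-10 RGB feature table for the default cohort (shared: expensive)."""
    cfg = PipelineConfig(radii=(10.0,), color_spaces=("RGB",))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return extract_cohort_features(default_cohort, cfg)


@pytest.fixture()
def sample_lesion():
    """One deterministic abrupt lesion (image, mask, label)."""
    spec = LesionSpec(seed=3, edge_profile="abrupt")
    return generate_lesion(spec)
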