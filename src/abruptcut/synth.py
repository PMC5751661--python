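"""Synthetic dermoscopy lesions with controllable border abruptness.

Each lesion is a star-convex blob whose radius is a random low-order
Fourier perturbation of a base radius,

    rho(theta) = R * (1 + sum_k a_k cos(k*theta + phi_k)),

filled with correlated brown pigment texture on a lighter skin background.
The border transition is either *abrupt* (the pigment pattern terminates
within about one pixel — the malignancy cue) or *gradual* (an erf-shaped
Gaussian-profile fade over ``edge_width`` pixels — the benign pattern).
Gaussian pixel noise is added last.  The class signal is carried only by
the edge profile; interior texture statistics are drawn identically for
both classes, so downstream classifier performance validates specifically
the peripheral features.

The binary mask is exactly the nominal lesion support {rho-interior};
star-convexity guarantees a single, hole-free component.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import erfc

__all__ = [
    "LesionSpec",
    "SyntheticCohort",
    "generate_lesion",
    "generate_cohort",
    "write_cohort",
    "MAX_FEATURE_RADIUS",
]

#: largest patch radius the feature stage supports; lesions must admit a
#: contraction of 4x this depth.
MAX_FEATURE_RADIUS = 15.0

# Pigment palette (RGB, 0-255): melanin-brown lesion on light skin.
PIGMENT_BASE = np.array([128.0, 84.0, 60.0])
PIGMENT_RANGE = np.array([38.0, 28.0, 20.0])
SKIN_RGB = np.array([206.0, 176.0, 156.0])
GLOBULE_RGB = np.array([82.0, 50.0, 36.0])


@dataclass(frozen=True)
class LesionSpec:
    """Generator parameters for one lesion.

    ``irregularity`` is the total amplitude of the radial Fourier
    perturbation as a fraction of ``base_radius`` (0..0.4);
    ``edge_profile`` determines the label (abrupt -> malignant-like,
    gradual -> benign-like).  ``edge_width`` is the fade length in pixels of
    gradual border segments; the fade ends (pigment reaches skin) at the
    mask border, so it occupies the lesion periphery itself.  For abrupt
    lesions, ``abrupt_fraction`` is the
    fraction of the border perimeter showing a sharp cutoff (a ramp of
    ``abrupt_width`` <= 1 px); the remaining arc fades gradually, mirroring
    the clinical picture where abrupt cutoff appears in a subset of border
    octants.  ``edge_jaggedness`` (px, sd) perturbs the cutoff line with
    high-frequency angular noise: a pigment pattern does not terminate on a
    smooth analytic curve but on a ragged one, which is what makes a sharp
    cutoff visible to co-occurrence statistics in every offset direction.
    ``noise_sd`` is the Gaussian pixel-noise standard deviation in 0-255
    intensity units.

    ``globule_density`` is the expected number of small dark peripheral
    globules (radius drawn from ``globule_radius``), a focal dermoscopic
    structure present in benign and malignant lesions alike.  Globules are
    drawn identically for both classes: they are a nuisance that creates
    locally sharp spots without carrying class signal.

    ``edge_offset`` centers the pigment transition that many pixels inside
    the nominal mask border (identical for both classes).  A segmentation
    mask encloses the pigment pattern, so the transition belongs to the
    peripheral layer; without the offset an abrupt cutoff would coincide
    with the mask boundary and be invisible to annulus-clipped patches.
    """

    image_size: tuple[int, int] = (256, 256)
    base_radius: float = 85.0
    irregularity: float = 0.15
    n_harmonics: int = 6
    edge_profile: str = "abrupt"
    edge_width: float = 20.0
    abrupt_fraction: float = 1.0
    abrupt_width: float = 0.5
    edge_jaggedness: float = 1.5
    edge_offset: float = 2.0
    globule_density: float = 3.0
    globule_radius: tuple[float, float] = (2.0, 4.0)
    interior_texture_scale: float = 3.0
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.edge_profile not in ("abrupt", "gradual"):
            raise ValueError("edge_profile must be 'abrupt' or 'gradual'")
        if not 0.0 <= self.irregularity <= 0.4:
            raise ValueError("irregularity must lie in [0, 0.4]")
        if self.edge_width < 0:
            raise ValueError("edge_width must be >= 0")
        if not 0.0 <= self.abrupt_fraction <= 1.0:
            raise ValueError("abrupt_fraction must lie in [0, 1]")
        if self.abrupt_width > 1.0:
            raise ValueError("abrupt_width must be <= 1 px (sharp cutoff)")
        if self.base_radius * (1.0 - self.irregularity) <= 4.0 * MAX_FEATURE_RADIUS:
            raise ValueError(
                "infeasible spec: base_radius*(1-irregularity) must exceed "
                f"{4 * MAX_FEATURE_RADIUS} px so every feature radius is usable"
            )
        h, w = self.image_size
        if self.base_radius * (1.0 + self.irregularity) >= min(h, w) / 2.0 - 2:
            raise ValueError("lesion does not fit in the image with a margin")

    @property
    def label(self) -> str:
        return "malignant" if self.edge_profile == "abrupt" else "benign"


def generate_lesion(spec: LesionSpec) -> tuple[np.ndarray, np.ndarray, str]:
    """Render one lesion.

    Returns ``(rgb_image uint8, mask uint8 {0,1}, label)``; fully
    deterministic in ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    # Radial profile: harmonics k >= 2 (k = 1 merely shifts the centroid).
    k = np.arange(2, spec.n_harmonics + 2)
    amp = rng.uniform(0.5, 1.0, size=k.size)
    amp *= spec.irregularity / amp.sum() if amp.sum() > 0 else 0.0
    phases = rng.uniform(0.0, 2.0 * np.pi, size=k.size)
    theta0 = rng.uniform(0.0, 2.0 * np.pi)  # center of any abrupt arc

    yy, xx = np.mgrid[0:h, 0:w]
    d = np.hypot(yy - cy, xx - cx)
    theta = np.arctan2(yy - cy, xx - cx)
    rho = spec.base_radius * (
        1.0 + sum(a * np.cos(kk * theta + p) for a, kk, p in zip(amp, k, phases))
    )
    signed = d - rho  # negative inside the nominal border
    mask = (signed <= 0).astype(np.uint8)

    edge = signed + spec.edge_offset  # sharp cutoff sits just inside the border
    ew = max(spec.edge_width, 1e-3)
    # Gradual profile: the pigment fades over ~ew pixels and reaches skin at
    # the mask border (a segmentation boundary marks where pigment becomes
    # indistinguishable from skin), so the fade occupies the peripheral band.
    alpha_gradual = 0.5 * erfc((signed + spec.edge_offset + ew / 2.0) / (ew / 4.0))
    if spec.edge_profile == "abrupt" and spec.abrupt_fraction > 0:
        # Ragged cutoff line: smooth periodic angular noise, ~2 degree
        # correlation scale, sd = edge_jaggedness pixels.
        base_jag = rng.standard_normal(360)
        base_jag = gaussian_filter(base_jag, 2.0, mode="wrap")
        sd_j = base_jag.std()
        if sd_j > 0:
            base_jag *= spec.edge_jaggedness / sd_j
        jag = np.interp(
            np.degrees(theta) % 360.0, np.arange(361.0),
            np.append(base_jag, base_jag[0]),
        )
        aw = max(spec.abrupt_width, 1e-3)
        alpha_sharp = np.clip(0.5 - (edge + jag) / aw, 0.0, 1.0)  # step-like ramp
        if spec.abrupt_fraction >= 1.0:
            alpha = alpha_sharp
        else:
            # Angular window: the cutoff occupies a contiguous arc covering
            # abrupt_fraction of the perimeter, with ~0.2 rad soft shoulders.
            half = np.pi * spec.abrupt_fraction
            ang = np.angle(np.exp(1j * (theta - theta0)))  # wrapped to (-pi, pi]
            window = np.clip((half - np.abs(ang)) / 0.2 + 0.5, 0.0, 1.0)
            alpha = window * alpha_sharp + (1.0 - window) * alpha_gradual
    else:
        alpha = alpha_gradual

    texture = gaussian_filter(rng.standard_normal((h, w)), spec.interior_texture_scale)
    sd = texture.std()
    if sd > 0:
        texture /= sd
    pigment = PIGMENT_BASE[None, None, :] + PIGMENT_RANGE[None, None, :] * texture[:, :, None]
    img = alpha[:, :, None] * pigment + (1.0 - alpha[:, :, None]) * SKIN_RGB[None, None, :]

    # Peripheral globules: small dark clods in the border zone, same
    # distribution for both classes.
    n_glob = rng.poisson(spec.globule_density)
    r_lo, r_hi = spec.globule_radius
    for _ in range(n_glob):
        gt = rng.uniform(0.0, 2.0 * np.pi)
        depth = rng.uniform(3.0, 22.0)
        g_rad = rng.uniform(r_lo, r_hi)
        rho_g = spec.base_radius * (
            1.0 + sum(a * np.cos(kk * gt + p) for a, kk, p in zip(amp, k, phases))
        )
        gy = cy + (rho_g - depth) * np.sin(gt)
        gx = cx + (rho_g - depth) * np.cos(gt)
        g_dist = np.hypot(yy - gy, xx - gx)
        g_alpha = np.clip(g_rad - g_dist + 0.5, 0.0, 1.0) * 0.85
        img = (1.0 - g_alpha[:, :, None]) * img + g_alpha[:, :, None] * GLOBULE_RGB[None, None, :]

    img += rng.normal(0.0, spec.noise_sd, size=(h, w, 3))
    img = np.clip(img, 0.0, 255.0).astype(np.uint8)
    return img, mask, spec.label


@dataclass
class SyntheticCohort:
    """Generated lesions with their masks, labels and specs."""

    ids: list[str]
    images: list[np.ndarray] = field(repr=False)
    masks: list[np.ndarray] = field(repr=False)
    labels: list[str]
    specs: list[LesionSpec]

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels:
            out[lab] = out.get(lab, 0) + 1
        return out


def _jittered_spec(
    rng: np.random.Generator, base: LesionSpec, profile: str, seed: int
) -> LesionSpec:
    # Per-lesion heterogeneity: size, shape irregularity, texture grain and
    # noise vary across the cohort; only the edge profile separates classes.
    if profile == "abrupt":
        # The cutoff arc varies from a sub-octant segment (easily missed,
        # even clinically) up to most of the perimeter.
        abrupt_fraction = rng.uniform(0.08, 0.9)
        edge_width = rng.uniform(12.0, 28.0)  # fade of the non-abrupt arc
    else:
        abrupt_fraction = 0.0
        edge_width = rng.uniform(8.0, 28.0)
    return replace(
        base,
        base_radius=rng.uniform(78.0, 95.0),
        irregularity=rng.uniform(0.08, 0.2),
        interior_texture_scale=rng.uniform(2.5, 3.5),
        noise_sd=rng.uniform(3.0, 5.0),
        edge_profile=profile,
        edge_width=float(edge_width),
        abrupt_fraction=float(abrupt_fraction),
        seed=int(seed),
    )


def generate_cohort(
    n_benign: int,
    n_malignant: int,
    base_spec: LesionSpec | None = None,
    seed: int = 0,
    jitter: bool = True,
    label_noise: float = 0.05,
) -> SyntheticCohort:
    """Generate a labeled cohort with per-lesion seeds from a master seed.

    ``label_noise`` is the probability that a lesion's recorded diagnosis is
    flipped, emulating the inter-observer disagreement on borderline
    melanocytic lesions that real cohort labels carry.  The generated border
    morphology is untouched — ``specs[i].edge_profile`` remains the ground
    truth; only the ``labels`` entry (what a classifier trains on) flips.
    Class counts refer to the generated morphologies.
    """
    if n_benign < 1 or n_malignant < 1:
        raise ValueError("both class counts must be >= 1")
    if not 0.0 <= label_noise < 0.5:
        raise ValueError("label_noise must lie in [0, 0.5)")
    base = base_spec if base_spec is not None else LesionSpec()
    rng = np.random.default_rng(seed)
    ids, images, masks, labels, specs = [], [], [], [], []
    plan = [("gradual", i) for i in range(n_benign)] + [
        ("abrupt", i) for i in range(n_malignant)
    ]
    for profile, i in plan:
        lesion_seed = int(rng.integers(0, 2**31))
        if jitter:
            spec = _jittered_spec(rng, base, profile, lesion_seed)
        else:
            spec = replace(base, edge_profile=profile, seed=lesion_seed)
        img, mask, label = generate_lesion(spec)
        if rng.random() < label_noise:
            label = "benign" if label == "malignant" else "malignant"
        prefix = "ben" if spec.label == "benign" else "mal"
        ids.append(f"{prefix}_{i:04d}")
        images.append(img)
        masks.append(mask)
        labels.append(label)
        specs.append(spec)
    return SyntheticCohort(ids=ids, images=images, masks=masks, labels=labels, specs=specs)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write ``images/*.png``, ``masks/*.png``, ``labels.csv``, ``specs.json``."""
    out = Path(outdir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for lid, img, mask in zip(cohort.ids, cohort.images, cohort.masks):
        iio.imwrite(out / "images" / f"{lid}.png", img)
        iio.imwrite(out / "masks" / f"{lid}.png", (mask * 255).astype(np.uint8))
    with open(out / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "label"])
        writer.writerows(zip(cohort.ids, cohort.labels))
    specs = [
        {**asdict(s), "image_size": list(s.image_size), "id": lid}
        for s, lid in zip(cohort.specs, cohort.ids)
    ]
    (out / "specs.json").write_text(json.dumps(specs, indent=2))
    return out
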