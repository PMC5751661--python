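"""End-to-end orchestration: mask -> chain code -> contraction -> features -> CV.

The feature table is long-format: one row per (image, radius, color_space)
with ``id``, ``label``, ``radius``, ``color_space`` columns followed by the
36 possible feature columns (R/G/B/H/S/V x six statistics); rows for a
single color space leave the unused channels empty.  Per-lesion failures
(over-contraction, annulus too thin for a radius) are logged and skipped so
cohort runs always complete; a manifest JSON records the configuration hash
and per-image status.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import LABELS, ClassifierConfig, EvalReport, cross_validate
from .io import read_image, read_mask
from .levelset import contract_border
from .synth import SyntheticCohort
from .texture import COLOR_SPACES, STAT_NAMES, GLCMParams, extract_features

__all__ = [
    "PipelineConfig",
    "FEATURE_COLUMNS",
    "feature_columns",
    "process_lesion",
    "run_extract",
    "extract_cohort_features",
    "run_evaluate",
]

logger = logging.getLogger("abruptcut")

#: all 36 possible feature columns, RGB channels first then HSV
FEATURE_COLUMNS = [f"{ch}_{s}" for ch in "RGBHSV" for s in STAT_NAMES]


def feature_columns(color_space: str) -> list[str]:
    return [f"{ch}_{s}" for ch in COLOR_SPACES[color_space] for s in STAT_NAMES]


@dataclass(frozen=True)
class PipelineConfig:
    """Workflow settings: radii, color spaces, GLCM, contraction, classifier."""

    radii: tuple[float, ...] = (5.0, 7.0, 10.0, 15.0)
    color_spaces: tuple[str, ...] = ("RGB", "HSV", "RGB+HSV")
    glcm_levels: int = 32
    glcm_offset: tuple[int, int] = (1, 0)
    contraction_method: str = "pde"
    dt: float = 0.5
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed: int = 0

    @property
    def glcm_params(self) -> GLCMParams:
        return GLCMParams(levels=self.glcm_levels, offset=self.glcm_offset)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        clf = ClassifierConfig(**raw.pop("classifier", {}))
        for key in ("radii", "color_spaces", "glcm_offset"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(classifier=clf, **raw)


def process_lesion(
    image: np.ndarray,
    mask: np.ndarray,
    config: PipelineConfig,
    label: str = "unknown",
) -> list[dict]:
    """Feature rows for one lesion across all configured radii/color spaces.

    A radius that is infeasible for this lesion contributes no rows; the
    reason is logged by the caller via the raised exception.
    """
    rows: list[dict] = []
    for radius in config.radii:
        result = contract_border(
            mask, 2.0 * radius, dt=config.dt, method=config.contraction_method
        )
        for cs in config.color_spaces:
            fv = extract_features(
                image, result, radius, cs, params=config.glcm_params, label=label
            )
            row = {"radius": radius, "color_space": cs, "label": label}
            row.update(fv.as_dict())
            rows.append(row)
    return rows


def run_extract(
    images_dir: str | Path,
    masks_dir: str | Path,
    config: PipelineConfig,
    out_csv: str | Path | None = None,
    labels_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Extract the feature table for every image/mask pair in two directories."""
    images_dir, masks_dir = Path(images_dir), Path(masks_dir)
    image_paths = sorted(images_dir.glob("*.png")) + sorted(images_dir.glob("*.jpg"))
    if not image_paths:
        raise FileNotFoundError(f"no images found in {images_dir}")
    labels: dict[str, str] = {}
    if labels_csv is not None:
        lab = pd.read_csv(labels_csv, dtype=str)
        labels = dict(zip(lab["id"], lab["label"]))
    all_rows: list[dict] = []
    status: dict[str, str] = {}
    for ipath in image_paths:
        lid = ipath.stem
        mpath = masks_dir / f"{lid}.png"
        if not mpath.exists():
            status[lid] = "skipped: no mask"
            logger.warning("no mask for %s", lid)
            continue
        image = read_image(ipath)
        mask = read_mask(mpath)
        label = labels.get(lid, "unknown")
        done = 0
        for radius in config.radii:
            try:
                result = contract_border(
                    mask, 2.0 * radius, dt=config.dt, method=config.contraction_method
                )
                for cs in config.color_spaces:
                    fv = extract_features(
                        image, result, radius, cs, params=config.glcm_params, label=label
                    )
                    row = {
                        "id": lid,
                        "label": label,
                        "radius": radius,
                        "color_space": cs,
                    }
                    row.update(fv.as_dict())
                    all_rows.append(row)
                done += 1
            except Exception as exc:  # per-lesion failures are not fatal
                logger.warning("%s @ r=%s skipped: %s", lid, radius, exc)
                status[lid] = f"partial: r={radius} skipped ({exc})"
        if lid not in status:
            status[lid] = "ok"
        elif done:
            pass  # partial status already recorded
    df = pd.DataFrame(all_rows, columns=["id", "label", "radius", "color_space"] + FEATURE_COLUMNS)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
        manifest = {
            "config_hash": PipelineConfig.config_hash(config),
            "config": config.to_dict(),
            "n_rows": len(df),
            "status": status,
        }
        Path(str(out_csv) + ".manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str)
        )
    return df


def extract_cohort_features(
    cohort: SyntheticCohort, config: PipelineConfig
) -> pd.DataFrame:
    """In-memory feature extraction for a synthetic cohort."""
    rows: list[dict] = []
    for lid, image, mask, label in zip(
        cohort.ids, cohort.images, cohort.masks, cohort.labels
    ):
        for radius in config.radii:
            try:
                result = contract_border(
                    mask, 2.0 * radius, dt=config.dt, method=config.contraction_method
                )
            except Exception as exc:
                logger.warning("%s @ r=%s skipped: %s", lid, radius, exc)
                continue
            for cs in config.color_spaces:
                fv = extract_features(
                    image, result, radius, cs, params=config.glcm_params, label=label
                )
                row = {"id": lid, "label": label, "radius": radius, "color_space": cs}
                row.update(fv.as_dict())
                rows.append(row)
    return pd.DataFrame(
        rows, columns=["id", "label", "radius", "color_space"] + FEATURE_COLUMNS
    )


def run_evaluate(
    features: pd.DataFrame | str | Path,
    config: PipelineConfig,
    classifiers: tuple[str, ...] = ("mlp_single", "mlp_multi", "svm"),
    labels_csv: str | Path | None = None,
) -> tuple[dict[str, EvalReport], pd.DataFrame]:
    """Cross-validate every (radius, color_space, classifier) combination.

    Returns the per-combination reports keyed ``r{radius}_{cs}_{clf}`` and a
    ranking table sorted by mean F1 (the best combination first).
    """
    df = (
        features
        if isinstance(features, pd.DataFrame)
        else pd.read_csv(features)
    )
    if labels_csv is not None:
        lab = pd.read_csv(labels_csv, dtype=str)
        df = df.drop(columns=["label"], errors="ignore").merge(lab, on="id", how="inner")
    if df.empty:
        raise ValueError("no feature rows to evaluate")
    unknown = set(df["label"]) - set(LABELS)
    if unknown:
        raise ValueError(f"unmapped labels: {sorted(unknown)}")
    reports: dict[str, EvalReport] = {}
    rank_rows: list[dict] = []
    for (radius, cs), grp in df.groupby(["radius", "color_space"], sort=True):
        cols = feature_columns(cs)
        X = grp[cols].to_numpy(dtype=float)
        y = grp["label"].map(LABELS).to_numpy()
        for kind in classifiers:
            cfg = dataclasses.replace(
                config.classifier, kind=kind, seed=config.seed
            )
            report = cross_validate(X, y, cfg)
            key = f"r{radius:g}_{cs}_{kind}"
            reports[key] = report
            rank_rows.append(
                {
                    "radius": radius,
                    "color_space": cs,
                    "classifier": kind,
                    **{m: getattr(report, m) for m in EvalReport.METRICS},
                }
            )
    ranking = pd.DataFrame(rank_rows).sort_values("f1", ascending=False).reset_index(
        drop=True
    )
    return reports, ranking
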