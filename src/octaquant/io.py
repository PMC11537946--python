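"""Manifest schema, run configuration and image readers/writers.

The manifest is a flat table — one row per (subject, arm) image — stored as
CSV or JSON with columns ``subject_id, group, fov, arm, path, seed``.
Validation collects *all* violations before raising, so a malformed manifest
reports every problem at once.

:class:`RunConfig` gathers every tunable of the pipeline in one serializable
object; its SHA-256 hash is embedded in every output file so a report can be
regenerated bit-identically from its recorded config + seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .types import VALID_ARMS, VALID_FOVS, ProjectionMap

__all__ = ["ManifestError", "RunConfig", "read_manifest", "read_image", "write_image"]

MANIFEST_COLUMNS = ["subject_id", "group", "fov", "arm", "path", "seed"]


class ManifestError(ValueError):
    """Raised with the full list of manifest validation violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid manifest:\n  - " + "\n  - ".join(violations))


@dataclass
class RunConfig:
    """All pipeline tunables in one place; hashable for provenance."""

    binarization: str = "otsu"
    binarization_threshold: float = 128.0
    adaptive_window: int = 31
    prune_len_px: float = 3.0
    bvt_min_chord_px: float = 1.0
    ssim_window: int = 11
    pcqi_window: int = 11
    pcqi_stride: int = 4
    extractor: str = "radial_profile_stats"
    ttest_paired: bool = False
    master_seed: int = 0
    report_scale: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)


def read_manifest(path: str | Path, check_paths: bool = True) -> pd.DataFrame:
    """Load and validate a cohort manifest from CSV or JSON.

    Checks: required columns, known fov/arm labels, uniqueness of
    (subject_id, arm), presence of a GT row for every subject, and (by
    default) that every image path exists.  All violations are reported in
    a single :class:`ManifestError`.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path, comment="#")

    violations: list[str] = []
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError([f"missing columns: {missing}"])

    bad_fov = sorted(set(df["fov"]) - set(VALID_FOVS))
    if bad_fov:
        violations.append(f"unknown fov labels: {bad_fov}")
    bad_arm = sorted(set(df["arm"]) - set(VALID_ARMS))
    if bad_arm:
        violations.append(f"unknown arm labels: {bad_arm}")

    dupes = df[df.duplicated(subset=["subject_id", "arm"], keep=False)]
    for key in sorted(set(zip(dupes["subject_id"], dupes["arm"]))):
        violations.append(f"duplicate (subject_id, arm): {key}")

    by_subject = df.groupby("subject_id")["arm"].apply(set)
    for subject_id, arms in by_subject.items():
        if "GT" not in arms:
            violations.append(f"subject {subject_id!r} has no GT row")

    if check_paths:
        for p in df["path"]:
            if not Path(p).exists():
                violations.append(f"image path does not exist: {p}")

    if violations:
        raise ManifestError(violations)
    return df.reset_index(drop=True)


def read_image(path: str | Path, fov: str = "3mm", subject_id: str = "",
               group: str = "", arm: str = "GT") -> ProjectionMap:
    """Read a grayscale PNG/TIFF into a :class:`ProjectionMap`."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:  # collapse accidental RGB to luminance
        img = img[..., :3].mean(axis=-1)
    return ProjectionMap(pixels=img, fov=fov, subject_id=subject_id, group=group, arm=arm)


def write_image(path: str | Path, pmap: ProjectionMap) -> None:
    """Write a projection map as 8-bit grayscale PNG/TIFF."""
    px = np.asarray(pmap.pixels)
    if px.dtype != np.uint8 and px.dtype != np.uint16:
        px = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), px)
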