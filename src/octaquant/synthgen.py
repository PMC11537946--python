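"""Seeded synthetic paired (GT, TR) OCTA-like projection maps.

The generator emulates the structure of a paired translation study — a
ground-truth arm of en-face vascular projection maps and a "translated" arm
produced by a parametric degradation model — so that every downstream stage
(morphometry, quality metrics, cohort statistics) is testable without any
clinical data.

Vascular geometry comes from a stochastic branching random walk: each root
vessel performs a unit-step walk whose heading diffuses with standard
deviation ``tortuosity_amp`` per step, bifurcating with probability
``branch_prob`` per step into two symmetric children of reduced caliber.
The walk's exact centerline polylines and per-branch radii are returned as a
geometry record, which serves as the ground-truth oracle for morphometry
tests.

The degradation model stands in for translation artifacts: Gaussian blur,
dropout of small-caliber branches, multiplicative caliber jitter, contrast
drift and additive noise.  An all-identity degradation returns the GT image
bit-for-bit.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .types import VALID_FOVS, ProjectionMap

__all__ = [
    "VascularNetworkSpec",
    "DegradationSpec",
    "BranchGeometry",
    "GeometryRecord",
    "GroupSpec",
    "CohortSpec",
    "generate_network",
    "degrade",
    "synthesize_subject",
    "make_cohort",
    "subject_seed",
]

_MAX_BRANCHES = 4096
_MAX_DEPTH = 12
_MIN_RADIUS_PX = 0.4
_SPLIT_ANGLE = np.pi / 7  # half-angle of symmetric bifurcation


@dataclass(frozen=True)
class VascularNetworkSpec:
    """Knobs of the branching random-walk vasculature model.

    Defaults are sized for a 256 px en-face map of a healthy macular scan:
    a handful of root vessels, mild heading diffusion, ~2 px root radius.
    """

    image_size: int = 256
    n_seeds: int = 8
    branch_prob: float = 0.04
    tortuosity_amp: float = 0.15
    caliber_root_px: float = 2.2
    caliber_decay: float = 0.8
    min_branch_len_px: float = 12.0
    fov_label: str = "3mm"
    rng_seed: int = 0

    def validate(self) -> None:
        if self.image_size < 16:
            raise ValueError(f"image_size must be >= 16, got {self.image_size}")
        if self.n_seeds < 0:
            raise ValueError(f"n_seeds must be >= 0, got {self.n_seeds}")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError(f"branch_prob must be in [0, 1], got {self.branch_prob}")
        if self.tortuosity_amp < 0:
            raise ValueError(f"tortuosity_amp must be >= 0, got {self.tortuosity_amp}")
        if self.caliber_root_px <= 0:
            raise ValueError(f"caliber_root_px must be > 0, got {self.caliber_root_px}")
        if not 0.0 < self.caliber_decay <= 1.0:
            raise ValueError(f"caliber_decay must be in (0, 1], got {self.caliber_decay}")
        if self.min_branch_len_px <= 0:
            raise ValueError(f"min_branch_len_px must be > 0, got {self.min_branch_len_px}")
        if self.fov_label not in VALID_FOVS:
            raise ValueError(f"fov_label must be one of {VALID_FOVS}, got {self.fov_label!r}")


@dataclass(frozen=True)
class DegradationSpec:
    """Parametric translation-artifact model applied to a GT map.

    All-zero severities (and unit gains) leave the image untouched.
    ``caliber_scale`` is a systematic multiplicative bias on branch radii
    (``< 1`` thins vessels), on top of the zero-mean ``caliber_jitter``.
    Intensities are treated on a 0–255 scale, so ``noise_sd`` is in 8-bit
    intensity units.
    """

    blur_sigma_px: float = 0.0
    dropout_frac: float = 0.0
    caliber_jitter: float = 0.0
    caliber_scale: float = 1.0
    contrast_gain: float = 1.0
    noise_sd: float = 0.0
    small_caliber_cutoff_px: float = 1.5
    rng_seed: int = 0

    def validate(self) -> None:
        if self.blur_sigma_px < 0:
            raise ValueError(f"blur_sigma_px must be >= 0, got {self.blur_sigma_px}")
        if not 0.0 <= self.dropout_frac <= 1.0:
            raise ValueError(f"dropout_frac must be in [0, 1], got {self.dropout_frac}")
        if self.caliber_jitter < 0:
            raise ValueError(f"caliber_jitter must be >= 0, got {self.caliber_jitter}")
        if self.caliber_scale <= 0:
            raise ValueError(f"caliber_scale must be > 0, got {self.caliber_scale}")
        if self.contrast_gain <= 0:
            raise ValueError(f"contrast_gain must be > 0, got {self.contrast_gain}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")

    @property
    def is_identity(self) -> bool:
        return (
            self.blur_sigma_px == 0
            and self.dropout_frac == 0
            and self.caliber_jitter == 0
            and self.caliber_scale == 1.0
            and self.contrast_gain == 1.0
            and self.noise_sd == 0
        )


@dataclass
class BranchGeometry:
    """Exact centerline polyline and radius of one generated branch."""

    points: np.ndarray  # (n, 2) float array of (row, col)
    radius_px: float

    @property
    def arc_length_px(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def chord_length_px(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(self.points[-1] - self.points[0]))


@dataclass
class GeometryRecord:
    """Ground-truth geometry of a generated network (the morphometry oracle)."""

    branches: list[BranchGeometry] = field(default_factory=list)
    image_size: int = 256

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def tortuosity_oracle(self) -> float:
        """Mean arc/chord ratio over branches with a non-degenerate chord."""
        ratios = [
            b.arc_length_px / b.chord_length_px
            for b in self.branches
            if b.chord_length_px >= 1.0
        ]
        return float(np.mean(ratios)) if ratios else float("nan")

    def rasterize_mask(self) -> np.ndarray:
        """Exact binary rasterization: a disc of the branch radius per step."""
        return _rasterize(self.branches, self.image_size)


def _disk_offsets(radius: float, _cache: dict = {}) -> np.ndarray:
    r = round(float(radius), 3)
    if r not in _cache:
        ri = max(int(np.floor(r)), 0)
        dy, dx = np.mgrid[-ri : ri + 1, -ri : ri + 1]
        keep = dy * dy + dx * dx <= r * r
        _cache[r] = np.stack([dy[keep], dx[keep]], axis=1)
    return _cache[r]


def _rasterize(branches: list[BranchGeometry], size: int) -> np.ndarray:
    mask = np.zeros((size, size), dtype=bool)
    for br in branches:
        if len(br.points) == 0:
            continue
        pts = np.rint(br.points).astype(int)
        pts = np.unique(pts, axis=0)
        coords = pts[:, None, :] + _disk_offsets(br.radius_px)[None, :, :]
        coords = coords.reshape(-1, 2)
        ok = (
            (coords[:, 0] >= 0)
            & (coords[:, 0] < size)
            & (coords[:, 1] >= 0)
            & (coords[:, 1] < size)
        )
        mask[coords[ok, 0], coords[ok, 1]] = True
    return mask


def _render_grayscale(mask: np.ndarray, profile_sigma: float = 0.6) -> np.ndarray:
    """8-bit grayscale arm: binary rasterization with a thin Gaussian profile."""
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.uint8)
    g = gaussian_filter(mask.astype(float), profile_sigma)
    g = g / g.max()
    return np.rint(255.0 * g).astype(np.uint8)


def _grow(spec: VascularNetworkSpec, rng: np.random.Generator) -> list[BranchGeometry]:
    size = spec.image_size
    queue: list[tuple[np.ndarray, float, float, int]] = []
    for _ in range(spec.n_seeds):
        pos = rng.uniform(0.1 * size, 0.9 * size, size=2)
        heading = rng.uniform(0.0, 2.0 * np.pi)
        queue.append((pos, heading, spec.caliber_root_px, 0))

    branches: list[BranchGeometry] = []
    max_steps = 3 * size
    while queue and len(branches) < _MAX_BRANCHES:
        pos, heading, radius, depth = queue.pop(0)
        pts = [pos.copy()]
        n_steps = 0
        while True:
            heading = heading + rng.normal(0.0, spec.tortuosity_amp)
            pos = pos + np.array([np.sin(heading), np.cos(heading)])
            n_steps += 1
            if not (1.0 <= pos[0] < size - 1 and 1.0 <= pos[1] < size - 1):
                break  # left the frame: branch ends, no children
            pts.append(pos.copy())
            bifurcate = rng.random() < spec.branch_prob
            if bifurcate and n_steps >= spec.min_branch_len_px:
                child_r = radius * spec.caliber_decay
                if child_r >= _MIN_RADIUS_PX and depth < _MAX_DEPTH:
                    queue.append((pos.copy(), heading + _SPLIT_ANGLE, child_r, depth + 1))
                    queue.append((pos.copy(), heading - _SPLIT_ANGLE, child_r, depth + 1))
                break
            if n_steps >= max_steps:
                break
        if len(pts) >= 2:
            branches.append(BranchGeometry(np.array(pts), radius))
    return branches


def generate_network(spec: VascularNetworkSpec) -> tuple[ProjectionMap, GeometryRecord]:
    """Grow and rasterize one synthetic vascular network.

    Returns the grayscale projection map (vessels bright on dark) and the
    exact geometry used to rasterize it.  Identical spec (including
    ``rng_seed``) gives bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    branches = _grow(spec, rng)
    geometry = GeometryRecord(branches=branches, image_size=spec.image_size)
    img = _render_grayscale(geometry.rasterize_mask())
    pmap = ProjectionMap(pixels=img, fov=spec.fov_label, arm="GT")
    return pmap, geometry


def degrade(
    gt: ProjectionMap,
    d: DegradationSpec,
    geometry: GeometryRecord | None = None,
) -> ProjectionMap:
    """Apply the translation-artifact model to a GT map, yielding the TR arm.

    Branch dropout and caliber perturbations re-rasterize from the geometry
    record and therefore require it; the purely photometric stages (blur,
    contrast gain, additive noise) act on the pixels directly.  An identity
    spec returns a pixel-identical copy.
    """
    d.validate()
    if d.is_identity:
        return replace(gt, pixels=gt.pixels.copy(), arm="TR")

    rng = np.random.default_rng(d.rng_seed)
    needs_geometry = d.dropout_frac > 0 or d.caliber_jitter > 0 or d.caliber_scale != 1.0
    if needs_geometry:
        if geometry is None:
            raise ValueError(
                "dropout_frac/caliber_jitter/caliber_scale require the geometry record"
            )
        branches = [BranchGeometry(b.points.copy(), b.radius_px) for b in geometry.branches]
        small = [i for i, b in enumerate(branches) if b.radius_px <= d.small_caliber_cutoff_px]
        n_drop = int(round(d.dropout_frac * len(small)))
        dropped = set(rng.choice(small, size=n_drop, replace=False)) if n_drop else set()
        kept = []
        for i, b in enumerate(branches):
            if i in dropped:
                continue
            factor = d.caliber_scale * max(0.2, 1.0 + rng.normal(0.0, d.caliber_jitter))
            kept.append(BranchGeometry(b.points, b.radius_px * factor))
        base = _render_grayscale(_rasterize(kept, geometry.image_size)).astype(float)
    else:
        base = gt.pixels.astype(float)

    if d.blur_sigma_px > 0:
        base = gaussian_filter(base, d.blur_sigma_px)
    base = base * d.contrast_gain
    if d.noise_sd > 0:
        base = base + rng.normal(0.0, d.noise_sd, size=base.shape)
    out = np.clip(np.rint(base), 0, 255).astype(np.uint8)
    return replace(gt, pixels=out, arm="TR")


def subject_seed(master_seed: int, subject_id: str, salt: str = "") -> int:
    """Stable per-subject seed derived from a master seed by hashing the id."""
    return zlib.crc32(f"{master_seed}:{subject_id}:{salt}".encode()) & 0x7FFFFFFF


@dataclass
class GroupSpec:
    """Per-group cohort entry: size plus network/degradation overrides."""

    n: int
    network: dict = field(default_factory=dict)
    degradation: dict = field(default_factory=dict)


@dataclass
class CohortSpec:
    """Declarative description of a paired synthetic cohort.

    ``network``/``degradation`` are cohort-wide field overrides; each
    group may override further.  Group sizes may be unbalanced, mirroring
    real disease cohorts.
    """

    groups: dict[str, GroupSpec]
    master_seed: int = 0
    fov: str = "3mm"
    image_size: int = 256
    network: dict = field(default_factory=dict)
    degradation: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: dict) -> "CohortSpec":
        groups = {}
        for name, g in cfg["groups"].items():
            if isinstance(g, int):
                groups[name] = GroupSpec(n=g)
            else:
                groups[name] = GroupSpec(
                    n=g["n"],
                    network=dict(g.get("network", {})),
                    degradation=dict(g.get("degradation", {})),
                )
        return cls(
            groups=groups,
            master_seed=int(cfg.get("master_seed", 0)),
            fov=cfg.get("fov", "3mm"),
            image_size=int(cfg.get("image_size", 256)),
            network=dict(cfg.get("network", {})),
            degradation=dict(cfg.get("degradation", {})),
        )


def synthesize_subject(
    net_spec: VascularNetworkSpec, deg_spec: DegradationSpec
) -> tuple[ProjectionMap, ProjectionMap, GeometryRecord]:
    """Generate one paired (GT, TR) subject plus its geometry record."""
    gt, geometry = generate_network(net_spec)
    tr = degrade(gt, deg_spec, geometry=geometry)
    return gt, tr, geometry


def make_cohort(spec: CohortSpec, out_dir: str | Path, fmt: str = "png") -> pd.DataFrame:
    """Write a paired synthetic cohort to disk and return its manifest.

    One GT and one TR image per subject; manifest columns are
    ``subject_id, group, fov, arm, path, seed``, written both as
    ``manifest.csv`` and ``manifest.json``.  Identical spec (including
    ``master_seed``) reproduces identical files.
    """
    if fmt not in ("png", "tiff"):
        raise ValueError(f"fmt must be 'png' or 'tiff', got {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for group, gspec in spec.groups.items():
        if gspec.n < 1:
            raise ValueError(f"group {group!r} must have n >= 1, got {gspec.n}")
        for i in range(gspec.n):
            subject_id = f"{group}_{i:03d}"
            seed = subject_seed(spec.master_seed, subject_id)
            net_kwargs = {
                "image_size": spec.image_size,
                "fov_label": spec.fov,
                **spec.network,
                **gspec.network,
                "rng_seed": seed,
            }
            deg_kwargs = {
                **spec.degradation,
                **gspec.degradation,
                "rng_seed": subject_seed(spec.master_seed, subject_id, salt="tr"),
            }
            gt, tr, _ = synthesize_subject(
                VascularNetworkSpec(**net_kwargs), DegradationSpec(**deg_kwargs)
            )
            for arm, pmap in (("GT", gt), ("TR", tr)):
                path = out_dir / f"{subject_id}_{arm}.{fmt}"
                if path.exists():
                    raise FileExistsError(f"output path collision: {path}")
                iio.imwrite(path, pmap.pixels)
                rows.append(
                    {
                        "subject_id": subject_id,
                        "group": group,
                        "fov": spec.fov,
                        "arm": arm,
                        "path": str(path),
                        "seed": seed,
                    }
                )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(rows, indent=2))
    return manifest
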