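"""Core domain containers shared across the pipeline.

A :class:`ProjectionMap` is one 2D grayscale en-face OCTA projection map with
its cohort metadata (field of view, subject, group, arm).  Morphometry
produces a :class:`VesselMask` (binary vasculature), a :class:`VesselSkeleton`
(1-px centerline decomposed into branches) and finally a
:class:`FeatureVector` holding the four vascular features.  Quality metrics
for one TR/GT pairing live in :class:`QualityScores`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProjectionMap",
    "VesselMask",
    "Branch",
    "VesselSkeleton",
    "FeatureVector",
    "QualityScores",
]

VALID_FOVS = ("3mm", "6mm")
VALID_ARMS = ("GT", "TR")


@dataclass
class ProjectionMap:
    """One grayscale en-face OCTA projection map plus cohort metadata.

    Parameters
    ----------
    pixels
        2D array of non-negative finite intensities (uint8 by convention;
        floats accepted).  Vessels are bright on a dark background.
    fov
        Field of view label, ``"3mm"`` or ``"6mm"``.  A 6 mm scan covers
        twice the physical width with the same pixel grid, i.e. half the
        px/mm sampling density.
    """

    pixels: np.ndarray
    fov: str = "3mm"
    subject_id: str = ""
    group: str = ""
    arm: str = "GT"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got ndim={self.pixels.ndim}")
        h, w = self.pixels.shape
        if h < 16 or w < 16:
            raise ValueError(f"projection map must be at least 16x16, got {h}x{w}")
        px = self.pixels.astype(float, copy=False)
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels must be finite")
        if px.min() < 0:
            raise ValueError("pixels must be non-negative")
        if self.fov not in VALID_FOVS:
            raise ValueError(f"fov must be one of {VALID_FOVS}, got {self.fov!r}")
        if self.arm not in VALID_ARMS:
            raise ValueError(f"arm must be one of {VALID_ARMS}, got {self.arm!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class VesselMask:
    """Binary vasculature mask with provenance of the binarization step."""

    mask: np.ndarray
    source: str = "unknown"
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def vascular_area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class Branch:
    """One centerline branch: an ordered pixel path between two nodes.

    Geodesic length sums per-step weights (1 for 4-neighbour moves, sqrt(2)
    for diagonal moves); Euclidean length is the straight-line distance
    between the two terminal pixels.  ``is_loop`` flags closed centerline
    loops, which have no meaningful endpoint chord.
    """

    path: np.ndarray  # (n, 2) int array of (row, col)
    is_loop: bool = False
    mean_radius_px: float | None = None

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=int)
        if self.path.ndim != 2 or self.path.shape[1] != 2:
            raise ValueError("branch path must be an (n, 2) array")

    @property
    def geodesic_len_px(self) -> float:
        if len(self.path) < 2:
            return 0.0
        steps = np.abs(np.diff(self.path, axis=0))
        return float(np.where(steps.sum(axis=1) == 2, np.sqrt(2.0), 1.0).sum())

    @property
    def euclid_len_px(self) -> float:
        if len(self.path) < 2 or self.is_loop:
            return 0.0
        return float(np.hypot(*(self.path[-1] - self.path[0]).astype(float)))


@dataclass
class VesselSkeleton:
    """1-px-wide centerline plus its branch decomposition.

    Junctions are connected clusters of skeleton pixels having three or more
    skeleton neighbours; endpoints have exactly one.  Branches run
    junction-to-junction or junction-to-endpoint.
    """

    skeleton: np.ndarray
    branches: list[Branch] = field(default_factory=list)
    junctions: list[tuple[int, int]] = field(default_factory=list)
    endpoints: list[tuple[int, int]] = field(default_factory=list)
    n_pruned: int = 0

    def __post_init__(self) -> None:
        self.skeleton = np.asarray(self.skeleton, dtype=bool)

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def total_length_px(self) -> float:
        return float(sum(b.geodesic_len_px for b in self.branches))


@dataclass
class FeatureVector:
    """The four vascular features of one map, plus raw intermediates.

    bvd is dimensionless in [0, 1]; bvc is in px (area per unit centerline
    length, an average caliber proxy); bvt is dimensionless and >= 1 for any
    skeleton with at least one retained branch; vpi is in 1/px (boundary
    length per unit vessel area).  Sentinel value for undefined features
    (e.g. empty mask) is NaN.
    """

    bvd: float
    bvc: float
    bvt: float
    vpi: float
    vessel_area_px: int = 0
    skeleton_len_px: float = 0.0
    perimeter_px: float = 0.0
    n_branches: int = 0
    n_loops_excluded: int = 0
    binarization: str = "unknown"

    def as_dict(self) -> dict[str, float]:
        return {
            "bvd": self.bvd,
            "bvc": self.bvc,
            "bvt": self.bvt,
            "vpi": self.vpi,
            "vessel_area_px": self.vessel_area_px,
            "skeleton_len_px": self.skeleton_len_px,
            "perimeter_px": self.perimeter_px,
            "n_branches": self.n_branches,
            "n_loops_excluded": self.n_loops_excluded,
            "binarization": self.binarization,
        }


@dataclass
class QualityScores:
    """Image-quality scores for one TR/GT pairing (or arm-pair of sets).

    ssim and pcqi are per-pair means over local windows/patches; fid is the
    set-level Fréchet distance between Gaussian fits to embedded image sets
    and is NaN on per-pair rows.
    """

    ssim: float
    pcqi: float
    fid: float = float("nan")
    metadata: dict = field(default_factory=dict)
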