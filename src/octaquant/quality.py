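"""Image-quality metrics comparing translated (TR) to ground-truth (GT) maps.

Three complementary views of translation fidelity:

* **SSIM** — mean local structural similarity over Gaussian-weighted sliding
  windows (luminance, contrast, structure terms); 1 for identical images.
* **PCQI** — patch-based contrast quality index: over local patches, the
  product of a patch-similarity term, a contrast-distortion term and a
  mean-luminance term, averaged; 1 for identical images (values above 1
  indicate contrast amplification).
* **Fréchet distance** — the Wasserstein-2 distance between Gaussian fits to
  embedded image *sets* (the FID construction), computed once per arm-pair
  rather than per pair.  The default embedding is a deterministic,
  download-free image descriptor (histogram, gradient and radial spectral
  statistics) so set-level distances are computable fully offline; a
  pretrained Inception pool3 embedding is the conventional choice when
  network weights are available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import linalg
from skimage.metrics import structural_similarity

from .types import ProjectionMap, QualityScores

__all__ = [
    "ssim",
    "pcqi",
    "pcqi_detail",
    "embed",
    "frechet_distance",
    "pairwise_quality",
    "EXTRACTORS",
]


def _pixels(x) -> np.ndarray:
    if isinstance(x, ProjectionMap):
        return np.asarray(x.pixels, dtype=float)
    return np.asarray(x, dtype=float)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")


def ssim(
    a,
    b,
    window: int = 11,
    k1: float = 0.01,
    k2: float = 0.03,
    data_range: float = 255.0,
    gaussian: bool = True,
) -> float:
    """Mean structural similarity between two equally-shaped images.

    Defaults are the canonical ones: an 11-px Gaussian-weighted window
    (sigma 1.5) with stabilizers K1=0.01, K2=0.03 on the given dynamic
    range.  ``gaussian=False`` switches to a uniform window, which makes
    single-window values reproducible by hand.
    """
    ia, ib = _pixels(a), _pixels(b)
    _check_shapes(ia, ib)
    return float(
        structural_similarity(
            ia,
            ib,
            win_size=window,
            K1=k1,
            K2=k2,
            data_range=data_range,
            gaussian_weights=gaussian,
            sigma=1.5,
            use_sample_covariance=False,
        )
    )


def _patch_stats(img: np.ndarray, window: int, stride: int):
    v = sliding_window_view(img, (window, window))[::stride, ::stride]
    mu = v.mean(axis=(-1, -2))
    var = v.var(axis=(-1, -2))
    return v, mu, var


def pcqi_detail(
    a,
    b,
    window: int = 11,
    stride: int = 4,
    data_range: float = 255.0,
    c: float = 3.0,
) -> dict:
    """Per-patch PCQI term maps for auditing.

    For reference patch x and test patch y with means mu_x, mu_y, variances
    sigma_x^2, sigma_y^2 and covariance sigma_xy:

    * patch similarity   q_s = (sigma_xy + c) / (sigma_x sigma_y + c)
    * contrast distortion q_c = (4/pi) atan((sigma_xy + c) / (sigma_x^2 + c))
    * mean luminance     q_l = exp(-|mu_x - mu_y| / L)

    and the per-patch score is their product.  For y = x all three terms are
    exactly 1; a pure offset moves only q_l; a pure contrast stretch moves
    only q_c.
    """
    ia, ib = _pixels(a), _pixels(b)
    _check_shapes(ia, ib)
    if min(ia.shape) < window:
        raise ValueError(f"image smaller than window={window}")
    va, mu_a, var_a = _patch_stats(ia, window, stride)
    vb, mu_b, var_b = _patch_stats(ib, window, stride)
    cov = (va * vb).mean(axis=(-1, -2)) - mu_a * mu_b

    q_sim = (cov + c) / (np.sqrt(var_a * var_b) + c)
    q_con = (4.0 / np.pi) * np.arctan((cov + c) / (var_a + c))
    q_lum = np.exp(-np.abs(mu_a - mu_b) / data_range)
    score_map = q_sim * q_con * q_lum
    return {
        "patch_similarity": q_sim,
        "contrast_distortion": q_con,
        "mean_luminance": q_lum,
        "score_map": score_map,
        "score": float(score_map.mean()),
    }


def pcqi(a, b, window: int = 11, stride: int = 4, data_range: float = 255.0) -> float:
    """Mean patch-based contrast quality index; 1 for identical inputs."""
    return pcqi_detail(a, b, window=window, stride=stride, data_range=data_range)["score"]


# ---------------------------------------------------------------------------
# set-level embedding + Fréchet distance


def _radial_profile_stats(img: np.ndarray) -> np.ndarray:
    """Deterministic fixed-length image descriptor (d = 28).

    Concatenates global intensity moments, a 16-bin intensity histogram,
    gradient-magnitude moments and an 8-bin radially averaged log power
    spectrum.  Purely numpy/scipy: no external weights, bit-reproducible.
    """
    x = img / 255.0
    feats = [x.mean(), x.std()]
    hist, _ = np.histogram(x, bins=16, range=(0.0, 1.0), density=True)
    feats.extend(hist / 16.0)
    gy, gx = np.gradient(x)
    gmag = np.hypot(gy, gx)
    feats.extend([gmag.mean(), gmag.std()])
    f = np.abs(np.fft.fftshift(np.fft.fft2(x))) ** 2
    h, w = f.shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - h / 2.0, xx - w / 2.0)
    r_max = r.max()
    for i in range(8):
        ring = (r >= i * r_max / 8.0) & (r < (i + 1) * r_max / 8.0)
        feats.append(np.log1p(f[ring].mean()) if ring.any() else 0.0)
    return np.asarray(feats, dtype=float)


def _inception_unavailable(img: np.ndarray) -> np.ndarray:
    raise RuntimeError(
        "inception_v3_pool3 embedding needs pretrained network weights, which "
        "are not bundled; use extractor='radial_profile_stats' for a "
        "deterministic offline embedding"
    )


EXTRACTORS = {
    "radial_profile_stats": _radial_profile_stats,
    "inception_v3_pool3": _inception_unavailable,
}


def embed(images, extractor: str = "radial_profile_stats") -> np.ndarray:
    """Embed a set of images into fixed-length feature vectors (n x d)."""
    if extractor not in EXTRACTORS:
        raise ValueError(f"unknown extractor {extractor!r}; options: {sorted(EXTRACTORS)}")
    fn = EXTRACTORS[extractor]
    imgs = [_pixels(im) for im in images]
    if not imgs:
        raise ValueError("cannot embed an empty image set")
    return np.stack([fn(im) for im in imgs])


def frechet_distance(feats_a: np.ndarray, feats_b: np.ndarray, eps: float = 1e-6) -> float:
    """Fréchet (Wasserstein-2) distance between Gaussian fits to two feature sets.

    d^2 = ||mu_A - mu_B||^2 + Tr(S_A + S_B - 2 (S_A S_B)^{1/2}), with both
    covariances regularized by ``eps * I`` against rank deficiency.
    Symmetric, non-negative, and 0 for identical sets.
    """
    a = np.atleast_2d(np.asarray(feats_a, dtype=float))
    b = np.atleast_2d(np.asarray(feats_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each feature set needs at least 2 samples")
    if a.shape[1] != b.shape[1]:
        raise ValueError("feature dimensions differ")
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    cov_a = np.cov(a, rowvar=False) + eps * np.eye(a.shape[1])
    cov_b = np.cov(b, rowvar=False) + eps * np.eye(b.shape[1])
    covmean = linalg.sqrtm(cov_a @ cov_b)
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    d2 = float(np.sum((mu_a - mu_b) ** 2) + np.trace(cov_a + cov_b - 2.0 * covmean))
    return max(d2, 0.0)


def pairwise_quality(
    pairs,
    window: int = 11,
    stride: int = 4,
    extractor: str = "radial_profile_stats",
) -> tuple[pd.DataFrame, float]:
    """SSIM/PCQI per (GT, TR) pair plus one set-level Fréchet distance.

    ``pairs`` is an iterable of ``(subject_id, gt_map, tr_map)``.  Returns a
    per-pair DataFrame and the arm-level Fréchet distance between the two
    embedded image sets (NaN when fewer than two pairs).
    """
    rows, gts, trs = [], [], []
    for subject_id, gt, tr in pairs:
        rows.append(
            {
                "subject_id": subject_id,
                "ssim": ssim(gt, tr, window=window),
                "pcqi": pcqi(gt, tr, window=window, stride=stride),
            }
        )
        gts.append(gt)
        trs.append(tr)
    if len(gts) >= 2:
        fid = frechet_distance(embed(gts, extractor), embed(trs, extractor))
    else:
        fid = float("nan")
    return pd.DataFrame(rows), fid
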