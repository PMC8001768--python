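"""Handcrafted image descriptors and their 550-dimensional fusion.

Three complementary views of a histology patch are computed and concatenated:

* **Zernike moment magnitudes** (25 values, radial orders 0-8) — projections
  of the gray image onto the orthogonal Zernike basis over the unit disk
  inscribed in the image,

      Z[n, m] = (n + 1) / alpha * sum_{rho <= 1} f(x, y) R[n, m](rho) e^{-i m theta},

  with ``alpha`` the number of pixels inside the disk.  Magnitudes are
  rotation-invariant shape/margin descriptors.
* **Haralick texture statistics** (13 values) — the classical co-occurrence
  statistics (angular second moment through the two information measures of
  correlation; the unstable 14th, maximal correlation coefficient, is
  omitted) computed on gray-level co-occurrence matrices at distances
  {1, 2, 4} and eight angles, then averaged element-wise across all
  distance/angle combinations.
* **Joint color histogram** (512 values) — the 8x8x8 RGB histogram,
  normalized to frequencies, flattened R-major.

The fused vector layout is fixed: [0:25) Zernike, [25:38) Haralick,
[38:550) color histogram.  Images are resized to 224 x 224 before
extraction so the handcrafted and deep arms see identical inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .synthetic import ImagePatch

__all__ = [
    "ZernikeSpec",
    "ZernikeResult",
    "GLCMSpec",
    "FEATURE_LENGTH",
    "ZERNIKE_SLICE",
    "HARALICK_SLICE",
    "HISTOGRAM_SLICE",
    "zernike_index_list",
    "zernike_moments",
    "quantize_gray",
    "glcm",
    "haralick_from_glcm",
    "haralick_features",
    "color_histogram",
    "fuse",
    "extract_features",
    "extract_features_table",
    "rgb_to_gray",
    "feature_column_names",
]

FEATURE_LENGTH = 550
ZERNIKE_SLICE = slice(0, 25)
HARALICK_SLICE = slice(25, 38)
HISTOGRAM_SLICE = slice(38, 550)

_LOG_EPS = 1e-12


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """ITU-R BT.601 luma, float in [0, 255]."""
    rgb = np.asarray(rgb, dtype=float)
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


# ---------------------------------------------------------------------------
# Zernike moments
# ---------------------------------------------------------------------------

def zernike_index_list(n_max: int) -> list[tuple[int, int]]:
    """Valid (n, m) pairs with 0 <= n <= n_max, m >= 0, n - m even, m <= n,
    sorted by (n, m).  25 pairs for n_max = 8."""
    return [(n, m) for n in range(n_max + 1) for m in range(n + 1)
            if (n - m) % 2 == 0]


@dataclass(frozen=True)
class ZernikeSpec:
    """Disk mapping and order bound for Zernike extraction: the grid is
    mapped onto the unit disk centered at the image center with radius
    min(H, W) / 2."""

    n_max: int = 8

    @property
    def index_list(self) -> list[tuple[int, int]]:
        return zernike_index_list(self.n_max)


@dataclass
class ZernikeResult:
    magnitudes: np.ndarray            # aligned to index_list, all >= 0
    alpha: float                      # normalization: pixel count in the disk
    index_list: list[tuple[int, int]] = field(default_factory=list)


def radial_polynomial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    """Zernike radial polynomial R_{n,m}(rho) (m >= 0, n - m even)."""
    out = np.zeros_like(rho, dtype=float)
    for s in range((n - m) // 2 + 1):
        coeff = ((-1) ** s * math.factorial(n - s)
                 / (math.factorial(s)
                    * math.factorial((n + m) // 2 - s)
                    * math.factorial((n - m) // 2 - s)))
        out += coeff * rho ** (n - 2 * s)
    return out


@lru_cache(maxsize=8)
def _zernike_basis(shape: tuple[int, int], n_max: int):
    """Precomputed conjugate basis rows over disk pixels for one grid shape.

    Returns (flat disk-pixel indices, alpha, complex basis matrix of shape
    (n_indices, n_disk_pixels))."""
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = min(h, w) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    rho = np.hypot((yy - cy) / radius, (xx - cx) / radius)
    inside = (rho <= 1.0).ravel()
    rho_d = rho.ravel()[inside]
    theta_d = np.arctan2((yy - cy).ravel()[inside], (xx - cx).ravel()[inside])
    idx = zernike_index_list(n_max)
    basis = np.empty((len(idx), rho_d.size), dtype=complex)
    for row, (n, m) in enumerate(idx):
        basis[row] = radial_polynomial(n, m, rho_d) * np.exp(-1j * m * theta_d)
    return inside, float(inside.sum()), basis


def zernike_moments(gray: np.ndarray, spec: ZernikeSpec = ZernikeSpec()) -> ZernikeResult:
    """Zernike moment magnitudes of a 2-D raster for all orders up to n_max.

    Pixels outside the inscribed unit disk contribute zero; an all-zero image
    yields a zero vector.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2 or min(gray.shape) < 8:
        raise ValueError(f"need a 2-D image at least 8x8, got shape {gray.shape}")
    inside, alpha, basis = _zernike_basis(gray.shape, spec.n_max)
    f = gray.ravel()[inside]
    idx = spec.index_list
    n_plus_1 = np.array([n + 1 for n, _ in idx], dtype=float)
    z = (n_plus_1 / alpha) * (basis @ f)
    return ZernikeResult(magnitudes=np.abs(z), alpha=alpha, index_list=idx)


# ---------------------------------------------------------------------------
# GLCM / Haralick
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GLCMSpec:
    """Gray-level co-occurrence setup: quantization levels, displacement
    distances and the eight compass angles."""

    levels: int = 32
    distances: tuple[int, ...] = (1, 2, 4)
    angles: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)
    symmetric: bool = True
    normalized: bool = True


def quantize_gray(gray: np.ndarray, levels: int) -> np.ndarray:
    """Uniform quantization of [0, 255] intensities into ``levels`` bins."""
    g = np.clip(np.asarray(gray, dtype=float), 0.0, 255.0)
    return np.minimum((g / 256.0 * levels).astype(np.intp), levels - 1)


def glcm(gray_q: np.ndarray, levels: int, d: int, angle: float,
         symmetric: bool = True, normalized: bool = True) -> np.ndarray:
    """Co-occurrence matrix of quantized levels at displacement
    (round(d cos a), -round(d sin a)) in (col, row) image coordinates."""
    gray_q = np.asarray(gray_q)
    h, w = gray_q.shape
    a = math.radians(angle)
    dc = int(round(d * math.cos(a)))
    dr = -int(round(d * math.sin(a)))
    if abs(dr) >= h or abs(dc) >= w:
        raise ValueError(f"displacement ({dr}, {dc}) exceeds image shape {gray_q.shape}")
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    src = gray_q[r0:r1, c0:c1].ravel()
    dst = gray_q[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    P = np.zeros((levels, levels), dtype=float)
    np.add.at(P, (src, dst), 1.0)
    if symmetric:
        P = P + P.T
    if normalized:
        total = P.sum()
        if total > 0:
            P = P / total
    return P


def haralick_from_glcm(P: np.ndarray) -> np.ndarray:
    """The 13 Haralick statistics of one normalized GLCM.

    Order: angular second moment, contrast, correlation, sum of squares
    variance, inverse difference moment, sum average, sum variance,
    sum entropy, entropy, difference variance, difference entropy,
    information measures of correlation 1 and 2.
    """
    P = np.asarray(P, dtype=float)
    L = P.shape[0]
    i = np.arange(L, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    sd_x = math.sqrt(float(((i - mu_x) ** 2) @ px))
    sd_y = math.sqrt(float(((i - mu_y) ** 2) @ py))

    # distributions of i+j (0..2L-2) and |i-j| (0..L-1)
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (ii + jj).astype(np.intp), P)
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(ii - jj).astype(np.intp), P)
    k_sum = np.arange(2 * L - 1, dtype=float)
    k_diff = np.arange(L, dtype=float)

    def _ent(q):
        return float(-(q * np.log2(q + _LOG_EPS)).sum())

    f = np.empty(13)
    f[0] = float((P ** 2).sum())                                   # ASM
    f[1] = float((k_diff ** 2) @ p_diff)                           # contrast
    if sd_x * sd_y > _LOG_EPS:
        f[2] = (float((ii * jj * P).sum()) - mu_x * mu_y) / (sd_x * sd_y)
    else:
        f[2] = 0.0                                                 # correlation
    f[3] = float((((ii - mu_x) ** 2) * P).sum())                   # variance
    f[4] = float((P / (1.0 + (ii - jj) ** 2)).sum())               # IDM
    f[5] = float(k_sum @ p_sum)                                    # sum average
    f[6] = float(((k_sum - f[5]) ** 2) @ p_sum)                    # sum variance
    f[7] = _ent(p_sum)                                             # sum entropy
    f[8] = _ent(P)                                                 # entropy
    mu_diff = float(k_diff @ p_diff)
    f[9] = float(((k_diff - mu_diff) ** 2) @ p_diff)               # diff variance
    f[10] = _ent(p_diff)                                           # diff entropy
    pxpy = np.outer(px, py)
    hxy = f[8]
    hxy1 = float(-(P * np.log2(pxpy + _LOG_EPS)).sum())
    hxy2 = _ent(pxpy)
    hx, hy = _ent(px), _ent(py)
    denom = max(hx, hy)
    f[11] = (hxy - hxy1) / denom if denom > _LOG_EPS else 0.0      # IMC 1
    f[12] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))  # IMC 2
    return f


def haralick_features(gray: np.ndarray, spec: GLCMSpec = GLCMSpec()) -> np.ndarray:
    """Element-wise mean of the 13 Haralick statistics over all
    (distance, angle) co-occurrence matrices."""
    gq = quantize_gray(gray, spec.levels)
    feats = [
        haralick_from_glcm(glcm(gq, spec.levels, d, ang,
                                symmetric=spec.symmetric,
                                normalized=spec.normalized))
        for d in spec.distances for ang in spec.angles
    ]
    return np.mean(feats, axis=0)


# ---------------------------------------------------------------------------
# Color histogram and fusion
# ---------------------------------------------------------------------------

def color_histogram(image, bins_per_channel: int = 8) -> np.ndarray:
    """Joint RGB histogram (bins_per_channel^3 entries), uniform bins over
    [0, 255], flattened R-major then G then B, normalized to sum 1."""
    px = image.pixels if isinstance(image, ImagePatch) else np.asarray(image)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {px.shape}")
    b = bins_per_channel
    q = np.minimum((px.reshape(-1, 3).astype(float) / 256.0 * b).astype(np.intp), b - 1)
    flat = (q[:, 0] * b + q[:, 1]) * b + q[:, 2]
    hist = np.bincount(flat, minlength=b ** 3).astype(float)
    return hist / hist.sum()


def fuse(z: ZernikeResult | np.ndarray, h: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Concatenate the three descriptors in the fixed 550-d layout."""
    zm = z.magnitudes if isinstance(z, ZernikeResult) else np.asarray(z, dtype=float)
    h = np.asarray(h, dtype=float)
    c = np.asarray(c, dtype=float)
    if zm.shape != (25,) or h.shape != (13,) or c.shape != (512,):
        raise ValueError(
            f"component lengths must be (25, 13, 512), got "
            f"({zm.shape}, {h.shape}, {c.shape})")
    v = np.concatenate([zm, h, c])
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite feature values")
    return v


def resize_image(px: np.ndarray, size: int) -> np.ndarray:
    """Anti-aliased resize to (size, size), back to uint8."""
    if px.shape[0] == size and px.shape[1] == size:
        return px
    out = _sk_resize(px, (size, size), preserve_range=True, anti_aliasing=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def extract_features(image, zspec: ZernikeSpec = ZernikeSpec(),
                     gspec: GLCMSpec = GLCMSpec(), bins_per_channel: int = 8,
                     resize_to: int = 224) -> np.ndarray:
    """The fused 550-d descriptor of one RGB image (resized first so the
    handcrafted and deep arms see identical inputs)."""
    px = image.pixels if isinstance(image, ImagePatch) else np.asarray(image)
    px = resize_image(px, resize_to)
    gray = rgb_to_gray(px)
    z = zernike_moments(gray, zspec)
    h = haralick_features(gray, gspec)
    c = color_histogram(px, bins_per_channel)
    return fuse(z, h, c)


def feature_column_names(zspec: ZernikeSpec = ZernikeSpec(),
                         bins_per_channel: int = 8) -> list[str]:
    """Layout-stable column names for the fused vector."""
    cols = [f"z_{n}_{m}" for n, m in zspec.index_list]
    cols += [f"har_{i:02d}" for i in range(1, 14)]
    b = bins_per_channel
    cols += [f"ch_{r}_{g}_{bl}" for r in range(b) for g in range(b) for bl in range(b)]
    return cols


def extract_features_table(manifest: pd.DataFrame, root: str | Path,
                           resize_to: int = 224, **kwargs) -> pd.DataFrame:
    """Fused features for every manifest record, one row per image, with the
    manifest's label columns appended."""
    from PIL import Image

    root = Path(root)
    rows = []
    for rel in manifest["image_path"]:
        px = np.asarray(Image.open(root / rel).convert("RGB"))
        rows.append(extract_features(px, resize_to=resize_to, **kwargs))
    feats = pd.DataFrame(np.asarray(rows), columns=feature_column_names())
    for col in ("image_path", "class", "subclass", "magnification", "patient_id"):
        if col in manifest.columns:
            feats[col] = manifest[col].to_numpy()
    return feats
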