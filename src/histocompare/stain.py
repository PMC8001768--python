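"""Stain-color normalization by sparse non-negative stain separation.

H&E color variation between scanners/batches is removed by (1) converting
RGB to optical density, OD = -log10(I / I0), where stain concentrations are
linear (Beer-Lambert), (2) factorizing tissue-pixel ODs as ``V ~ W @ H`` with
a 3x2 non-negative stain-color matrix ``W`` (unit-norm columns) and sparse
non-negative concentrations ``H``, and (3) re-composing the source image's
concentration maps with a reference image's stain matrix after matching
robust concentration maxima.  Concentration structure — hence tissue
morphology — is preserved; only color is exchanged.

The factorization solves

    min ||V - W H||_F^2 + lambda * sum_i ||H_i||_1,   W >= 0, H >= 0

by multiplicative updates (column normalization each sweep, entries floored
away from the absorbing zero boundary) started from a geometric estimate:
the angular extremes of the tissue pixels projected onto their dominant
2-D OD plane.  Without pure-stain pixels the factorization is only weakly
identifiable — prolonged unconstrained descent over-spreads the stain cone —
so the refinement is budgeted (200 sweeps, early stop on relative objective
change) and stays near the extreme-ray solution, which is the quantity of
interest.  Defaults: OD tissue threshold beta = 0.15, sparsity
lambda = 0.02 in this module's units (log10 OD, summed squared error);
published values for the natural-log, per-pixel averaged form of the
objective are larger.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .synthetic import DEFAULT_STAIN_MATRIX, ImagePatch

__all__ = [
    "NoTissueError",
    "StainProfile",
    "rgb_to_od",
    "od_to_rgb",
    "estimate_stain_matrix",
    "stain_profile",
    "normalize_stains",
]

_EPS = 1e-12


class NoTissueError(ValueError):
    """Raised when an image has too few tissue pixels for stain separation;
    callers in pipeline mode should skip normalization for that image."""


@dataclass
class StainProfile:
    """A 3x2 unit-column stain matrix (hematoxylin first) plus robust
    (99th-percentile) concentration maxima of the fitted image."""

    W: np.ndarray       # (3, 2), columns unit Euclidean norm, W >= 0
    c_max: np.ndarray   # (2,) 99th percentile of each concentration row

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"W": self.W.tolist(), "c_max": self.c_max.tolist()}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StainProfile":
        d = json.loads(Path(path).read_text())
        return cls(W=np.asarray(d["W"], dtype=float),
                   c_max=np.asarray(d["c_max"], dtype=float))


def _as_pixels(image) -> np.ndarray:
    px = image.pixels if isinstance(image, ImagePatch) else np.asarray(image)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {px.shape}")
    return px


def rgb_to_od(image, I0: int = 255) -> np.ndarray:
    """Optical density per channel: od = -log10(max(I, 1) / I0).

    Zero exactly where the pixel equals I0 (pure white background)."""
    px = _as_pixels(image).astype(float)
    px = np.clip(px, 1.0, I0)
    return -np.log10(px / I0)


def od_to_rgb(od: np.ndarray, I0: int = 255) -> np.ndarray:
    """Inverse OD transform, rounded and clipped to [0, 255] uint8."""
    return np.clip(np.rint(I0 * 10.0 ** (-np.asarray(od, dtype=float))),
                   0, 255).astype(np.uint8)


_W_FLOOR = 1e-4  # keeps multiplicative updates off the absorbing zero boundary


def _geometric_init(V: np.ndarray, rng: np.random.Generator,
                    pct: float = 1.0) -> np.ndarray:
    """Initial stain matrix from the angular extremes of the OD pixels.

    Tissue ODs live (up to noise) in the non-negative cone spanned by the two
    stain vectors.  Projecting onto the dominant 2-D plane of the pixel cloud
    and taking robust extreme angles recovers the cone's edge rays.
    """
    U, _, _ = np.linalg.svd(V, full_matrices=False)
    U = U[:, :2]
    if U[:, 0].sum() < 0:  # orient first axis toward the data
        U[:, 0] = -U[:, 0]
    P = U.T @ V
    ang = np.arctan2(P[1], P[0])
    lo, hi = np.percentile(ang, [pct, 100.0 - pct])
    W = np.column_stack([
        U @ np.array([np.cos(lo), np.sin(lo)]),
        U @ np.array([np.cos(hi), np.sin(hi)]),
    ])
    W = np.abs(W) if (W < 0).all(axis=0).any() else np.clip(W, _W_FLOOR, None)
    if np.linalg.matrix_rank(W, tol=1e-8) < 2:  # degenerate cloud
        W = np.clip(W + rng.uniform(0.0, 0.1, W.shape), _W_FLOOR, None)
    return W / np.linalg.norm(W, axis=0, keepdims=True)


def _sparse_nmf(V: np.ndarray, lam: float, seed: int,
                max_iter: int = 200, tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Two-stain sparse NMF of OD pixels V (3, N) by multiplicative updates
    from the geometric extreme-ray initialization; deterministic per seed."""
    rng = np.random.default_rng(seed)
    W = _geometric_init(V, rng)
    H = np.clip(np.linalg.lstsq(W, V, rcond=None)[0], _EPS, None)
    prev = np.inf
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + lam + _EPS)
        H = np.maximum(H, _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        W = np.maximum(W, _W_FLOOR)
        norms = np.linalg.norm(W, axis=0, keepdims=True)
        W /= norms
        H *= norms.T
        obj = float(np.sum((V - W @ H) ** 2) + lam * np.abs(H).sum())
        if abs(prev - obj) <= tol * max(prev, 1.0):
            break
        prev = obj
    return W, H


def _order_hematoxylin_first(W: np.ndarray, H: np.ndarray):
    """Column with the larger blue-channel OD loading is hematoxylin."""
    if W[2, 0] < W[2, 1]:
        W = W[:, ::-1].copy()
        H = H[::-1].copy()
    return W, H


def _tissue_mask(od: np.ndarray, beta: float) -> np.ndarray:
    return od.max(axis=-1) > beta


def estimate_stain_matrix(od: np.ndarray, lam: float = 0.02, beta: float = 0.15,
                          seed: int = 0) -> StainProfile:
    """Estimate the stain profile of an image from its OD raster.

    Only tissue pixels (max-channel OD > beta) enter the factorization.
    Raises :class:`NoTissueError` below 100 tissue pixels.
    """
    od = np.asarray(od, dtype=float)
    mask = _tissue_mask(od, beta)
    n_tissue = int(mask.sum())
    if n_tissue < 100:
        raise NoTissueError(
            f"only {n_tissue} tissue pixels above OD {beta}; "
            "skip stain normalization for this image")
    V = od[mask].T  # (3, N)
    W, H = _sparse_nmf(V, lam=lam, seed=seed)
    W, H = _order_hematoxylin_first(W, H)
    # c_max from unpenalized concentrations: the L1 term is a fitting device
    # for W, not part of the reconstruction scale
    H_fit = _nnls_concentrations(V, W)
    c_max = np.percentile(H_fit, 99, axis=1)
    return StainProfile(W=W, c_max=c_max)


def stain_profile(image, lam: float = 0.02, beta: float = 0.15,
                  seed: int = 0) -> StainProfile:
    """Convenience wrapper: estimate a stain profile directly from RGB."""
    return estimate_stain_matrix(rgb_to_od(image), lam=lam, beta=beta, seed=seed)


def _nnls_concentrations(V: np.ndarray, W: np.ndarray,
                         n_iter: int = 200) -> np.ndarray:
    """Non-negative least-squares concentrations H (2, N) for fixed W, by
    multiplicative updates of H only (no sparsity penalty)."""
    H = np.clip(np.linalg.pinv(W) @ V, _EPS, None)
    WtV = np.maximum(W.T @ V, 0.0)
    WtW = W.T @ W
    for _ in range(n_iter):
        H *= WtV / (WtW @ H + _EPS)
        H = np.maximum(H, 0.0)
    return H


def concentrations(od: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Non-negative concentration maps H (2, N) of all pixels for fixed W."""
    return _nnls_concentrations(od.reshape(-1, 3).T, W)


def normalize_stains(source, reference: StainProfile, lam: float = 0.02,
                     beta: float = 0.15, seed: int = 0) -> np.ndarray:
    """Map a source image onto the reference stain basis.

    Decomposes the source into (W_src, H_src), rescales each concentration
    row by reference.c_max / source.c_max, recomposes with reference.W and
    inverts OD back to RGB.  White background stays white (zero
    concentration).  Raises :class:`NoTissueError` for near-empty images.
    """
    px = _as_pixels(source)
    od = rgb_to_od(px)
    src = estimate_stain_matrix(od, lam=lam, beta=beta, seed=seed)
    H = concentrations(od, src.W)
    mask = _tissue_mask(od, beta).reshape(-1)
    src_cmax = np.percentile(H[:, mask], 99, axis=1) if mask.any() else src.c_max
    scale = reference.c_max / np.maximum(src_cmax, _EPS)
    od_new = (reference.W @ (H * scale[:, None])).T.reshape(px.shape)
    return od_to_rgb(od_new)
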