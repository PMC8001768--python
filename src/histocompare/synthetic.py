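"""Seeded synthetic H&E-like image generation.

Real H&E patches mix two dyes: hematoxylin stains nuclei purple/blue, eosin
stains cytoplasm and stroma pink.  The generator renders patches with a
two-stain Beer-Lambert color model

    RGB(x, y) = 255 * exp(-W @ c(x, y))

where ``W`` is a 3x2 non-negative stain-color (optical density) matrix with
unit-norm columns and ``c`` the per-pixel two-stain concentration vector.
Nuclei carry high hematoxylin concentration; a band-passed noise field plays
the role of eosin-stained stroma.  Class identity is encoded the way tumor
classes differ in real tissue: nucleus size, count, eccentricity, margin
irregularity, spatial clustering and background texture scale.  Benign-like
classes have small round nuclei with smooth margins; malignant-like classes
have larger, more irregular, more clustered nuclei.

Every function is deterministic for a fixed seed, and every generated image
comes with pixel-exact ground truth (nucleus centers and the union mask of
rendered nuclei), so downstream stages can be tested without any real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "ClassSpec",
    "GroundTruth",
    "ImagePatch",
    "DEFAULT_STAIN_MATRIX",
    "MAGNIFICATION_SCALE",
    "default_benign_spec",
    "default_malignant_spec",
    "subclass_specs",
    "kimia_class_specs",
    "jitter_stain_matrix",
    "generate_image",
    "generate_dataset",
    "generate_kimia_fixture",
    "read_manifest",
]

#: Reference H&E stain matrix in OD space (columns: hematoxylin, eosin),
#: widely used literature values, normalized to unit Euclidean column norm.
_RAW_STAINS = np.array([[0.65, 0.07], [0.70, 0.99], [0.29, 0.11]], dtype=float)
DEFAULT_STAIN_MATRIX = _RAW_STAINS / np.linalg.norm(_RAW_STAINS, axis=0, keepdims=True)

#: Magnification realized purely as a nucleus-scale multiplier at fixed
#: patch size (no resampling).
MAGNIFICATION_SCALE = {40: 1.0, 100: 1.6, 200: 2.5, 400: 4.0}

MANIFEST_COLUMNS = [
    "image_path",
    "class",
    "subclass",
    "magnification",
    "patient_id",
    "split_tag",
]


@dataclass(frozen=True)
class ClassSpec:
    """Generative parameters for one image class.

    Parameters mirror the morphology axes pathologists describe: nucleus
    count/size, shape (eccentricity), margin irregularity (radial
    perturbation amplitude), spatial clustering, background texture
    frequency band (cycles per patch) and per-image stain-matrix jitter.
    """

    class_id: str
    nucleus_count_range: tuple[int, int] = (8, 15)
    nucleus_radius_range: tuple[float, float] = (3.0, 6.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.3)
    margin_irregularity: float = 0.05
    clustering: float = 0.2
    texture_band: tuple[float, float] = (4.0, 8.0)
    stain_jitter: float = 0.02
    nucleus_stain: float = 1.1  # hematoxylin concentration inside nuclei
    stroma_stain: float = 0.6   # eosin concentration scale of the stroma field
    signal_quadrant: str = "none"  # one of TL, TR, BL, BR, none

    def validate(self) -> None:
        def _rng_ok(r, lo_ok=0.0):
            return len(r) == 2 and r[0] <= r[1] and r[0] >= lo_ok

        if not _rng_ok(self.nucleus_count_range) or self.nucleus_count_range[0] < 0:
            raise ValueError(f"invalid nucleus_count_range {self.nucleus_count_range}")
        if not _rng_ok(self.nucleus_radius_range):
            raise ValueError(f"invalid nucleus_radius_range {self.nucleus_radius_range}")
        e = self.eccentricity_range
        if not (_rng_ok(e) and 0.0 <= e[0] and e[1] < 1.0):
            raise ValueError(f"invalid eccentricity_range {e}")
        if self.margin_irregularity < 0 or self.stain_jitter < 0:
            raise ValueError("margin_irregularity and stain_jitter must be >= 0")
        if not 0.0 <= self.clustering <= 1.0:
            raise ValueError("clustering must lie in [0, 1]")
        if not _rng_ok(self.texture_band) or self.texture_band[0] <= 0:
            raise ValueError(f"invalid texture_band {self.texture_band}")
        if self.signal_quadrant not in {"TL", "TR", "BL", "BR", "none"}:
            raise ValueError(f"invalid signal_quadrant {self.signal_quadrant!r}")


@dataclass
class GroundTruth:
    """Pixel-exact generation record for one image."""

    nucleus_centers: np.ndarray  # (n, 2) array of (row, col)
    nucleus_mask: np.ndarray     # (H, W) bool, union of rendered nuclei
    signal_quadrant: str = "none"


@dataclass
class ImagePatch:
    """An RGB raster with provenance metadata."""

    pixels: np.ndarray  # (H, W, 3) uint8
    label: str = ""
    subclass: str = ""
    magnification: int | None = None
    patient_id: str = ""


def default_benign_spec(**overrides) -> ClassSpec:
    """Benign-like class: small round nuclei, smooth margins, coarse stroma."""
    kw = dict(
        class_id="benign",
        nucleus_count_range=(8, 15),
        nucleus_radius_range=(3.0, 6.0),
        eccentricity_range=(0.0, 0.3),
        margin_irregularity=0.05,
        clustering=0.2,
        texture_band=(4.0, 8.0),
        stain_jitter=0.02,
    )
    kw.update(overrides)
    return ClassSpec(**kw)


def default_malignant_spec(**overrides) -> ClassSpec:
    """Malignant-like class: larger irregular clustered nuclei, finer texture."""
    kw = dict(
        class_id="malignant",
        nucleus_count_range=(10, 20),
        nucleus_radius_range=(6.0, 11.0),
        eccentricity_range=(0.3, 0.7),
        margin_irregularity=0.35,
        clustering=0.55,
        texture_band=(8.0, 16.0),
        stain_jitter=0.05,
    )
    kw.update(overrides)
    return ClassSpec(**kw)


#: The eight tumor sub-classes: four benign-like (A, F, PT, TA) and four
#: malignant-like (DC, LC, MC, PC), separated by graded morphology knobs.
_SUBCLASS_TABLE = {
    # id: (parent, radius_range, margin, clustering, texture_band, count)
    "A":  ("benign", (3.0, 5.0), 0.04, 0.15, (3.0, 6.0), (8, 14)),
    "F":  ("benign", (3.5, 6.0), 0.06, 0.25, (4.0, 8.0), (9, 16)),
    "PT": ("benign", (4.0, 6.5), 0.08, 0.30, (5.0, 9.0), (8, 15)),
    "TA": ("benign", (3.0, 6.0), 0.10, 0.35, (6.0, 10.0), (10, 16)),
    "DC": ("malignant", (6.0, 10.0), 0.30, 0.50, (8.0, 14.0), (10, 18)),
    "LC": ("malignant", (6.5, 10.5), 0.35, 0.55, (9.0, 15.0), (11, 19)),
    "MC": ("malignant", (7.0, 11.0), 0.40, 0.60, (10.0, 17.0), (10, 20)),
    "PC": ("malignant", (7.5, 11.5), 0.45, 0.65, (11.0, 18.0), (12, 20)),
}


def subclass_specs() -> dict[str, ClassSpec]:
    """Specs for the eight tumor sub-classes, keyed by sub-class label."""
    out = {}
    for cid, (parent, rad, marg, clus, band, cnt) in _SUBCLASS_TABLE.items():
        base = default_benign_spec if parent == "benign" else default_malignant_spec
        out[cid] = base(
            class_id=cid,
            nucleus_radius_range=rad,
            margin_irregularity=marg,
            clustering=clus,
            texture_band=band,
            nucleus_count_range=cnt,
        )
    return out


def kimia_class_specs() -> dict[str, ClassSpec]:
    """Twenty texture-patch classes labeled A..T.

    Classes are separated mainly by background texture frequency band and
    stain composition, with a mild sweep of nuclear morphology — emulating a
    tissue-texture benchmark rather than a tumor-grading one.
    """
    specs = {}
    for i in range(20):
        label = chr(ord("A") + i)
        lo = 2.0 + 1.4 * i
        hi = lo + 3.0 + 0.4 * i
        specs[label] = ClassSpec(
            class_id=label,
            nucleus_count_range=(3 + (i % 5), 6 + (i % 5)),
            nucleus_radius_range=(2.5 + 0.35 * (i % 7), 5.0 + 0.35 * (i % 7)),
            eccentricity_range=(0.05 * (i % 4), 0.05 * (i % 4) + 0.25),
            margin_irregularity=0.03 + 0.02 * (i % 6),
            clustering=0.1 + 0.04 * (i % 8),
            texture_band=(lo, hi),
            stain_jitter=0.02,
            nucleus_stain=0.8 + 0.05 * (i % 6),
            stroma_stain=0.35 + 0.05 * (i % 7),
        )
    return specs


def jitter_stain_matrix(rng: np.random.Generator, sigma: float,
                        base: np.ndarray | None = None) -> np.ndarray:
    """Perturb stain-matrix columns with Gaussian noise, clip to >= 0 and
    renormalize each column to unit Euclidean length."""
    W = (DEFAULT_STAIN_MATRIX if base is None else base).copy()
    if sigma > 0:
        W = np.clip(W + rng.normal(0.0, sigma, W.shape), 0.0, None)
    norms = np.linalg.norm(W, axis=0, keepdims=True)
    norms[norms == 0] = 1.0
    return W / norms


def _bandpass_noise(rng: np.random.Generator, shape: tuple[int, int],
                    band: tuple[float, float]) -> np.ndarray:
    """Isotropic noise band-passed to ``band`` cycles per patch, in [0, 1]."""
    h, w = shape
    white = rng.standard_normal(shape)
    fy = np.fft.fftfreq(h)[:, None] * h
    fx = np.fft.fftfreq(w)[None, :] * w
    f = np.hypot(fy, fx)
    lo, hi = band
    mid, width = 0.5 * (lo + hi), max(0.5 * (hi - lo), 1e-6)
    weight = np.exp(-0.5 * ((f - mid) / width) ** 2)
    tex = np.real(np.fft.ifft2(np.fft.fft2(white) * weight))
    tmin, tmax = tex.min(), tex.max()
    if tmax - tmin < 1e-12:
        return np.zeros(shape)
    return (tex - tmin) / (tmax - tmin)


def _quadrant_box(quadrant: str, h: int, w: int) -> tuple[float, float, float, float]:
    """(row_lo, row_hi, col_lo, col_hi) of the region nuclei may occupy."""
    if quadrant == "none":
        return 0.0, float(h), 0.0, float(w)
    r_half, c_half = h / 2.0, w / 2.0
    return {
        "TL": (0.0, r_half, 0.0, c_half),
        "TR": (0.0, r_half, c_half, float(w)),
        "BL": (r_half, float(h), 0.0, c_half),
        "BR": (r_half, float(h), c_half, float(w)),
    }[quadrant]


def _render_nucleus(mask: np.ndarray, rng: np.random.Generator, center,
                    radius: float, ecc: float, margin: float) -> None:
    """Rasterize one nucleus into ``mask`` (in place).

    Boundary: an ellipse with semi-axes (a, b), b = a*sqrt(1 - ecc^2), whose
    normalized radius is perturbed as r(theta) = 1 + margin * sum of 3
    low-order sinusoids with random phases.
    """
    h, w = mask.shape
    a = radius
    b = radius * np.sqrt(1.0 - ecc ** 2)
    phi = rng.uniform(0, 2 * np.pi)             # orientation
    amps = rng.dirichlet(np.ones(3))            # sinusoid weights, sum 1
    phases = rng.uniform(0, 2 * np.pi, 3)
    reach = a * (1.0 + margin) + 1.0
    r0 = max(int(np.floor(center[0] - reach)), 0)
    r1 = min(int(np.ceil(center[0] + reach)) + 1, h)
    c0 = max(int(np.floor(center[1] - reach)), 0)
    c1 = min(int(np.ceil(center[1] + reach)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = yy - center[0]
    dx = xx - center[1]
    # rotate into the ellipse frame
    u = np.cos(phi) * dx + np.sin(phi) * dy
    v = -np.sin(phi) * dx + np.cos(phi) * dy
    rho = np.hypot(u / a, v / b)
    theta = np.arctan2(v, u)
    bound = 1.0
    for k, (amp, ph) in enumerate(zip(amps, phases), start=2):
        bound = bound + margin * amp * np.sin(k * theta + ph)
    mask[r0:r1, c0:c1] |= rho <= bound


def generate_image(spec: ClassSpec, size: tuple[int, int] = (96, 96),
                   seed: int = 0, magnification: int = 40,
                   stain_matrix: np.ndarray | None = None,
                   ) -> tuple[ImagePatch, GroundTruth]:
    """Render one synthetic H&E-like patch.

    Deterministic for fixed ``(spec, size, seed, magnification)``.  Returns
    the image together with its ground truth (nucleus centers, union mask).
    """
    spec.validate()
    h, w = int(size[0]), int(size[1])
    if h < 32 or w < 32:
        raise ValueError(f"size must be at least 32x32, got {size}")
    if magnification not in MAGNIFICATION_SCALE:
        raise ValueError(f"magnification must be one of {sorted(MAGNIFICATION_SCALE)}")
    rng = np.random.default_rng(seed)
    scale = MAGNIFICATION_SCALE[magnification]

    n = int(rng.integers(spec.nucleus_count_range[0], spec.nucleus_count_range[1] + 1))
    r_lo, r_hi = spec.nucleus_radius_range
    row_lo, row_hi, col_lo, col_hi = _quadrant_box(spec.signal_quadrant, h, w)

    mask = np.zeros((h, w), dtype=bool)
    centers = np.empty((n, 2), dtype=float)
    if n > 0:
        # clustering pulls nuclei toward a few shared attractor points
        n_clusters = max(1, int(round(n * (1.0 - spec.clustering))))
        attract = np.column_stack([
            rng.uniform(row_lo, row_hi, n_clusters),
            rng.uniform(col_lo, col_hi, n_clusters),
        ])
        spread = (1.0 - spec.clustering) * min(row_hi - row_lo, col_hi - col_lo) / 4.0 + 2.0
        for i in range(n):
            cl = attract[int(rng.integers(n_clusters))]
            center = cl + rng.normal(0.0, spread, 2)
            center[0] = np.clip(center[0], row_lo, row_hi - 1e-9)
            center[1] = np.clip(center[1], col_lo, col_hi - 1e-9)
            centers[i] = center
            radius = rng.uniform(r_lo, r_hi) * scale
            ecc = rng.uniform(*spec.eccentricity_range)
            _render_nucleus(mask, rng, center, radius, ecc, spec.margin_irregularity)

    tex = _bandpass_noise(rng, (h, w), spec.texture_band)
    mask_f = mask.astype(float)
    # hematoxylin: strong in nuclei, faint in stroma; eosin: stroma texture
    c_h = spec.nucleus_stain * mask_f + 0.06 * spec.stroma_stain * tex
    c_e = spec.stroma_stain * (0.25 + 0.75 * tex) * (1.0 - 0.6 * mask_f)

    W = jitter_stain_matrix(rng, spec.stain_jitter, base=stain_matrix)
    od = c_h[..., None] * W[:, 0] + c_e[..., None] * W[:, 1]
    rgb = np.clip(np.rint(255.0 * np.exp(-od)), 0, 255).astype(np.uint8)

    patch = ImagePatch(pixels=rgb, label=spec.class_id, magnification=magnification)
    truth = GroundTruth(nucleus_centers=centers, nucleus_mask=mask,
                        signal_quadrant=spec.signal_quadrant)
    return patch, truth


@dataclass(frozen=True)
class DesignCell:
    """One cell of a dataset design: ``count`` images of one class at one
    magnification."""

    spec: ClassSpec
    count: int
    magnification: int = 40
    class_label: str | None = None     # defaults to spec.class_id
    subclass_label: str = ""

    @property
    def label(self) -> str:
        return self.class_label if self.class_label is not None else self.spec.class_id


def _write_manifest(records: list[dict], out_dir: Path) -> pd.DataFrame:
    manifest = pd.DataFrame(records, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"image_path": str, "class": str},
                     keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    return df


def generate_dataset(design: list[DesignCell], out_dir: str | Path, seed: int = 0,
                     size: tuple[int, int] = (96, 96),
                     images_per_patient: int = 5) -> pd.DataFrame:
    """Write PNG images plus a CSV manifest for a dataset design.

    Record counts per (class, magnification) cell match the design exactly;
    identical seeds reproduce bit-identical files.  Synthetic patient IDs
    cycle every ``images_per_patient`` images within a cell.
    """
    if not design:
        raise ValueError("design must be non-empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    records = []
    for ci, cell in enumerate(design):
        sub_dir = out_dir / cell.label / f"{cell.magnification}x"
        sub_dir.mkdir(parents=True, exist_ok=True)
        for i in range(cell.count):
            img_seed = int(master.integers(2 ** 31))
            patch, _ = generate_image(cell.spec, size=size, seed=img_seed,
                                      magnification=cell.magnification)
            name = f"{cell.label}_{cell.magnification}x_{i:04d}.png"
            path = sub_dir / name
            Image.fromarray(patch.pixels).save(path)
            records.append({
                "image_path": str(path.relative_to(out_dir)),
                "class": cell.label,
                "subclass": cell.subclass_label or cell.spec.class_id,
                "magnification": cell.magnification,
                "patient_id": f"P{ci:02d}_{i // images_per_patient:03d}",
                "split_tag": "",
            })
    manifest = _write_manifest(records, out_dir)
    sidecar = {
        "seed": int(seed),
        "size": [int(size[0]), int(size[1])],
        "cells": [
            {"class": c.label, "subclass": c.subclass_label or c.spec.class_id,
             "magnification": c.magnification, "count": c.count,
             "spec": asdict(c.spec)}
            for c in design
        ],
    }
    (out_dir / "generator_params.json").write_text(json.dumps(sidecar, indent=2))
    return manifest


def generate_kimia_fixture(out_dir: str | Path, seed: int = 0,
                           per_class: int = 48,
                           size: tuple[int, int] = (168, 308)) -> pd.DataFrame:
    """A 20-class texture-patch fixture: classes A-T, 48 patches each of
    308 x 168 pixels (width x height), PNG format."""
    design = [
        DesignCell(spec=s, count=per_class, magnification=40)
        for s in kimia_class_specs().values()
    ]
    return generate_dataset(design, out_dir, seed=seed, size=size)
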