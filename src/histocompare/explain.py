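"""Visual explanation: 2-D PCA/KPCA feature embeddings and Grad-CAM heatmaps.

Two complementary views explain the classifiers' behavior.  Embedding the
550-d handcrafted or 4096-d deep feature vectors into 2-D (PCA, or kernel
PCA with linear/polynomial/rbf/sigmoid kernels) shows how separable the
classes are in each representation.  Grad-CAM shows *where* the network
looks: the class-score gradient at the last convolutional layer is averaged
spatially into per-map weights alpha_k, the weighted rectified sum
relu(sum_k alpha_k A_k) is upsampled to the input size and min-max
normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from sklearn.decomposition import PCA, KernelPCA
from skimage.transform import resize as _sk_resize

__all__ = [
    "Embedding2D",
    "Heatmap",
    "pca_2d",
    "kpca_2d",
    "grad_cam",
    "overlay",
    "plot_embedding",
]

KPCA_KERNELS = ("linear", "poly", "rbf", "sigmoid")


@dataclass
class Embedding2D:
    """A 2-D embedding of an (n, p) feature matrix."""

    points: np.ndarray                      # (n, 2)
    method: str                             # pca | kpca-<kernel>
    explained_variance: np.ndarray | None   # (2,) for pca, else None
    labels: np.ndarray | None = None


@dataclass
class Heatmap:
    """Per-pixel relevance in [0, 1], aligned to the input image."""

    values: np.ndarray           # (H, W) floats in [0, 1]
    target_class: object
    source_layer: str = "last_conv"


def _check_features(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError(f"need an (n >= 3, p >= 2) matrix, got {X.shape}")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    return X


def pca_2d(features, labels=None) -> Embedding2D:
    """Mean-centered projection onto the top-2 covariance eigenvectors.

    Component signs follow the convention that each component's
    largest-magnitude loading is positive, so plots are reproducible.
    """
    X = _check_features(features)
    if np.allclose(X, X[0], atol=1e-12):
        raise ValueError("rank-0 input: all rows identical")
    p = PCA(n_components=2, svd_solver="full").fit(X)
    return Embedding2D(points=p.transform(X), method="pca",
                       explained_variance=p.explained_variance_.copy(),
                       labels=None if labels is None else np.asarray(labels))


def kpca_2d(features, kernel: str = "rbf", gamma: float | None = None,
            degree: int = 3, coef0: float = 1.0, labels=None) -> Embedding2D:
    """Kernel PCA embedding (double-centered kernel eigendecomposition).

    gamma defaults to 1/p for rbf and sigmoid.  With the linear kernel the
    embedding equals :func:`pca_2d` up to per-component sign.
    """
    X = _check_features(features)
    if kernel not in KPCA_KERNELS:
        raise ValueError(f"kernel must be one of {KPCA_KERNELS}, got {kernel!r}")
    kp = KernelPCA(n_components=2, kernel=kernel, gamma=gamma, degree=degree,
                   coef0=coef0, eigen_solver="dense")
    try:
        pts = kp.fit_transform(X)
    except np.linalg.LinAlgError as err:  # pragma: no cover - rare numeric failure
        raise ValueError(f"kernel eigendecomposition failed: {err}") from err
    if kp.eigenvalues_.min() < -1e-8 * max(kp.eigenvalues_.max(), 1.0):
        raise ValueError(
            f"kernel matrix not numerically PSD (eigenvalues {kp.eigenvalues_})")
    return Embedding2D(points=pts, method=f"kpca-{kernel}",
                       explained_variance=None,
                       labels=None if labels is None else np.asarray(labels))


def grad_cam(network, image, target_class, class_names=None,
             upsample: str = "bilinear") -> Heatmap:
    """Class-discriminative heatmap from the last convolutional layer.

    ``network`` must expose ``last_conv_activation_and_gradient(x, idx)``
    (see :class:`histocompare.deep.VGG19Network`) and ``input_size``.
    ``image`` is (H, W, 3) uint8 at the network's input size;
    ``target_class`` is either an integer class index or a label resolved
    through ``class_names``.
    """
    from .deep import preprocess_images

    px = image.pixels if hasattr(image, "pixels") else np.asarray(image)
    if class_names is not None and not isinstance(target_class, (int, np.integer)):
        if target_class not in class_names:
            raise ValueError(f"unknown class {target_class!r}")
        idx = list(class_names).index(target_class)
    else:
        idx = int(target_class)
    x = preprocess_images(px[None], getattr(network, "input_stats", None))[0]
    A, dA = network.last_conv_activation_and_gradient(x, idx)
    alpha = dA.mean(axis=(1, 2))                       # per-map weights
    raw = np.maximum((alpha[:, None, None] * A).sum(axis=0), 0.0)
    order = 1 if upsample == "bilinear" else 0
    up = _sk_resize(raw.astype(float), px.shape[:2], order=order,
                    preserve_range=True, anti_aliasing=False)
    up = np.maximum(up, 0.0)
    m = up.max()
    values = up / m if m > 0 else np.zeros_like(up)
    return Heatmap(values=values, target_class=target_class)


def overlay(heatmap: Heatmap | np.ndarray, image, colormap: str = "jet",
            alpha: float = 0.5) -> np.ndarray:
    """Blend a blue-to-red colormap of the heatmap over the image."""
    values = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    px = image.pixels if hasattr(image, "pixels") else np.asarray(image)
    if values.shape != px.shape[:2]:
        raise ValueError(
            f"heatmap {values.shape} does not align with image {px.shape[:2]}")
    cmap = colormaps[colormap]
    heat_rgb = cmap(np.clip(values, 0.0, 1.0))[..., :3] * 255.0
    out = (1.0 - alpha) * px.astype(float) + alpha * heat_rgb
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def plot_embedding(embedding: Embedding2D, path=None, title: str | None = None):
    """Scatter plot of a 2-D embedding colored by label; returns the figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    pts = embedding.points
    if embedding.labels is None:
        ax.scatter(pts[:, 0], pts[:, 1], s=12)
    else:
        for lab in np.unique(embedding.labels):
            sel = embedding.labels == lab
            ax.scatter(pts[sel, 0], pts[sel, 1], s=12, label=str(lab))
        ax.legend(fontsize=7, markerscale=1.2)
    ax.set_xlabel("component 1")
    ax.set_ylabel("component 2")
    ax.set_title(title or embedding.method)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
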