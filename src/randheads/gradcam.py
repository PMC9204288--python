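"""Gradient-weighted class activation maps over the feature extractor.

The map is tapped at the last convolutional layer of the backbone: each
channel's weight is the spatial mean of the class-score gradient over
that channel, the weighted channel sum is rectified, min-max normalised
to [0, 1] (an identically-zero raw map stays zero) and bilinearly
upsampled to the requested size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .features import _BN_EPS, FeatureExtractor, preprocess

__all__ = ["CamHeatmap", "grad_cam", "extractor_cam", "save_heatmap_tsv", "save_overlay_png"]


@dataclass(frozen=True)
class CamHeatmap:
    """Per-image attention map with values in [0, 1]."""

    values: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("heatmap must be 2-D")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("heatmap values must lie in [0, 1]")
        object.__setattr__(self, "values", v)


def grad_cam(activations: np.ndarray, gradients: np.ndarray,
             target_size: tuple[int, int], image_id: str = "") -> CamHeatmap:
    """Build a CAM from channel activations and class-score gradients.

    activations, gradients: C x h x w arrays of matching shape.
    """
    A = np.asarray(activations, dtype=float)
    G = np.asarray(gradients, dtype=float)
    if A.shape != G.shape or A.ndim != 3 or A.shape[0] < 1:
        raise ValueError(f"activations {A.shape} and gradients {G.shape} must be matching C x h x w")
    alphas = G.mean(axis=(1, 2))
    raw = np.maximum(np.tensordot(alphas, A, axes=1), 0.0)
    peak = raw.max()
    if peak > 0:
        raw = raw / peak
    if raw.shape != tuple(target_size):
        raw = _sk_resize(raw, target_size, order=1, mode="reflect", anti_aliasing=False)
        raw = np.clip(raw, 0.0, 1.0)
    return CamHeatmap(values=raw, image_id=image_id)


def extractor_cam(extractor: FeatureExtractor, image: np.ndarray,
                  target_class: int | None = None, image_id: str = "") -> CamHeatmap:
    """Grad-CAM of one image through the toy extractor.

    Gradients are taken for ``target_class`` (default: the predicted
    class) with respect to the backbone's ReLU'd convolution maps, and
    the heatmap is returned at the input image's resolution.
    """
    b = extractor.backbone
    img = np.asarray(image, dtype=float)
    A = b.conv_maps(img)                      # C x s x s
    pooled = b.pool_maps(A)
    f = pooled.ravel()
    inv_trunk_sd = None
    if extractor.trunk_mean is not None:
        inv_trunk_sd = 1.0 / extractor.trunk_sd
        f = (f - extractor.trunk_mean) * inv_trunk_sd

    z1 = f @ extractor.W1 + extractor.b1
    r = np.maximum(z1, 0.0)
    inv_std = 1.0 / np.sqrt(extractor.run_var + _BN_EPS)
    hb = extractor.gamma * (r - extractor.run_mean) * inv_std + extractor.beta
    logits = hb @ extractor.W2 + extractor.b2
    k = int(np.argmax(logits)) if target_class is None else int(target_class)
    if not 0 <= k < logits.size:
        raise ValueError(f"target class {k} out of range")

    # backprop d logits[k] / d A through the (eval-mode) head and pooling
    dhb = extractor.W2[:, k]
    dr = dhb * extractor.gamma * inv_std
    dz1 = dr * (z1 > 0)
    df = extractor.W1 @ dz1
    if inv_trunk_sd is not None:
        df = df * inv_trunk_sd
    d_pooled = df.reshape(pooled.shape)
    dA = b.unpool_gradient(d_pooled)

    return grad_cam(A, dA, target_size=img.shape, image_id=image_id)


def save_heatmap_tsv(heatmap: CamHeatmap, path) -> None:
    """Write the raw heatmap matrix as TSV."""
    np.savetxt(path, heatmap.values, delimiter="\t", fmt="%.6f")


def save_overlay_png(heatmap: CamHeatmap, image: np.ndarray, path,
                     alpha: float = 0.45, size: int | None = None) -> None:
    """Save a jet-colormap overlay of the heatmap on the grayscale image."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    from matplotlib import cm
    from PIL import Image

    img = np.asarray(image, dtype=float)
    if size is not None:
        img = preprocess(img, size)
    hm = heatmap.values
    if hm.shape != img.shape:
        hm = np.clip(_sk_resize(hm, img.shape, order=1, mode="reflect",
                                anti_aliasing=False), 0.0, 1.0)
    base = np.stack([img] * 3, axis=-1)
    color = cm.jet(hm)[..., :3]
    blend = np.clip((1 - alpha) * base + alpha * color, 0.0, 1.0)
    Image.fromarray((blend * 255).astype(np.uint8)).save(path)
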