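"""Backbone contract and feature extraction.

The pipeline modifies a pretrained CNN by replacing its classifier with
the ordered head [FC128, ReLU, BatchNorm, FC2, softmax, classification],
fine-tunes it with cross-entropy, and taps the linear FC128 output as the
feature embedding that feeds the closed-form classifier heads.

Pretrained ImageNet backbones are an optional *external* dependency that
is not available in this build; the shipped backbone is
:class:`ToyConvBackbone`, a small frozen random convolution-pool network
that stands in for the pretrained feature trunk so the full pipeline is
exercisable on a laptop CPU.  Only the added head layers are trained when
fine-tuning on top of the toy trunk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "FineTuneConfig",
    "LabeledImageSet",
    "ToyConvBackbone",
    "FeatureExtractor",
    "build_modified_head",
    "builtin_toy_extractor",
    "fine_tune",
    "extract_features",
    "preprocess",
    "save_extractor",
    "load_extractor",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1
EMBED_DIM = 128
NUM_CLASSES = 2


@dataclass
class FineTuneConfig:
    """Hyper-parameters of the fine-tuning stage.

    The numeric defaults (mini-batch 10, 4 epochs, learning rate 1e-4,
    400 hidden nodes) are the reference settings of the method.
    """

    minibatch_size: int = 10
    max_epoch: int = 4
    learning_rate: float = 1e-4
    hidden_nodes_V: int = 400
    backbone_name: str = "toy"
    seed: int = 0
    momentum: float = 0.9
    image_size: int = 64  # internal working resolution of the toy backbone
    train_backbone: bool = False

    def validate(self) -> None:
        for name in ("minibatch_size", "max_epoch", "hidden_nodes_V", "image_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class LabeledImageSet:
    """Grayscale images with binary labels (1 = positive/unhealthy)."""

    images: list
    labels: np.ndarray
    ids: list
    lesion_masks: list | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.images) == self.labels.size == len(self.ids)):
            raise ValueError("images, labels and ids must have equal lengths")
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sample ids must be unique")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, indices) -> "LabeledImageSet":
        idx = np.asarray(indices, dtype=int)
        masks = None
        if self.lesion_masks is not None:
            masks = [self.lesion_masks[i] for i in idx]
        return LabeledImageSet(
            images=[self.images[i] for i in idx],
            labels=self.labels[idx],
            ids=[self.ids[i] for i in idx],
            lesion_masks=masks,
        )


def build_modified_head(num_features_in: int) -> list[dict]:
    """Ordered specification of the replacement head.

    Returns the six-layer list [FC128, ReLU, BatchNorm, FC2, softmax,
    classification]; the FC128 output (index 0) is the feature tap.
    """
    if num_features_in < 1:
        raise ValueError(f"num_features_in must be >= 1, got {num_features_in}")
    return [
        {"layer": "fc", "in": int(num_features_in), "out": EMBED_DIM, "feature_tap": True},
        {"layer": "relu"},
        {"layer": "batchnorm", "dim": EMBED_DIM},
        {"layer": "fc", "in": EMBED_DIM, "out": NUM_CLASSES},
        {"layer": "softmax"},
        {"layer": "classification"},
    ]


def preprocess(image: np.ndarray, size: int) -> np.ndarray:
    """Resize to size x size (bilinear) and clip to [0, 1]; idempotent."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("images must be 2-D grayscale arrays")
    if img.shape != (size, size):
        img = _sk_resize(img, (size, size), order=1, mode="reflect", anti_aliasing=False)
    return np.clip(img, 0.0, 1.0)


class ToyConvBackbone:
    """Frozen random convolution-pool trunk standing in for a pretrained CNN.

    One valid 5x5 convolution bank (ReLU) followed by average pooling.
    Filters are zero-mean random with a small positive DC component so
    bright structures raise activations.  Deterministic per seed.
    """

    name = "toy"

    def __init__(self, seed: int, in_size: int = 64, channels: int = 8,
                 kernel: int = 5, pool: int = 4):
        if (in_size - kernel + 1) % pool != 0:
            raise ValueError("conv output size must be divisible by the pool factor")
        self.seed = int(seed)
        self.in_size = in_size
        self.channels = channels
        self.kernel = kernel
        self.pool = pool
        rng = np.random.default_rng(seed)
        filt = rng.normal(0.0, 1.0, size=(channels, kernel, kernel))
        filt -= filt.mean(axis=(1, 2), keepdims=True)
        filt += 0.5 / kernel**2
        self.filters = filt / kernel

    @property
    def conv_size(self) -> int:
        return self.in_size - self.kernel + 1

    @property
    def pooled_size(self) -> int:
        return self.conv_size // self.pool

    @property
    def out_dim(self) -> int:
        return self.channels * self.pooled_size**2

    def conv_maps(self, image: np.ndarray) -> np.ndarray:
        """ReLU'd convolution maps, shape (channels, conv_size, conv_size)."""
        img = preprocess(image, self.in_size)
        win = np.lib.stride_tricks.sliding_window_view(img, (self.kernel, self.kernel))
        maps = np.einsum("xykl,ckl->cxy", win, self.filters)
        return np.maximum(maps, 0.0)

    def pool_maps(self, maps: np.ndarray) -> np.ndarray:
        c, s, p = self.channels, self.conv_size, self.pool
        return maps.reshape(c, s // p, p, s // p, p).mean(axis=(2, 4))

    def features(self, image: np.ndarray) -> np.ndarray:
        return self.pool_maps(self.conv_maps(image)).ravel()

    def unpool_gradient(self, grad_pooled: np.ndarray) -> np.ndarray:
        """Distribute a pooled-map gradient back over the conv map."""
        p = self.pool
        g = np.repeat(np.repeat(grad_pooled, p, axis=1), p, axis=2)
        return g / p**2


@dataclass
class FeatureExtractor:
    """Backbone + modified head, tapped at the linear FC128 output.

    ``embed`` returns the 128-dimensional FC128 activation (pre-ReLU), so
    the extracted features are by construction independent of every layer
    after the tap.
    """

    backbone: ToyConvBackbone
    W1: np.ndarray
    b1: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray
    run_mean: np.ndarray
    run_var: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    # trunk-output standardisation fitted on the training set (None = identity)
    trunk_mean: np.ndarray | None = None
    trunk_sd: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def embed_dim(self) -> int:
        return self.W1.shape[1]

    def _trunk(self, image: np.ndarray) -> np.ndarray:
        f = self.backbone.features(image)
        if self.trunk_mean is not None:
            f = (f - self.trunk_mean) / self.trunk_sd
        return f

    def embed(self, image: np.ndarray) -> np.ndarray:
        """Length-128 feature vector of one image (FC128 linear output)."""
        return self._trunk(image) @ self.W1 + self.b1

    def head_logits(self, z1: np.ndarray) -> np.ndarray:
        """Post-tap head in inference mode: ReLU -> BN(running stats) -> FC2."""
        r = np.maximum(z1, 0.0)
        hb = self.gamma * (r - self.run_mean) / np.sqrt(self.run_var + _BN_EPS) + self.beta
        return hb @ self.W2 + self.b2

    def class_scores(self, image: np.ndarray) -> np.ndarray:
        """Softmax class probabilities for one image."""
        logits = self.head_logits(self.embed(image))
        e = np.exp(logits - logits.max())
        return e / e.sum()


def builtin_toy_extractor(seed: int) -> FeatureExtractor:
    """Desk-scale extractor with a frozen random trunk and a random head.

    Exists so every downstream module is testable without pretrained
    weights or a GPU; :func:`fine_tune` starts from the same construction.
    """
    backbone = ToyConvBackbone(seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    D = backbone.out_dim
    return FeatureExtractor(
        backbone=backbone,
        W1=rng.normal(0.0, np.sqrt(2.0 / D), size=(D, EMBED_DIM)),
        b1=np.zeros(EMBED_DIM),
        gamma=np.ones(EMBED_DIM),
        beta=np.zeros(EMBED_DIM),
        run_mean=np.zeros(EMBED_DIM),
        run_var=np.ones(EMBED_DIM),
        W2=rng.normal(0.0, np.sqrt(2.0 / EMBED_DIM), size=(EMBED_DIM, NUM_CLASSES)),
        b2=np.zeros(NUM_CLASSES),
        metadata={"backbone": "toy", "seed": int(seed), "fine_tuned": False},
    )


def _softmax_rows(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def fine_tune(extractor_backbone, data: LabeledImageSet, cfg: FineTuneConfig) -> FeatureExtractor:
    """Fine-tune the modified head with cross-entropy SGD and return the extractor.

    ``extractor_backbone`` may be None (a toy trunk is built from
    ``cfg.seed``), a :class:`ToyConvBackbone`, or a backbone name string.
    The toy trunk is a frozen stand-in, so only the added head layers
    (FC128, BN, FC2) receive gradient updates; requesting
    ``train_backbone=True`` on the toy trunk is rejected.
    """
    cfg.validate()
    if len(data) == 0:
        raise ValueError("empty training set")
    classes = np.unique(data.labels)
    if classes.size < 2:
        raise ValueError("fine-tuning requires at least one sample of each class")

    if extractor_backbone is None or (isinstance(extractor_backbone, str)
                                      and extractor_backbone == "toy"):
        backbone = ToyConvBackbone(cfg.seed, in_size=cfg.image_size)
    elif isinstance(extractor_backbone, ToyConvBackbone):
        backbone = extractor_backbone
    else:
        raise NotImplementedError(
            f"backbone {extractor_backbone!r} requires pretrained weights that are "
            "not bundled; only the built-in 'toy' backbone is available here"
        )
    if cfg.train_backbone:
        raise NotImplementedError("the toy trunk is frozen; only the head is trainable")

    F0 = np.stack([backbone.features(img) for img in data.images])
    # standardise the frozen trunk output on the training set; the statistics
    # become part of the extractor (applied identically at inference)
    trunk_mean = F0.mean(axis=0)
    trunk_sd = F0.std(axis=0)
    trunk_sd[trunk_sd == 0] = 1.0
    F0 = (F0 - trunk_mean) / trunk_sd
    y = data.labels
    N, D = F0.shape

    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x5EED]))
    W1 = rng.normal(0.0, np.sqrt(2.0 / D), size=(D, EMBED_DIM))
    b1 = np.zeros(EMBED_DIM)
    gamma = np.ones(EMBED_DIM)
    beta = np.zeros(EMBED_DIM)
    W2 = rng.normal(0.0, np.sqrt(2.0 / EMBED_DIM), size=(EMBED_DIM, NUM_CLASSES))
    b2 = np.zeros(NUM_CLASSES)
    run_mean = np.zeros(EMBED_DIM)
    run_var = np.ones(EMBED_DIM)
    vel = {k: 0.0 for k in ("W1", "b1", "gamma", "beta", "W2", "b2")}

    onehot = np.zeros((N, NUM_CLASSES))
    onehot[np.arange(N), y] = 1.0
    lr, mom = cfg.learning_rate, cfg.momentum
    loss_history = []

    for _ in range(cfg.max_epoch):
        order = rng.permutation(N)
        epoch_losses = []
        for start in range(0, N, cfg.minibatch_size):
            idx = order[start:start + cfg.minibatch_size]
            Fb, Tb = F0[idx], onehot[idx]
            B = len(idx)

            z1 = Fb @ W1 + b1
            r = np.maximum(z1, 0.0)
            mu = r.mean(axis=0)
            var = r.var(axis=0)
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            rhat = (r - mu) * inv_std
            hb = gamma * rhat + beta
            logits = hb @ W2 + b2
            p = _softmax_rows(logits)
            epoch_losses.append(float(-np.mean(np.log(np.sum(p * Tb, axis=1) + 1e-300))))

            run_mean = (1 - _BN_MOMENTUM) * run_mean + _BN_MOMENTUM * mu
            run_var = (1 - _BN_MOMENTUM) * run_var + _BN_MOMENTUM * var

            dlogits = (p - Tb) / B
            grads = {
                "W2": hb.T @ dlogits,
                "b2": dlogits.sum(axis=0),
            }
            dhb = dlogits @ W2.T
            grads["gamma"] = (dhb * rhat).sum(axis=0)
            grads["beta"] = dhb.sum(axis=0)
            drhat = dhb * gamma
            dr = (inv_std / B) * (B * drhat - drhat.sum(axis=0)
                                  - rhat * (drhat * rhat).sum(axis=0))
            dz1 = dr * (z1 > 0)
            grads["W1"] = Fb.T @ dz1
            grads["b1"] = dz1.sum(axis=0)

            params = {"W1": W1, "b1": b1, "gamma": gamma, "beta": beta, "W2": W2, "b2": b2}
            for k, g in grads.items():
                vel[k] = mom * vel[k] - lr * g
                params[k] += vel[k]
        loss_history.append(float(np.mean(epoch_losses)))

    return FeatureExtractor(
        backbone=backbone, W1=W1, b1=b1, gamma=gamma, beta=beta,
        run_mean=run_mean, run_var=run_var, W2=W2, b2=b2,
        trunk_mean=trunk_mean, trunk_sd=trunk_sd,
        metadata={
            "backbone": backbone.name,
            "seed": int(cfg.seed),
            "fine_tuned": True,
            "loss_history": loss_history,
            "epochs": cfg.max_epoch,
        },
    )


def extract_features(extractor: FeatureExtractor, data: LabeledImageSet) -> np.ndarray:
    """N x 128 feature matrix, one row per image in dataset order."""
    if len(data) == 0:
        raise ValueError("empty dataset")
    F = np.stack([extractor.embed(img) for img in data.images])
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite features extracted")
    return F


def save_extractor(extractor: FeatureExtractor, path) -> None:
    """Serialize an extractor as named arrays plus JSON metadata."""
    b = extractor.backbone
    meta = dict(extractor.metadata)
    meta.update(in_size=b.in_size, channels=b.channels, kernel=b.kernel,
                pool=b.pool, backbone_seed=b.seed)
    arrays = dict(
        filters=b.filters,
        W1=extractor.W1, b1=extractor.b1, gamma=extractor.gamma, beta=extractor.beta,
        run_mean=extractor.run_mean, run_var=extractor.run_var,
        W2=extractor.W2, b2=extractor.b2,
    )
    if extractor.trunk_mean is not None:
        arrays.update(trunk_mean=extractor.trunk_mean, trunk_sd=extractor.trunk_sd)
    np.savez(path, meta=np.asarray(json.dumps(meta)), **arrays)


def load_extractor(path) -> FeatureExtractor:
    """Load an extractor saved by :func:`save_extractor`."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        backbone = ToyConvBackbone(
            meta["backbone_seed"], in_size=meta["in_size"], channels=meta["channels"],
            kernel=meta["kernel"], pool=meta["pool"],
        )
        backbone.filters = np.array(z["filters"])
        return FeatureExtractor(
            backbone=backbone, W1=z["W1"], b1=z["b1"], gamma=z["gamma"], beta=z["beta"],
            run_mean=z["run_mean"], run_var=z["run_var"], W2=z["W2"], b2=z["b2"],
            trunk_mean=z["trunk_mean"] if "trunk_mean" in z else None,
            trunk_sd=z["trunk_sd"] if "trunk_sd" in z else None,
            metadata={k: v for k, v in meta.items()
                      if k not in ("in_size", "channels", "kernel", "pool", "backbone_seed")},
        )
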