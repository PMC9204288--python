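"""Closed-form randomized neural-network classifier heads.

Three single-hidden-layer networks share a frozen random hidden layer
(weights and biases drawn once and never updated) and differ only in how
the output layer is wired:

* ``SNN``  -- hidden activations plus a trainable output *bias*, solved
  jointly by least squares on a ones-augmented design matrix.
* ``ELM``  -- hidden activations only; output weights are the
  Moore-Penrose pseudo-inverse of the activation matrix times the targets.
* ``RVFL`` -- hidden activations concatenated with direct (shortcut)
  links from the raw inputs.

All three are trained in closed form: the output weights are the
minimum-norm least-squares solution obtained from an SVD-based
pseudo-inverse (relative singular-value cutoff ``1e-12``), optionally
regularised by a ridge term for ill-conditioned inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

__all__ = [
    "FeatureMatrix",
    "TargetMatrix",
    "RandomHiddenLayer",
    "SnnModel",
    "ElmModel",
    "RvflModel",
    "make_hidden_layer",
    "hidden_output",
    "train_snn",
    "train_elm",
    "train_rvfl",
    "predict",
    "save_model",
    "load_model",
    "sigmoid",
]

#: relative singular-value cutoff for the pseudo-inverse
PINV_RCOND = 1e-12


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function 1 / (1 + exp(-z))."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _freeze(a: np.ndarray) -> np.ndarray:
    a = np.array(a, dtype=float, copy=True)
    a.flags.writeable = False
    return a


@dataclass(frozen=True)
class FeatureMatrix:
    """N x n real feature matrix; rows are samples."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"feature matrix must be 2-D, got ndim={v.ndim}")
        if v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError(f"feature matrix must be at least 1x1, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature matrix contains non-finite entries")
        object.__setattr__(self, "values", _freeze(v))

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class TargetMatrix:
    """N x m real target matrix.

    For classification the rows are one-hot, but arbitrary finite real
    targets are accepted (the closed-form solvers are plain least squares).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError(f"target matrix must be 2-D and nonempty, got shape {np.shape(v)}")
        if not np.all(np.isfinite(v)):
            raise ValueError("target matrix contains non-finite entries")
        object.__setattr__(self, "values", _freeze(v))

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_labels(cls, labels: Sequence[int], m: int | None = None) -> "TargetMatrix":
        """One-hot encode integer class labels into an N x m target matrix."""
        lab = np.asarray(labels, dtype=int)
        if lab.ndim != 1 or lab.size < 1:
            raise ValueError("labels must be a nonempty 1-D sequence")
        if m is None:
            m = int(lab.max()) + 1
        if np.any(lab < 0) or np.any(lab >= m):
            raise ValueError(f"labels out of range for m={m}")
        Y = np.zeros((lab.size, m))
        Y[np.arange(lab.size), lab] = 1.0
        return cls(Y)


@dataclass(frozen=True)
class RandomHiddenLayer:
    """Frozen random hidden layer: weights W (V x n), biases d (V,), sigmoid activation."""

    W: np.ndarray
    d: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        d = np.asarray(self.d, dtype=float)
        if W.ndim != 2 or d.ndim != 1 or W.shape[0] != d.shape[0]:
            raise ValueError("inconsistent hidden-layer shapes")
        if W.shape[0] < 1 or W.shape[1] < 1:
            raise ValueError("hidden layer needs V >= 1 and n >= 1")
        object.__setattr__(self, "W", _freeze(W))
        object.__setattr__(self, "d", _freeze(d))

    @property
    def V(self) -> int:
        return self.W.shape[0]

    @property
    def n_in(self) -> int:
        return self.W.shape[1]


@dataclass(frozen=True)
class SnnModel:
    """Schmidt network: output weights P (V x m) and output bias q (m,)."""

    hidden: RandomHiddenLayer
    P: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        q = np.asarray(self.q, dtype=float)
        if P.ndim != 2 or P.shape[0] != self.hidden.V or q.shape != (P.shape[1],):
            raise ValueError("inconsistent SNN output-layer shapes")
        object.__setattr__(self, "P", _freeze(P))
        object.__setattr__(self, "q", _freeze(q))

    @property
    def m(self) -> int:
        return self.P.shape[1]


@dataclass(frozen=True)
class ElmModel:
    """ELM: output weights P (V x m), no output bias."""

    hidden: RandomHiddenLayer
    P: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or P.shape[0] != self.hidden.V:
            raise ValueError("inconsistent ELM output-layer shapes")
        object.__setattr__(self, "P", _freeze(P))

    @property
    def m(self) -> int:
        return self.P.shape[1]


@dataclass(frozen=True)
class RvflModel:
    """RVFL: output weights p ((n + V) x m); the first n rows multiply the direct input links."""

    hidden: RandomHiddenLayer
    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 2 or p.shape[0] != self.hidden.n_in + self.hidden.V:
            raise ValueError("inconsistent RVFL output-layer shapes")
        object.__setattr__(self, "p", _freeze(p))

    @property
    def m(self) -> int:
        return self.p.shape[1]


AnyHeadModel = Union[SnnModel, ElmModel, RvflModel]


def make_hidden_layer(n: int, V: int, seed: int) -> RandomHiddenLayer:
    """Draw a frozen random hidden layer.

    Entries of W and d are i.i.d. uniform on [-1, 1] from a generator
    seeded by ``seed``; the same seed always yields bit-identical values.
    """
    if n < 1:
        raise ValueError(f"input dimension n must be >= 1, got {n}")
    if V < 1:
        raise ValueError(f"hidden-node count V must be >= 1, got {V}")
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(V, n))
    d = rng.uniform(-1.0, 1.0, size=V)
    return RandomHiddenLayer(W=W, d=d, seed=int(seed))


def _as_features(X) -> FeatureMatrix:
    return X if isinstance(X, FeatureMatrix) else FeatureMatrix(np.asarray(X))


def _as_targets(Y) -> TargetMatrix:
    return Y if isinstance(Y, TargetMatrix) else TargetMatrix(np.asarray(Y))


def hidden_output(layer: RandomHiddenLayer, X) -> np.ndarray:
    """Hidden activation matrix: entry (i, j) = sigmoid(w_j . x_i + d_j)."""
    Xm = _as_features(X)
    if Xm.n != layer.n_in:
        raise ValueError(f"feature dimension {Xm.n} != hidden-layer input dimension {layer.n_in}")
    return sigmoid(Xm.values @ layer.W.T + layer.d)


def _solve_output_weights(A: np.ndarray, Y: np.ndarray, ridge: float) -> np.ndarray:
    """Minimum-norm least-squares solution of A beta = Y (or its ridge variant)."""
    if ridge > 0.0:
        G = A.T @ A + ridge * np.eye(A.shape[1])
        return np.linalg.solve(G, A.T @ Y)
    return np.linalg.pinv(A, rcond=PINV_RCOND) @ Y


def _check_pair(X, Y, layer: RandomHiddenLayer) -> tuple[FeatureMatrix, TargetMatrix]:
    Xm, Ym = _as_features(X), _as_targets(Y)
    if Xm.N != Ym.N:
        raise ValueError(f"X has {Xm.N} rows but Y has {Ym.N}")
    if Xm.n != layer.n_in:
        raise ValueError(f"feature dimension {Xm.n} != hidden-layer input dimension {layer.n_in}")
    return Xm, Ym


def train_snn(X, Y, layer: RandomHiddenLayer, ridge: float = 0.0) -> SnnModel:
    """Fit the Schmidt head: (P, q) jointly minimise ||[A | 1] [P; q] - Y||_F."""
    Xm, Ym = _check_pair(X, Y, layer)
    A = hidden_output(layer, Xm)
    A_aug = np.hstack([A, np.ones((Xm.N, 1))])
    beta = _solve_output_weights(A_aug, Ym.values, ridge)
    return SnnModel(hidden=layer, P=beta[:-1], q=beta[-1])


def train_elm(X, Y, layer: RandomHiddenLayer, ridge: float = 0.0) -> ElmModel:
    """Fit the ELM head: P = pinv(A) Y on the hidden activation matrix alone."""
    Xm, Ym = _check_pair(X, Y, layer)
    A = hidden_output(layer, Xm)
    return ElmModel(hidden=layer, P=_solve_output_weights(A, Ym.values, ridge))


def train_rvfl(X, Y, layer: RandomHiddenLayer, ridge: float = 0.0,
               include_bias: bool = False) -> RvflModel:
    """Fit the RVFL head on the direct-link design matrix [X | K].

    ``include_bias`` appends a ones column (off by default: the design
    matrix is the plain concatenation of inputs and hidden activations).
    """
    Xm, Ym = _check_pair(X, Y, layer)
    K = hidden_output(layer, Xm)
    cols = [Xm.values, K]
    if include_bias:
        cols.append(np.ones((Xm.N, 1)))
    A = np.hstack(cols)
    p = _solve_output_weights(A, Ym.values, ridge)
    if include_bias:
        # fold the learned bias into an RVFL model by storing it separately is
        # not supported; keep the augmented weight matrix shape contract instead
        raise_if = p.shape[0] != Xm.n + layer.V + 1
        if raise_if:
            raise AssertionError("unexpected solution shape")
        model = RvflModel(hidden=layer, p=p[:-1])
        object.__setattr__(model, "_bias", p[-1].copy())
        return model
    return RvflModel(hidden=layer, p=p)


def design_matrix(model: AnyHeadModel, X) -> np.ndarray:
    """Design matrix the model's output weights multiply, for features X."""
    if isinstance(model, (SnnModel, ElmModel)):
        return hidden_output(model.hidden, X)
    if isinstance(model, RvflModel):
        Xm = _as_features(X)
        return np.hstack([Xm.values, hidden_output(model.hidden, Xm)])
    raise TypeError(f"unknown model type {type(model).__name__}")


def predict(model: AnyHeadModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Scores (N x m) and argmax class labels; ties break toward the lowest index."""
    Xm = _as_features(X)
    if Xm.n != model.hidden.n_in:
        raise ValueError(f"feature dimension {Xm.n} != model input dimension {model.hidden.n_in}")
    A = design_matrix(model, Xm)
    if isinstance(model, SnnModel):
        scores = A @ model.P + model.q
    elif isinstance(model, ElmModel):
        scores = A @ model.P
    else:
        scores = A @ model.p
        bias = getattr(model, "_bias", None)
        if bias is not None:
            scores = scores + bias
    return scores, np.argmax(scores, axis=1)


_HEAD_KINDS = {SnnModel: "snn", ElmModel: "elm", RvflModel: "rvfl"}


def save_model(model: AnyHeadModel, path) -> None:
    """Serialize a head model as an archive of named arrays plus JSON metadata."""
    kind = _HEAD_KINDS[type(model)]
    meta = {
        "kind": kind,
        "n": model.hidden.n_in,
        "V": model.hidden.V,
        "m": model.m,
        "seed": model.hidden.seed,
    }
    arrays = {"W": model.hidden.W, "d": model.hidden.d}
    if isinstance(model, SnnModel):
        arrays.update(P=model.P, q=model.q)
    elif isinstance(model, ElmModel):
        arrays.update(P=model.P)
    else:
        arrays.update(p=model.p)
    np.savez(path, meta=np.asarray(json.dumps(meta)), **arrays)


def load_model(path) -> AnyHeadModel:
    """Load a head model saved by :func:`save_model`."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        layer = RandomHiddenLayer(W=z["W"], d=z["d"], seed=int(meta["seed"]))
        if meta["kind"] == "snn":
            return SnnModel(hidden=layer, P=z["P"], q=z["q"])
        if meta["kind"] == "elm":
            return ElmModel(hidden=layer, P=z["P"])
        if meta["kind"] == "rvfl":
            return RvflModel(hidden=layer, p=z["p"])
    raise ValueError(f"unknown head kind {meta['kind']!r}")
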