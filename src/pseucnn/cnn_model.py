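"""A compact convolutional network over DFT amplitude features.

Architecture: the 1-D feature vector is mapped onto a square
reshape_dim × reshape_dim grid — either through a learnable linear
projection (default) or by zero-padding to reshape_dim² and reshaping
row-major — then a single valid 2-D convolution with a square kernel,
2×2 max pooling (stride 2, no padding; skipped when the convolved side
is 1), and a dynamically sized fully connected stack whose depth and
width are hyperparameters, each dense layer followed by 30% dropout.
A 2-unit softmax head outputs the class probability distribution.

Training is plain minibatch SGD with the Adam optimizer on the
cross-entropy loss, implemented in numpy with explicit backpropagation.
One integer seed drives weight initialization, shuffling and dropout
masks, so training is bit-reproducible on a given platform.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Literal

import numpy as np

logger = logging.getLogger(__name__)

MappingMode = Literal["dense_projection", "zero_pad"]

DROPOUT_RATE = 0.30
_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


class ShapeError(ValueError):
    """A hyperparameter combination produces an impossible layer shape."""


class TrainingDivergedError(RuntimeError):
    """The training loss became non-finite."""


@dataclass(frozen=True)
class HyperParams:
    """The six architecture/training knobs tuned by random search.

    reshape_dim: side of the square grid the features are mapped onto.
    conv_kernel: side of the square convolution kernel.
    conv_stride: convolution stride.
    dense_layers / dense_units: depth and width of the dense stack.
    activation: "relu" or "selu", used after the convolution and in the
    dense stack.
    """

    reshape_dim: int = 8
    conv_kernel: int = 4
    conv_stride: int = 2
    dense_layers: int = 1
    dense_units: int = 32
    activation: str = "relu"

    def __post_init__(self) -> None:
        for name in ("reshape_dim", "conv_kernel", "conv_stride", "dense_layers", "dense_units"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        act = self.activation.lower()
        if act not in ("relu", "selu"):
            raise ValueError(f"activation must be 'relu' or 'selu', got {self.activation!r}")
        object.__setattr__(self, "activation", act)
        if self.conv_kernel > self.reshape_dim:
            raise ShapeError(
                f"conv_kernel {self.conv_kernel} exceeds reshape_dim {self.reshape_dim}"
            )


#: Best configurations found for the three benchmark training sets.
HUMAN_CONFIG = HyperParams(8, 5, 3, 2, 32, "selu")
YEAST_CONFIG = HyperParams(8, 4, 2, 1, 32, "relu")
MOUSE_CONFIG = HyperParams(8, 4, 2, 1, 32, "relu")


def conv_output_side(input_side: int, kernel: int, stride: int) -> int:
    """Output side of a valid convolution: floor((n - k)/s) + 1."""
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if kernel > input_side:
        raise ShapeError(f"kernel {kernel} exceeds input side {input_side}")
    return (input_side - kernel) // stride + 1


def map_input(
    features: np.ndarray,
    reshape_dim: int,
    mode: MappingMode = "zero_pad",
    projection: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Map 1-D feature vectors onto (reshape_dim, reshape_dim, 1) grids.

    zero_pad appends reshape_dim² - dim zeros and reshapes row-major
    (a 60-feature vector on an 8×8 grid gains exactly 4 zeros);
    dense_projection applies the learnable affine map ``projection``
    (weights of shape (dim, reshape_dim²), bias of shape (reshape_dim²,)).
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    n, dim = x.shape
    target = reshape_dim * reshape_dim
    if mode == "zero_pad":
        if target < dim:
            raise ShapeError(
                f"zero_pad: grid {reshape_dim}x{reshape_dim}={target} cannot hold "
                f"{dim} features"
            )
        padded = np.concatenate([x, np.zeros((n, target - dim))], axis=1)
        return padded.reshape(n, reshape_dim, reshape_dim, 1)
    if mode == "dense_projection":
        if projection is None:
            raise ValueError("dense_projection requires the learned (W, b) projection")
        w, b = projection
        if w.shape != (dim, target):
            raise ShapeError(f"projection weights {w.shape} != ({dim}, {target})")
        return (x @ w + b).reshape(n, reshape_dim, reshape_dim, 1)
    raise ValueError(f"unknown mapping mode {mode!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Fully resolved shapes of the network; construction is pure."""

    input_dim: int
    mode: str
    hp: HyperParams
    filters: int
    conv_side: int
    pooled: bool
    pool_side: int
    flat_dim: int
    dropout: float = DROPOUT_RATE

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        d["hp"] = HyperParams(**d["hp"])
        return cls(**d)


def build_model(
    hp: HyperParams,
    input_dim: int,
    filters: int = 16,
    mode: MappingMode = "dense_projection",
) -> ModelSpec:
    """Resolve every layer shape for a hyperparameter combination.

    Raises :class:`ShapeError` if the kernel exceeds the grid, the zero-pad
    grid is too small for the features, or the convolved map vanishes. A
    convolved side of exactly 1 skips the 2×2 pooling stage (logged) rather
    than erroring: the shape is degenerate but legal.
    """
    if input_dim < 1:
        raise ValueError("input_dim must be positive")
    if filters < 1:
        raise ValueError("filters must be positive")
    if mode == "zero_pad" and hp.reshape_dim**2 < input_dim:
        raise ShapeError(
            f"zero_pad: grid {hp.reshape_dim}x{hp.reshape_dim} < {input_dim} features"
        )
    s_c = conv_output_side(hp.reshape_dim, hp.conv_kernel, hp.conv_stride)
    if s_c < 1:
        raise ShapeError(
            f"convolution of {hp.reshape_dim} with kernel {hp.conv_kernel} "
            f"stride {hp.conv_stride} yields empty output"
        )
    if s_c >= 2:
        pooled, s_p = True, s_c // 2
    else:
        pooled, s_p = False, s_c
        logger.info(
            "conv side 1 for %s: 2x2 pooling skipped (degenerate but shape-legal)", hp
        )
    return ModelSpec(
        input_dim=input_dim,
        mode=mode,
        hp=hp,
        filters=filters,
        conv_side=s_c,
        pooled=pooled,
        pool_side=s_p,
        flat_dim=s_p * s_p * filters,
    )


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    return _SELU_SCALE * np.where(z > 0, z, _SELU_ALPHA * (np.exp(z) - 1.0))


def _activate_grad(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (z > 0).astype(float)
    return _SELU_SCALE * np.where(z > 0, 1.0, _SELU_ALPHA * np.exp(z))


class _Network:
    """Parameter container with forward/backward passes and Adam state."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        self.spec = spec
        hp = spec.hp
        r2 = hp.reshape_dim**2
        k2 = hp.conv_kernel**2
        self.params: dict[str, np.ndarray] = {}
        init = self._init_weight
        if spec.mode == "dense_projection":
            self.params["W_map"] = init(rng, spec.input_dim, r2)
            self.params["b_map"] = np.zeros(r2)
        self.params["W_conv"] = init(rng, k2, spec.filters)
        self.params["b_conv"] = np.zeros(spec.filters)
        fan_in = spec.flat_dim
        for i in range(hp.dense_layers):
            self.params[f"W_d{i}"] = init(rng, fan_in, hp.dense_units)
            self.params[f"b_d{i}"] = np.zeros(hp.dense_units)
            fan_in = hp.dense_units
        self.params["W_out"] = init(rng, fan_in, 2)
        self.params["b_out"] = np.zeros(2)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    def _init_weight(self, rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
        # He-style scaling for ReLU, LeCun-style for SeLU (self-normalizing nets)
        gain = 2.0 if self.spec.hp.activation == "relu" else 1.0
        return rng.normal(0.0, np.sqrt(gain / fan_in), size=(fan_in, fan_out))

    # -- forward -----------------------------------------------------------

    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        spec, hp = self.spec, self.spec.hp
        R, K, s, F = hp.reshape_dim, hp.conv_kernel, hp.conv_stride, spec.filters
        n = X.shape[0]
        cache: dict = {"X": X}

        if spec.mode == "dense_projection":
            g = X @ self.params["W_map"] + self.params["b_map"]
        else:
            g = np.concatenate([X, np.zeros((n, R * R - spec.input_dim))], axis=1)
        grid = g.reshape(n, R, R)
        cache["grid"] = grid

        sc = spec.conv_side
        pre = np.empty((n, sc, sc, F))
        patches = np.empty((n, sc, sc, K * K))
        for i in range(sc):
            for j in range(sc):
                patch = grid[:, i * s : i * s + K, j * s : j * s + K].reshape(n, K * K)
                patches[:, i, j, :] = patch
                pre[:, i, j, :] = patch @ self.params["W_conv"] + self.params["b_conv"]
        cache["patches"], cache["conv_pre"] = patches, pre
        act = _activate(pre, hp.activation)

        if spec.pooled:
            sp = spec.pool_side
            windows = act[:, : 2 * sp, : 2 * sp, :].reshape(n, sp, 2, sp, 2, F)
            pooled = windows.max(axis=(2, 4))
            cache["pool_windows"], cache["pool_out"] = windows, pooled
        else:
            pooled = act
        cache["act"] = act

        h = pooled.reshape(n, -1)
        cache["dense_in"] = []
        cache["dense_pre"] = []
        cache["drop_mask"] = []
        for i in range(hp.dense_layers):
            cache["dense_in"].append(h)
            z = h @ self.params[f"W_d{i}"] + self.params[f"b_d{i}"]
            cache["dense_pre"].append(z)
            h = _activate(z, hp.activation)
            if train:
                keep = 1.0 - spec.dropout
                mask = (rng.random(h.shape) < keep) / keep
                h = h * mask
                cache["drop_mask"].append(mask)
            else:
                cache["drop_mask"].append(None)
        cache["head_in"] = h
        logits = h @ self.params["W_out"] + self.params["b_out"]
        logits -= logits.max(axis=1, keepdims=True)
        exp = np.exp(logits)
        probs = exp / exp.sum(axis=1, keepdims=True)
        return probs, cache

    # -- backward ----------------------------------------------------------

    def backward(self, probs: np.ndarray, y: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        spec, hp = self.spec, self.spec.hp
        n = probs.shape[0]
        grads: dict[str, np.ndarray] = {}

        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n

        grads["W_out"] = cache["head_in"].T @ dlogits
        grads["b_out"] = dlogits.sum(axis=0)
        dh = dlogits @ self.params["W_out"].T

        for i in reversed(range(hp.dense_layers)):
            mask = cache["drop_mask"][i]
            if mask is not None:
                dh = dh * mask
            dz = dh * _activate_grad(cache["dense_pre"][i], hp.activation)
            grads[f"W_d{i}"] = cache["dense_in"][i].T @ dz
            grads[f"b_d{i}"] = dz.sum(axis=0)
            dh = dz @ self.params[f"W_d{i}"].T

        F = spec.filters
        dpool = dh.reshape(n, spec.pool_side, spec.pool_side, F)
        if spec.pooled:
            sp = spec.pool_side
            windows = cache["pool_windows"]
            is_max = windows == cache["pool_out"][:, :, None, :, None, :]
            # split gradient evenly among tied maxima within each 2x2 window
            counts = is_max.sum(axis=(2, 4), keepdims=True)
            dwin = is_max / counts * dpool[:, :, None, :, None, :]
            dact = np.zeros_like(cache["act"])
            dact[:, : 2 * sp, : 2 * sp, :] = dwin.reshape(n, 2 * sp, 2 * sp, F)
        else:
            dact = dpool

        dpre = dact * _activate_grad(cache["conv_pre"], hp.activation)
        R, K, s = hp.reshape_dim, hp.conv_kernel, hp.conv_stride
        sc = spec.conv_side
        dW_conv = np.zeros_like(self.params["W_conv"])
        dgrid = np.zeros((n, R, R))
        for i in range(sc):
            for j in range(sc):
                d = dpre[:, i, j, :]
                dW_conv += cache["patches"][:, i, j, :].T @ d
                dgrid[:, i * s : i * s + K, j * s : j * s + K] += (
                    d @ self.params["W_conv"].T
                ).reshape(n, K, K)
        grads["W_conv"] = dW_conv
        grads["b_conv"] = dpre.sum(axis=(0, 1, 2))

        if spec.mode == "dense_projection":
            dg = dgrid.reshape(n, R * R)
            grads["W_map"] = cache["X"].T @ dg
            grads["b_map"] = dg.sum(axis=0)
        return grads

    def adam_step(
        self,
        grads: dict[str, np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            v = self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class TrainedModel:
    """A fitted network: spec, learned weights and training metadata."""

    spec: ModelSpec
    network: _Network
    epochs: int
    seed: int
    final_loss: float
    loss_history: list[float] = field(default_factory=list)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probability matrix of shape (n, 2); rows sum to 1.

        Dropout is disabled: repeated calls on the same inputs are identical.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"expected (n, {self.spec.input_dim}) features, got {X.shape}"
            )
        probs, _ = self.network.forward(X, train=False)
        return probs

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        """Hard labels from thresholding the class-1 probability."""
        return (self.predict_proba(X)[:, 1] >= threshold).astype(int)

    def save(self, path: str | Path) -> None:
        """Save as a single .npz archive: spec JSON + weight arrays."""
        meta = {
            "spec": self.spec.to_json(),
            "epochs": self.epochs,
            "seed": self.seed,
            "final_loss": self.final_loss,
            "loss_history": self.loss_history,
        }
        arrays = {f"param_{k}": v for k, v in self.network.params.items()}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            spec = ModelSpec.from_json(meta["spec"])
            net = _Network(spec, np.random.default_rng(0))
            for key in list(net.params):
                net.params[key] = archive[f"param_{key}"]
        return cls(
            spec=spec,
            network=net,
            epochs=meta["epochs"],
            seed=meta["seed"],
            final_loss=meta["final_loss"],
            loss_history=list(meta["loss_history"]),
        )


def predict_site_probability(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Per-row probability that the window is a pseudouridine site (class 1)."""
    return model.predict_proba(X)[:, 1]


def train(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int = 30,
    seed: int = 0,
    lr: float = 1e-3,
    batch_size: int = 32,
) -> TrainedModel:
    """Fit the network by minibatch Adam on the cross-entropy loss.

    One seed drives initialization, shuffling and dropout, so the same
    (spec, data, epochs, seed) always yields the same model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"X {X.shape} and y {y.shape} are inconsistent")
    if X.shape[1] != spec.input_dim:
        raise ValueError(f"X has {X.shape[1]} columns, spec expects {spec.input_dim}")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"binary task requires both classes; got labels {classes}")

    rng = np.random.default_rng(seed)
    net = _Network(spec, rng)
    n = X.shape[0]
    history: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            probs, cache = net.forward(X[idx], train=True, rng=rng)
            loss = -np.mean(np.log(probs[np.arange(len(idx)), y[idx]] + 1e-12))
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at step {net._adam_t + 1}; "
                    "try a lower learning rate"
                )
            epoch_loss += loss * len(idx)
            grads = net.backward(probs, y[idx], cache)
            net.adam_step(grads, lr=lr)
        history.append(epoch_loss / n)
    return TrainedModel(
        spec=spec,
        network=net,
        epochs=epochs,
        seed=seed,
        final_loss=history[-1],
        loss_history=history,
    )
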