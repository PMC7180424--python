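"""Pluggable patch-level classifier with a CPU-trainable reference backend.

The contract every backend satisfies: ``predict_probs(patches) -> (n, 5)``
row-stochastic probability matrix over the fixed class order
(TA, TVA, HP, SSA, NORM); hard labels are the argmax with ties broken by that
order. The reference backend is a compact two-conv-block network implemented
in numpy (forward and backward by hand) that downsamples 224-px patches by 8x
internally; deeper architectures (e.g. a ResNet) can be slotted in behind the
same interface. Training follows a geometric learning-rate schedule:
``lr(e) = initial_lr * decay^(e-1)`` with defaults 0.001 and 0.9 per epoch.

Ensembles combine members by unweighted softmax averaging.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .patching import AugmentSpec, augment
from .wsi_io import PATCH_CLASSES

INIT_SCHEMES = ("he_normal", "fixed_seed_uniform")


@dataclass(frozen=True)
class TrainConfig:
    """Training schedule for the reference backend.

    ``epochs`` defaults to a desk-scale 20; the full-scale schedule this
    mirrors ran 200 epochs. The learning rate at (1-based) epoch e is
    ``initial_lr * lr_decay_per_epoch**(e-1)``.
    """

    epochs: int = 20
    initial_lr: float = 0.001
    lr_decay_per_epoch: float = 0.9
    batch_size: int = 32
    momentum: float = 0.9
    seed: int = 0
    augment: AugmentSpec = field(default_factory=AugmentSpec)
    init_scheme: str = "he_normal"
    input_downsample: int = 8
    n_filters: tuple[int, int] = (8, 16)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.lr_decay_per_epoch <= 1.0:
            raise ValueError("lr_decay_per_epoch must lie in (0, 1]")
        if self.init_scheme not in INIT_SCHEMES:
            raise ValueError(f"init_scheme must be one of {INIT_SCHEMES}")


def learning_rate(config: TrainConfig, epoch: int) -> float:
    """Learning rate at 1-based epoch ``epoch``."""
    if epoch < 1:
        raise ValueError("epochs are 1-based")
    return config.initial_lr * config.lr_decay_per_epoch ** (epoch - 1)


def config_hash(config: TrainConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def hard_labels(probs: np.ndarray) -> np.ndarray:
    """Argmax labels; np.argmax returns the first maximum, which realizes the
    fixed-class-order tie-break."""
    probs = np.atleast_2d(probs)
    return np.array([PATCH_CLASSES[i] for i in probs.argmax(axis=1)])


# ---------------------------------------------------------------------------
# Reference backend: two conv blocks + linear head, in numpy
# ---------------------------------------------------------------------------

def _pool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """2x2 max pool (stride 2, floor). Returns pooled, routing mask, crop."""
    n, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    xc = x[:, : 2 * h2, : 2 * w2]
    r = xc.reshape(n, h2, 2, w2, 2, c)
    pooled = r.max(axis=(2, 4))
    mask = r == pooled[:, :, None, :, None, :]
    return pooled, mask, (2 * h2, 2 * w2)


def _unpool2(dp: np.ndarray, mask: np.ndarray, shape: tuple[int, ...],
             crop: tuple[int, int]) -> np.ndarray:
    n, h2, _, w2, _, c = mask.shape
    dr = mask * dp[:, :, None, :, None, :]
    out = np.zeros(shape, dtype=dp.dtype)
    out[:, : crop[0], : crop[1]] = dr.reshape(n, 2 * h2, 2 * w2, c)
    return out


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid 3x3 convolution; x (n,h,w,cin), w (3,3,cin,cout)."""
    win = np.lib.stride_tricks.sliding_window_view(x, (3, 3), axis=(1, 2))
    # win: (n, h-2, w-2, cin, 3, 3); contract (cin, dy, dx)
    return np.tensordot(win, w, axes=([3, 4, 5], [2, 0, 1])) + b


class SmallCNN:
    """Reference convolutional patch classifier.

    Input patches are uint8 RGB squares of ``patch_size``; internally each is
    block-mean downsampled by ``input_downsample`` and normalized to
    [-0.5, 0.5] before two 3x3-conv + relu + 2x2-maxpool blocks and a linear
    softmax head over the five patch classes.
    """

    class_order = PATCH_CLASSES

    def __init__(self, params: dict[str, np.ndarray], patch_size: int,
                 input_downsample: int, config: TrainConfig | None = None):
        self.params = params
        self.patch_size = patch_size
        self.input_downsample = input_downsample
        self.config = config

    # -- initialization ------------------------------------------------------

    @staticmethod
    def _init_params(inner: int, config: TrainConfig,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
        f1, f2 = config.n_filters
        d1 = inner - 2
        p1 = d1 // 2
        d2 = p1 - 2
        p2 = d2 // 2
        if p2 < 1:
            raise ValueError(f"downsampled input {inner}px too small for the network")
        flat = p2 * p2 * f2
        shapes = {
            "W1": (3, 3, 3, f1), "b1": (f1,),
            "W2": (3, 3, f1, f2), "b2": (f2,),
            "W3": (flat, len(PATCH_CLASSES)), "b3": (len(PATCH_CLASSES),),
        }
        params = {}
        for name, shape in shapes.items():
            if name.startswith("b"):
                params[name] = np.zeros(shape)
            elif config.init_scheme == "he_normal":
                fan_in = int(np.prod(shape[:-1]))
                params[name] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
            else:  # fixed_seed_uniform
                params[name] = rng.uniform(-0.05, 0.05, size=shape)
        return params

    # -- preprocessing -------------------------------------------------------

    def _preprocess(self, patches: np.ndarray) -> np.ndarray:
        patches = np.asarray(patches)
        if patches.ndim == 3:
            patches = patches[None]
        if patches.shape[1] != self.patch_size or patches.shape[2] != self.patch_size:
            raise ValueError(
                f"patch size {patches.shape[1]}x{patches.shape[2]} does not match "
                f"model patch size {self.patch_size}"
            )
        x = patches.astype(np.float64)
        if patches.dtype == np.uint8:
            x = x / 255.0
        f = self.input_downsample
        if f > 1:
            n, h, w, c = x.shape
            x = x[:, : h - h % f, : w - w % f]
            x = x.reshape(n, h // f, f, w // f, f, c).mean(axis=(2, 4))
        return x - 0.5

    # -- forward / backward --------------------------------------------------

    def _forward(self, x: np.ndarray, cache: bool = False):
        p = self.params
        z1 = _conv_forward(x, p["W1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        p1, m1, c1 = _pool2(a1)
        z2 = _conv_forward(p1, p["W2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        p2, m2, c2 = _pool2(a2)
        flat = p2.reshape(len(x), -1)
        logits = flat @ p["W3"] + p["b3"]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        if not cache:
            return probs, None
        return probs, dict(x=x, z1=z1, a1=a1, p1=p1, m1=m1, c1=c1,
                           z2=z2, a2=a2, m2=m2, c2=c2, flat=flat)

    def _backward(self, probs: np.ndarray, y: np.ndarray, cache: dict
                  ) -> dict[str, np.ndarray]:
        p = self.params
        n = len(y)
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads = {
            "W3": cache["flat"].T @ dlogits,
            "b3": dlogits.sum(axis=0),
        }
        dflat = dlogits @ p["W3"].T
        dp2 = dflat.reshape(
            n, cache["a2"].shape[1] // 2, cache["a2"].shape[2] // 2, -1)
        da2 = _unpool2(dp2, cache["m2"], cache["a2"].shape, cache["c2"])
        dz2 = da2 * (cache["z2"] > 0)
        win1 = np.lib.stride_tricks.sliding_window_view(cache["p1"], (3, 3), axis=(1, 2))
        # (n,h,w,cin,3,3) x (n,h,w,cout) -> (cin,3,3,cout) -> (3,3,cin,cout)
        grads["W2"] = np.tensordot(win1, dz2, axes=([0, 1, 2], [0, 1, 2])
                                   ).transpose(1, 2, 0, 3)
        grads["b2"] = dz2.sum(axis=(0, 1, 2))
        dp1 = np.zeros_like(cache["p1"])
        hh, ww = dz2.shape[1:3]
        for di in range(3):
            for dj in range(3):
                dp1[:, di : di + hh, dj : dj + ww] += dz2 @ p["W2"][di, dj].T
        da1 = _unpool2(dp1, cache["m1"], cache["a1"].shape, cache["c1"])
        dz1 = da1 * (cache["z1"] > 0)
        win0 = np.lib.stride_tricks.sliding_window_view(cache["x"], (3, 3), axis=(1, 2))
        grads["W1"] = np.tensordot(win0, dz1, axes=([0, 1, 2], [0, 1, 2])
                                   ).transpose(1, 2, 0, 3)
        grads["b1"] = dz1.sum(axis=(0, 1, 2))
        return grads

    # -- public API ----------------------------------------------------------

    def predict_probs(self, patches: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Probability matrix (n, 5); rows sum to 1 within 1e-6."""
        x = self._preprocess(patches)
        out = []
        for i in range(0, len(x), batch_size):
            probs, _ = self._forward(x[i : i + batch_size])
            out.append(probs)
        return np.concatenate(out) if out else np.empty((0, len(PATCH_CLASSES)))

    def save(self, path) -> None:
        """Checkpoint: npz parameters + JSON sidecar with the class order,
        patch size and config hash."""
        path = Path(path)
        np.savez(path, **self.params)
        sidecar = {
            "class_order": list(self.class_order),
            "patch_size": self.patch_size,
            "input_downsample": self.input_downsample,
            "config_hash": config_hash(self.config) if self.config else None,
        }
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, path) -> "SmallCNN":
        path = Path(path)
        with np.load(path) as npz:
            params = {k: npz[k] for k in npz.files}
        with open(path.with_suffix(path.suffix + ".json")) as fh:
            sidecar = json.load(fh)
        if tuple(sidecar["class_order"]) != PATCH_CLASSES:
            raise ValueError("checkpoint class order does not match this build")
        return cls(params, sidecar["patch_size"], sidecar["input_downsample"])


def train_patch_classifier(
    patches: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig = TrainConfig(),
    log_path=None,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> SmallCNN:
    """Train the reference backend with seeded SGD + momentum.

    Deterministic given ``config.seed`` and the input data. Optional
    ``validation`` (patches, labels) is scored each epoch into the training
    log (epoch, lr, loss, val_accuracy).
    """
    patches = np.asarray(patches)
    labels = np.asarray(labels)
    if patches.ndim != 4 or patches.shape[1] != patches.shape[2]:
        raise ValueError("patches must be a uniform (n, s, s, 3) stack of squares")
    present = set(labels.tolist())
    if len(present) < 2:
        raise ValueError("training requires at least 2 classes present")
    unknown = present - set(PATCH_CLASSES)
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}")

    rng = np.random.default_rng(config.seed)
    patch_size = patches.shape[1]
    inner = patch_size // config.input_downsample
    model = SmallCNN(
        SmallCNN._init_params(inner, config, rng),
        patch_size=patch_size,
        input_downsample=config.input_downsample,
        config=config,
    )
    y = np.array([PATCH_CLASSES.index(l) for l in labels])

    # preprocess once; augmentation operates on the downsampled [0,1] images
    x_small = model._preprocess(patches) + 0.5
    do_augment = config.augment != AugmentSpec.disabled()

    velocity = {k: np.zeros_like(v) for k, v in model.params.items()}
    log_rows = []
    n = len(y)
    for epoch in range(1, config.epochs + 1):
        lr = learning_rate(config, epoch)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x_small[idx]
            if do_augment:
                seeds = rng.integers(0, 2**31 - 1, size=len(idx))
                xb = np.stack([
                    augment(xb[i], config.augment, int(seeds[i]))
                    for i in range(len(idx))
                ])
            probs, cache = model._forward(xb - 0.5, cache=True)
            yb = y[idx]
            losses.append(-np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-12)))
            grads = model._backward(probs, yb, cache)
            for k in model.params:
                velocity[k] = config.momentum * velocity[k] - lr * grads[k]
                model.params[k] += velocity[k]
        val_acc = np.nan
        if validation is not None:
            vp = model.predict_probs(validation[0])
            val_acc = float(np.mean(hard_labels(vp) == np.asarray(validation[1])))
        log_rows.append((epoch, lr, float(np.mean(losses)), val_acc))

    if log_path is not None:
        import pandas as pd

        pd.DataFrame(log_rows, columns=["epoch", "lr", "loss", "val_accuracy"]
                     ).to_csv(log_path, index=False)
    return model


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------

class SoftmaxEnsemble:
    """Unweighted softmax-averaging ensemble of patch classifiers."""

    def __init__(self, members: list):
        if not members:
            raise ValueError("ensemble requires at least one member")
        orders = {tuple(m.class_order) for m in members}
        if len(orders) > 1:
            raise ValueError("ensemble members disagree on class order")
        self.members = list(members)
        self.class_order = members[0].class_order
        self.patch_size = members[0].patch_size

    def predict_probs(self, patches: np.ndarray) -> np.ndarray:
        mean = np.mean([m.predict_probs(patches) for m in self.members], axis=0)
        sums = mean.sum(axis=1, keepdims=True)
        bad = np.abs(sums - 1.0) > 1e-9
        if bad.any():  # renormalize only if numerically needed
            mean = mean / sums
        return mean


def ensemble_predict(models: list, patches: np.ndarray) -> np.ndarray:
    """Functional form of :class:`SoftmaxEnsemble`."""
    return SoftmaxEnsemble(models).predict_probs(patches)
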