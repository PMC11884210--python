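"""The 2D U-Net segmentation model and its training loop.

A single 2D U-Net serves all three slicing orientations: it maps a P x P
intensity patch to a P x P x (C+1) field of class probabilities through a
symmetric encoder/decoder with skip connections — 3x3 convolutions with
'same' padding (spatial dimensions preserved throughout), ReLU activations,
2x2 max pooling on the way down, 2x2 transposed convolutions on the way up,
and a channel-wise softmax head, following the standard U-Net design with
feature widths doubling from a base count at each encoder level.

Training minimises unweighted pixel-wise cross entropy (background
included — the framework is expected to cope with class imbalance without
re-weighting) with Adam, a step learning-rate schedule (multiply by a drop
factor every drop period), L2 weight regularisation and global L2-norm
gradient clipping. Patches are re-augmented with fresh random draws every
epoch so the network never sees the same patch twice. All arithmetic is
numpy; the patch-based design keeps tensors small enough that no GPU or
deep-learning runtime is needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _nnops as nn
from .augment import AugmentationPolicy, augment_pair, identity_policy
from .triplanar import (
    ALL_ORIENTATIONS,
    Orientation,
    PatchGrid,
    extract_slices,
    tile_slice,
)
from .volumes import ImageVolume, LabelVolume, ValidationError


class ConfigurationError(ValueError):
    """Raised for invalid model or training configurations."""


class TrainingError(RuntimeError):
    """Raised when optimisation fails (e.g. the loss becomes non-finite)."""


@dataclass
class TrainingConfig:
    """Hyper-parameters of the training recipe.

    Defaults are the framework's cross-application settings: patch size 128
    (256 for the fetal MR application), learning rate 1e-3 (5e-3 fetal)
    dropped by ``lr_drop_factor`` every ``lr_drop_period`` epochs, encoder
    depth 4, Adam with decay rates (0.9, 0.999), L2 strength 1e-4, L2-norm
    gradient clipping, 100 epochs, batch size 30, hold-out validation. Tests
    and phantom studies scale patch size, depth and epochs down.
    """

    patch_size: int = 128
    learning_rate: float = 0.001
    lr_drop_period: int = 5
    lr_drop_factor: float = 0.85
    encoder_depth: int = 4
    optimizer: str = "adam"
    l2_strength: float = 1e-4
    gradient_clip: str = "l2_norm"
    gradient_clip_threshold: float = 10.0
    gradient_decay: float = 0.9
    squared_gradient_decay: float = 0.999
    epochs: int = 100
    batch_size: int = 30
    base_filters: int = 64
    split: str = "holdout"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size < 1 or self.patch_size % 2**self.encoder_depth:
            raise ConfigurationError(
                f"patch_size {self.patch_size} must be a positive multiple of "
                f"2^encoder_depth = {2**self.encoder_depth}"
            )
        for name in ("learning_rate", "l2_strength", "lr_drop_period", "epochs",
                     "batch_size", "base_filters"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0 < self.lr_drop_factor <= 1:
            raise ConfigurationError("lr_drop_factor must be in (0, 1]")
        if self.optimizer != "adam":
            raise ConfigurationError("only the adam optimizer is supported")
        if self.gradient_clip != "l2_norm":
            raise ConfigurationError("only l2_norm gradient clipping is supported")

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate for a 1-based epoch index under the step schedule."""
        drops = (epoch - 1) // self.lr_drop_period
        return self.learning_rate * self.lr_drop_factor**drops

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SegmentationModel:
    """A 2D U-Net parameter container with forward/backward passes.

    The same parameters serve every slicing orientation at inference;
    ``orientation_set`` records which orientations the model is meant to be
    fused over (all three by default, two for the mandible-style case).
    """

    encoder_depth: int
    num_classes: int  # foreground classes C; the head emits C+1 channels
    patch_size: int
    base_filters: int = 64
    in_channels: int = 1
    class_names: list[str] = field(default_factory=list)
    orientation_set: tuple[Orientation, ...] = ALL_ORIENTATIONS
    normalization: str = "minmax"
    params: dict[str, np.ndarray] = field(default_factory=dict)

    # -- construction -------------------------------------------------

    def _layer_plan(self) -> list[tuple[str, str, int, int, int]]:
        """(name, kind, c_in, c_out, kernel) for every parameterised layer."""
        d, b = self.encoder_depth, self.base_filters
        plan: list[tuple[str, str, int, int, int]] = []
        c = self.in_channels
        for i in range(d):
            f = b * 2**i
            plan += [(f"enc{i}_c1", "conv", c, f, 3), (f"enc{i}_c2", "conv", f, f, 3)]
            c = f
        fb = b * 2**d
        plan += [("bot_c1", "conv", c, fb, 3), ("bot_c2", "conv", fb, fb, 3)]
        c = fb
        for i in reversed(range(d)):
            f = b * 2**i
            plan += [
                (f"up{i}", "upconv", c, f, 2),
                (f"dec{i}_c1", "conv", 2 * f, f, 3),
                (f"dec{i}_c2", "conv", f, f, 3),
            ]
            c = f
        plan += [("head", "conv", c, self.num_classes + 1, 1)]
        return plan

    def initialize(self, rng: np.random.Generator) -> None:
        """He-normal weight initialisation, zero biases."""
        self.params = {}
        for name, kind, c_in, c_out, k in self._layer_plan():
            if kind == "conv":
                std = np.sqrt(2.0 / (c_in * k * k))
                w = rng.normal(0, std, (c_out, c_in, k, k)).astype(np.float32)
            else:  # upconv
                std = np.sqrt(2.0 / (c_in * k * k))
                w = rng.normal(0, std, (c_in, c_out, k, k)).astype(np.float32)
            self.params[f"{name}_w"] = w
            self.params[f"{name}_b"] = np.zeros(c_out, dtype=np.float32)

    # -- forward / backward -------------------------------------------

    def _conv_relu(self, h, name, cache):
        out = nn.relu_forward(
            nn.conv2d_forward(h, self.params[f"{name}_w"], self.params[f"{name}_b"])
        )
        cache.append((name, h, out))
        return out

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Map (N, in, P, P) patches to (N, C+1, P, P) logits."""
        if x.ndim != 4 or x.shape[2] != self.patch_size or x.shape[3] != self.patch_size:
            raise ValidationError(
                f"expected (N, {self.in_channels}, {self.patch_size}, {self.patch_size}) input,"
                f" got {x.shape}"
            )
        cache: dict = {"convs": [], "pools": [], "ups": [], "skips": []}
        h = x.astype(np.float32)
        for i in range(self.encoder_depth):
            h = self._conv_relu(h, f"enc{i}_c1", cache["convs"])
            h = self._conv_relu(h, f"enc{i}_c2", cache["convs"])
            cache["skips"].append(h)
            pooled, idx = nn.maxpool2_forward(h)
            cache["pools"].append((idx, h.shape))
            h = pooled
        h = self._conv_relu(h, "bot_c1", cache["convs"])
        h = self._conv_relu(h, "bot_c2", cache["convs"])
        for i in reversed(range(self.encoder_depth)):
            up_in = h
            h = nn.upconv2_forward(h, self.params[f"up{i}_w"], self.params[f"up{i}_b"])
            cache["ups"].append((f"up{i}", up_in))
            h = np.concatenate([cache["skips"][i], h], axis=1)
            h = self._conv_relu(h, f"dec{i}_c1", cache["convs"])
            h = self._conv_relu(h, f"dec{i}_c2", cache["convs"])
        logits = nn.conv2d_forward(h, self.params["head_w"], self.params["head_b"])
        cache["head_in"] = h
        return (logits, cache) if want_cache else logits

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. every parameter, given d(loss)/d(logits)."""
        grads: dict[str, np.ndarray] = {}
        convs = list(cache["convs"])
        ups = list(cache["ups"])
        pools = list(cache["pools"])

        def conv_bwd(dout, entry):
            name, x_in, out = entry
            dout = nn.relu_backward(dout, out)
            dx, dw, db = nn.conv2d_backward(dout, x_in, self.params[f"{name}_w"])
            grads[f"{name}_w"] = dw
            grads[f"{name}_b"] = db
            return dx

        dh, dw, db = nn.conv2d_backward(dlogits, cache["head_in"], self.params["head_w"])
        grads["head_w"] = dw
        grads["head_b"] = db

        dskips: dict[int, np.ndarray] = {}
        for i in range(self.encoder_depth):  # decoder levels, deepest last in lists
            dh = conv_bwd(dh, convs.pop())  # dec{i}_c2
            dh = conv_bwd(dh, convs.pop())  # dec{i}_c1
            f = self.base_filters * 2**i
            dskip, dup = dh[:, :f], dh[:, f:]
            dskips[i] = dskip
            name, up_in = ups.pop()
            dh, dw, db = nn.upconv2_backward(dup, up_in, self.params[f"{name}_w"])
            grads[f"{name}_w"] = dw
            grads[f"{name}_b"] = db
        dh = conv_bwd(dh, convs.pop())  # bot_c2
        dh = conv_bwd(dh, convs.pop())  # bot_c1
        for i in reversed(range(self.encoder_depth)):
            idx, in_shape = pools.pop()
            dh = nn.maxpool2_backward(dh, idx, in_shape)
            dh = dh + dskips[i]
            dh = conv_bwd(dh, convs.pop())  # enc{i}_c2
            dh = conv_bwd(dh, convs.pop())  # enc{i}_c1
        return grads

    # -- inference -----------------------------------------------------

    def predict_probs(self, patches: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Softmax class probabilities for (N, P, P) or (N, 1, P, P) patches."""
        x = np.asarray(patches, np.float32)
        if x.ndim == 3:
            x = x[:, None]
        out = []
        for start in range(0, len(x), batch_size):
            logits = self.forward(x[start : start + batch_size])
            out.append(nn.softmax(logits))
        return np.concatenate(out, axis=0)

    # -- persistence ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint: parameters plus architecture/recipe metadata in one npz."""
        meta = {
            "encoder_depth": self.encoder_depth,
            "num_classes": self.num_classes,
            "patch_size": self.patch_size,
            "base_filters": self.base_filters,
            "in_channels": self.in_channels,
            "class_names": self.class_names,
            "orientation_set": [o.value for o in self.orientation_set],
            "normalization": self.normalization,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), np.uint8), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "SegmentationModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
            params = {k: data[k] for k in data.files if k != "__meta__"}
        model = cls(
            encoder_depth=meta["encoder_depth"],
            num_classes=meta["num_classes"],
            patch_size=meta["patch_size"],
            base_filters=meta["base_filters"],
            in_channels=meta["in_channels"],
            class_names=list(meta["class_names"]),
            orientation_set=tuple(Orientation(o) for o in meta["orientation_set"]),
            normalization=meta["normalization"],
        )
        model.params = params
        return model


def build_unet(
    encoder_depth: int,
    num_classes: int,
    patch_size: int,
    base_filters: int = 64,
    class_names: Sequence[str] | None = None,
    orientations: Sequence[Orientation] = ALL_ORIENTATIONS,
    seed: int = 0,
) -> SegmentationModel:
    """Construct and initialise a 2D U-Net.

    ``patch_size`` must be divisible by ``2**encoder_depth`` so every max
    pooling halves cleanly and the decoder restores the input size exactly.
    """
    if encoder_depth < 1:
        raise ConfigurationError("encoder_depth must be >= 1")
    if patch_size % 2**encoder_depth:
        raise ConfigurationError(
            f"patch_size {patch_size} is not divisible by 2^{encoder_depth}"
        )
    model = SegmentationModel(
        encoder_depth=encoder_depth,
        num_classes=num_classes,
        patch_size=patch_size,
        base_filters=base_filters,
        class_names=list(class_names or [f"class_{i}" for i in range(1, num_classes + 1)]),
        orientation_set=tuple(orientations),
    )
    model.initialize(np.random.default_rng(seed))
    return model


# ---------------------------------------------------------------------------
# Training data


@dataclass
class PatchSample:
    image: np.ndarray  # (P, P) float32
    label: np.ndarray  # (P, P) integer class map
    orientation: Orientation


def extract_training_patches(
    vol: ImageVolume,
    lab: LabelVolume,
    patch_size: int,
    stride: int,
    orientations: Sequence[Orientation] = ALL_ORIENTATIONS,
) -> list[PatchSample]:
    """Tile an image/label volume pair into training patches.

    Every slice of every requested orientation is tiled with the shared
    anchor grid, so image and label patches cover identical voxels and
    every foreground voxel appears in at least one patch per orientation.
    Sampling over the tiled patches is uniform (no foreground balancing).
    """
    if vol.shape != lab.shape:
        raise ValidationError("image and label volumes must share a lattice")
    samples: list[PatchSample] = []
    for orientation in orientations:
        img_stack = extract_slices(vol.data, orientation)
        lab_stack = extract_slices(lab.data, orientation)
        grid = PatchGrid(patch_size, stride, img_stack.shape[1:])
        for img_slice, lab_slice in zip(img_stack, lab_stack):
            img_tiles = tile_slice(img_slice, grid)
            lab_tiles = tile_slice(lab_slice, grid)
            for (ip, anchor), (lp, _) in zip(img_tiles, lab_tiles):
                samples.append(
                    PatchSample(
                        ip.astype(np.float32), lp.astype(np.int16), orientation
                    )
                )
    return samples


# ---------------------------------------------------------------------------
# Training loop


def train_model(
    dataset: Sequence[PatchSample],
    config: TrainingConfig,
    policy: AugmentationPolicy | None = None,
    model: SegmentationModel | None = None,
    num_classes: int | None = None,
    class_names: Sequence[str] | None = None,
    orientations: Sequence[Orientation] = ALL_ORIENTATIONS,
    verbose: bool = False,
):
    """Train a U-Net on tiled patches.

    Each epoch shuffles the patch order and re-draws the augmentation of
    every patch, then runs minibatch Adam with the step learning-rate
    schedule, L2 regularisation (weights only) and global L2-norm gradient
    clipping. Deterministic given ``config.seed``.

    Returns
    -------
    (model, history) : the trained model and a pandas DataFrame with one
    row per epoch (epoch, loss, lr).
    """
    import pandas as pd

    if not dataset:
        raise ValidationError("training dataset is empty")
    policy = policy or identity_policy()
    rng = np.random.default_rng(config.seed)
    if num_classes is None:
        num_classes = int(max(int(s.label.max()) for s in dataset))
    if model is None:
        model = build_unet(
            config.encoder_depth,
            num_classes,
            config.patch_size,
            base_filters=config.base_filters,
            class_names=class_names,
            orientations=orientations,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    state = nn.AdamState(model.params)
    weight_keys = [k for k in model.params if k.endswith("_w")]
    history = []
    n = len(dataset)
    for epoch in range(1, config.epochs + 1):
        lr = config.lr_at_epoch(epoch)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch_idx = order[start : start + config.batch_size]
            imgs, labs = [], []
            for j in batch_idx:
                s = dataset[j]
                img, lab_p = augment_pair(s.image, s.label, policy, rng)
                imgs.append(img)
                labs.append(lab_p)
            x = np.stack(imgs)[:, None].astype(np.float32)
            y = np.stack(labs).astype(np.int64)
            logits, cache = model.forward(x, want_cache=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            grads = model.backward(dlogits, cache)
            for k in weight_keys:  # L2 penalty on weights, not biases
                grads[k] += config.l2_strength * model.params[k]
            nn.clip_gradients_l2(grads, config.gradient_clip_threshold)
            nn.adam_step(
                model.params,
                grads,
                state,
                lr,
                beta1=config.gradient_decay,
                beta2=config.squared_gradient_decay,
            )
            losses.append(loss)
        history.append({"epoch": epoch, "loss": float(np.mean(losses)), "lr": lr})
        if verbose:
            print(f"epoch {epoch:3d}  loss {history[-1]['loss']:.4f}  lr {lr:.2e}")
    return model, pd.DataFrame(history)


__all__ = [
    "TrainingConfig",
    "SegmentationModel",
    "PatchSample",
    "ConfigurationError",
    "TrainingError",
    "build_unet",
    "extract_training_patches",
    "train_model",
]
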