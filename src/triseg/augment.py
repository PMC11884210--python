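"""Stochastic training-time augmentation of image/label patches.

Each transform has an activation probability and, where applicable, a
parameter drawn from a uniform distribution U(a, b) at activation time.
Geometric transforms (2D rotation, scaling, mirroring, transposition) are
applied identically to the image patch and its label patch (labels with
nearest-neighbour interpolation); intensity transforms (noise, streaks,
brightness, contrast, blur, sharpening) touch the image only. A global 3D
rotation can additionally be applied to the whole volume before patches are
generated.

Augmentation is re-drawn for every patch at every epoch, so the network
never sees the exact same patch twice. All randomness flows through an
explicit ``numpy.random.Generator``: the same seed reproduces the same
augmented stream bit for bit.

Shipped presets: ``generic`` (CT applications), ``mandible`` (no mirroring
or transposition — the spatial relation between mandible and cranium is the
discriminative signal and must not be scrambled), ``fetal`` (MR; no
mirroring/transposition/streaks, sharpening enabled), and ``phantom``
(narrow intensity jitter suited to the normalised synthetic phantoms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
from scipy import ndimage

from .volumes import ImageVolume, LabelVolume, ValidationError

# canonical application order; geometric transforms first so intensity
# statistics are computed on the geometry the network will see
TRANSFORM_ORDER = (
    "rotation2d",
    "scaling",
    "mirror_h",
    "mirror_v",
    "transpose",
    "white_noise",
    "streak_noise",
    "brightness",
    "contrast",
    "gaussian_blur",
    "sharpening",
)

GEOMETRIC = {"rotation2d", "scaling", "mirror_h", "mirror_v", "transpose"}


@dataclass(frozen=True)
class TransformSetting:
    """Activation probability plus the U(a, b) parameter range of a transform."""

    probability: float
    range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValidationError(f"probability must be in [0,1], got {self.probability}")
        if self.range is not None:
            a, b = self.range
            if not (np.isfinite(a) and np.isfinite(b) and a <= b):
                raise ValidationError(f"invalid parameter range {self.range}")


def _ts(p: float, rng: tuple[float, float] | None = None) -> TransformSetting:
    return TransformSetting(p, rng)


@dataclass(frozen=True)
class AugmentationPolicy:
    """Per-transform activation probabilities and parameter ranges.

    Units: rotations in degrees; scaling/contrast/sharpening are
    multiplicative factors; white and streak noise amplitudes are fractions
    of the patch intensity range; brightness is an additive offset in the
    image's native intensity units (HU for CT); gaussian_blur's range holds
    the odd filter size in pixels.

    ``rotation3d`` is special: it applies to the whole volume before patch
    extraction (see :func:`rotate_volume_3d`), not inside
    :func:`augment_pair`.
    """

    rotation3d: TransformSetting = _ts(0.0, (-20, 20))
    rotation2d: TransformSetting = _ts(0.20, (-45, 45))
    scaling: TransformSetting = _ts(0.20, (0.6, 1.4))
    mirror_h: TransformSetting = _ts(0.50)
    mirror_v: TransformSetting = _ts(0.50)
    transpose: TransformSetting = _ts(0.50)
    white_noise: TransformSetting = _ts(0.10, (0.0, 0.15))
    streak_noise: TransformSetting = _ts(0.10, (0.0, 0.70))
    brightness: TransformSetting = _ts(0.15, (-100, 100))
    contrast: TransformSetting = _ts(0.15, (0.65, 1.5))
    gaussian_blur: TransformSetting = _ts(0.25, (3, 3))
    sharpening: TransformSetting = _ts(0.0, (0.7, 1.3))

    def setting(self, name: str) -> TransformSetting:
        return getattr(self, name)

    def to_dict(self) -> dict:
        return {k: {"probability": v["probability"], "range": list(v["range"]) if v["range"] else None}
                for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "AugmentationPolicy":
        kwargs = {}
        for name, spec in d.items():
            rng = spec.get("range")
            kwargs[name] = TransformSetting(
                float(spec["probability"]), tuple(rng) if rng else None
            )
        return cls(**kwargs)


def identity_policy() -> AugmentationPolicy:
    """All activation probabilities zero; augment_pair becomes the identity."""
    kwargs = {name: _ts(0.0, getattr(AugmentationPolicy(), name).range)
              for name in TRANSFORM_ORDER + ("rotation3d",)}
    return AugmentationPolicy(**kwargs)


def generic_policy() -> AugmentationPolicy:
    """Default CT preset (the dataclass defaults)."""
    return AugmentationPolicy()


def mandible_policy() -> AugmentationPolicy:
    """CT preset with mirroring/transposition disabled.

    Mandible and cranium are the same tissue with the same attenuation, so
    the network must rely on relative position and orientation — which
    mirroring and transposing would destroy.
    """
    return AugmentationPolicy(
        rotation2d=_ts(0.25, (-20, 20)),
        scaling=_ts(0.20, (0.7, 1.3)),
        mirror_h=_ts(0.0),
        mirror_v=_ts(0.0),
        transpose=_ts(0.0),
        brightness=_ts(0.15, (-30, 30)),
        contrast=_ts(0.15, (0.95, 1.05)),
    )


def fetal_policy() -> AugmentationPolicy:
    """MR preset: no mirroring/transposition/streaks; unsharp sharpening on."""
    return AugmentationPolicy(
        mirror_h=_ts(0.0),
        mirror_v=_ts(0.0),
        transpose=_ts(0.0),
        streak_noise=_ts(0.0, (0.0, 0.70)),
        brightness=_ts(0.15, (-0.1, 0.1)),
        contrast=_ts(0.15, (0.7, 1.3)),
        sharpening=_ts(0.15, (0.7, 1.3)),
    )


def phantom_policy() -> AugmentationPolicy:
    """Preset for the synthetic phantoms (intensities normalised to [0, 1]).

    Geometric transforms at the generic settings; intensity jitter narrowed
    to the normalised scale so class-mean separations (the phantoms' tissue
    contrast) are perturbed, not erased.
    """
    return AugmentationPolicy(
        rotation2d=_ts(0.20, (-20, 20)),
        scaling=_ts(0.20, (0.7, 1.3)),
        white_noise=_ts(0.10, (0.0, 0.15)),
        streak_noise=_ts(0.0, (0.0, 0.70)),
        brightness=_ts(0.15, (-0.05, 0.05)),
        contrast=_ts(0.15, (0.95, 1.05)),
    )


PRESETS: dict[str, Callable[[], AugmentationPolicy]] = {
    "identity": identity_policy,
    "generic": generic_policy,
    "mandible": mandible_policy,
    "fetal": fetal_policy,
    "phantom": phantom_policy,
}


# ---------------------------------------------------------------------------
# Individual transforms


def _geom_pair(img: np.ndarray, lab: np.ndarray, matrix, offset, out_shape):
    img_t = ndimage.affine_transform(
        img.astype(np.float32), matrix, offset=offset, output_shape=out_shape,
        order=1, mode="nearest",
    )
    lab_t = ndimage.affine_transform(
        lab, matrix, offset=offset, output_shape=out_shape, order=0, mode="nearest"
    )
    return img_t, lab_t


def rotate_pair_2d(img: np.ndarray, lab: np.ndarray, angle_deg: float):
    """Rotate an image/label patch pair about its centre, shape preserved."""
    a = np.deg2rad(angle_deg)
    R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    centre = (np.array(img.shape, float) - 1) / 2
    offset = centre - R @ centre
    return _geom_pair(img, lab, R, offset, img.shape)


def scale_pair(img: np.ndarray, lab: np.ndarray, factor: float):
    """Zoom about the patch centre by ``factor`` (>1 enlarges), shape preserved."""
    M = np.eye(2) / factor
    centre = (np.array(img.shape, float) - 1) / 2
    offset = centre - M @ centre
    return _geom_pair(img, lab, M, offset, img.shape)


def apply_white_noise(patch: np.ndarray, amplitude_fraction: float, rng: np.random.Generator):
    """Additive per-pixel noise drawn U(-A, A), A a fraction of the patch range."""
    A = amplitude_fraction * float(patch.max() - patch.min())
    return patch + rng.uniform(-A, A, size=patch.shape).astype(np.float32)


def apply_streak_noise(
    patch: np.ndarray,
    amplitude_fraction: float,
    rng: np.random.Generator,
    n_streaks: int | None = None,
):
    """Add constant offsets to a few whole rows/columns, mimicking CT streaks.

    Each streak picks a full row or column uniformly and shifts it by a
    constant drawn U(-A, A) with A = ``amplitude_fraction`` x patch range.
    Pixels off the streaks are returned bit-identical.
    """
    if not 0.0 <= amplitude_fraction <= 1.0:
        raise ValidationError("amplitude_fraction must be in [0, 1]")
    out = patch.astype(np.float32, copy=True)
    A = amplitude_fraction * float(patch.max() - patch.min())
    if n_streaks is None:
        n_streaks = int(rng.integers(1, 5))
    for _ in range(n_streaks):
        axis = int(rng.integers(0, 2))
        idx = int(rng.integers(0, patch.shape[axis]))
        offset = np.float32(rng.uniform(-A, A))
        if axis == 0:
            out[idx, :] += offset
        else:
            out[:, idx] += offset
    return out


def apply_brightness(patch: np.ndarray, offset: float):
    return patch + np.float32(offset)


def apply_contrast(patch: np.ndarray, factor: float):
    """Scale contrast about the patch mean: x -> mean + f * (x - mean)."""
    m = np.float32(patch.mean())
    return m + np.float32(factor) * (patch - m)


def _gaussian_kernel_blur(patch: np.ndarray, size: int):
    # filter size in pixels; sigma tied to size so the kernel fills its support
    sigma = max((size - 1) / 4.0, 1e-3)
    radius = (int(size) - 1) // 2
    return ndimage.gaussian_filter(
        patch.astype(np.float32), sigma=sigma, radius=radius, mode="nearest"
    )


def apply_sharpening(patch: np.ndarray, strength: float):
    """Unsharp masking: x + s * (x - blur(x))."""
    blurred = _gaussian_kernel_blur(patch, 3)
    return patch + np.float32(strength) * (patch.astype(np.float32) - blurred)


# ---------------------------------------------------------------------------
# Global 3D rotation (volume level)


def rotate_volume_3d(
    vol: ImageVolume,
    lab: LabelVolume,
    angle_deg: float,
    rng: np.random.Generator,
    axis: np.ndarray | None = None,
) -> tuple[ImageVolume, LabelVolume]:
    """Rotate a whole volume/label pair about a random axis through its centre.

    The rotation axis is drawn uniformly on the sphere (unless given), the
    image is interpolated linearly and the labels nearest-neighbour with the
    identical transform; shape is preserved and out-of-field voxels take the
    edge value.
    """
    if axis is None:
        v = rng.normal(size=3)
        axis = v / np.linalg.norm(v)
    else:
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)  # Rodrigues
    centre = (np.array(vol.shape, float) - 1) / 2
    offset = centre - R @ centre
    img_t = ndimage.affine_transform(
        vol.data.astype(np.float32), R, offset=offset, order=1, mode="nearest"
    )
    lab_t = ndimage.affine_transform(lab.data, R, offset=offset, order=0, mode="nearest")
    return (
        ImageVolume(img_t, vol.spacing, vol.units),
        LabelVolume(lab_t, lab.spacing, lab.class_names),
    )


# ---------------------------------------------------------------------------
# Per-patch pipeline


def draw_transform_plan(
    policy: AugmentationPolicy, rng: np.random.Generator
) -> list[tuple[str, float | None]]:
    """Draw which patch-level transforms activate and their parameters.

    One uniform activation draw per transform in the canonical order, then
    one parameter draw per activated transform that has a range — a fixed
    draw structure so a seed reproduces the exact plan.
    """
    plan: list[tuple[str, float | None]] = []
    for name in TRANSFORM_ORDER:
        s = policy.setting(name)
        if rng.random() < s.probability:
            param = None
            if s.range is not None:
                param = float(rng.uniform(s.range[0], s.range[1]))
            plan.append((name, param))
    return plan


def apply_plan(
    patch: np.ndarray,
    label_patch: np.ndarray,
    plan: list[tuple[str, float | None]],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply an explicit transform plan to an image/label patch pair."""
    img, lab = patch, label_patch
    for name, param in plan:
        if name == "rotation2d":
            img, lab = rotate_pair_2d(img, lab, param)
        elif name == "scaling":
            img, lab = scale_pair(img, lab, param)
        elif name == "mirror_h":
            img, lab = img[:, ::-1], lab[:, ::-1]
        elif name == "mirror_v":
            img, lab = img[::-1, :], lab[::-1, :]
        elif name == "transpose":
            img, lab = img.T, lab.T
        elif name == "white_noise":
            img = apply_white_noise(img, param, rng)
        elif name == "streak_noise":
            img = apply_streak_noise(img, param, rng)
        elif name == "brightness":
            img = apply_brightness(img, param)
        elif name == "contrast":
            img = apply_contrast(img, param)
        elif name == "gaussian_blur":
            img = _gaussian_kernel_blur(img, int(round(param)))
        elif name == "sharpening":
            img = apply_sharpening(img, param)
        else:
            raise ValidationError(f"unknown transform {name!r}")
    return np.ascontiguousarray(img), np.ascontiguousarray(lab)


def augment_pair(
    patch: np.ndarray,
    label_patch: np.ndarray,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Stochastically augment one image/label patch pair.

    Every transform activates independently with its policy probability;
    geometric transforms are applied to both grids, intensity transforms to
    the image only. Shapes are preserved; an all-zero policy returns the
    inputs unchanged.
    """
    if patch.shape != label_patch.shape:
        raise ValidationError("patch and label_patch must share a shape")
    plan = draw_transform_plan(policy, rng)
    if not plan:
        return patch, label_patch
    return apply_plan(patch, label_patch, plan, rng)


__all__ = [
    "AugmentationPolicy",
    "TransformSetting",
    "TRANSFORM_ORDER",
    "GEOMETRIC",
    "PRESETS",
    "identity_policy",
    "generic_policy",
    "mandible_policy",
    "fetal_policy",
    "phantom_policy",
    "augment_pair",
    "apply_plan",
    "draw_transform_plan",
    "rotate_pair_2d",
    "scale_pair",
    "rotate_volume_3d",
    "apply_white_noise",
    "apply_streak_noise",
    "apply_brightness",
    "apply_contrast",
    "apply_sharpening",
]
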