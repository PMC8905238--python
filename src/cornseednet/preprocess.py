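"""Chip data augmentation and stratified train/test splitting.

Augmentation covers the three operations used for single-seed image decks:
brightness adjustment (multiplicative, all 4 channels), rotation (multiples
of 90 degrees are lossless; other angles resample bilinearly about the chip
centre) and additive Gaussian noise.  Augmentation never changes a chip's
label or shape.

Splitting and augmentation are separate steps composed by the caller.  The
recommended order is split first, then augment the training set only, so
augmented copies of one seed can never straddle the train/test boundary;
augmenting the full pool before splitting reproduces pipelines that report
a split of the augmented dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import rotate as _sk_rotate

from .segmentation import SeedChip

VALID_OPS = ("brightness", "rotate", "noise")


@dataclass
class AugmentationSpec:
    brightness_deltas: tuple = (0.8, 1.2)     # multiplicative factors
    rotation_angles: tuple = (90, 180, 270)   # degrees
    gaussian_sigma: float = 5.0               # 8-bit noise std
    target_per_class: int = None
    rng_seed: int = 0

    def __post_init__(self):
        if any(f <= 0 for f in self.brightness_deltas):
            raise ValueError("brightness factors must be > 0")
        if any(not (0 <= a < 360) for a in self.rotation_angles):
            raise ValueError("rotation angles must lie in [0, 360)")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")

    def single_ops(self):
        ops = [("brightness", f) for f in self.brightness_deltas]
        ops += [("rotate", a) for a in self.rotation_angles]
        if self.gaussian_sigma > 0:
            ops.append(("noise", self.gaussian_sigma))
        return ops


def _rotate_plane(plane: np.ndarray, angle: float, order: int) -> np.ndarray:
    k = angle / 90.0
    if k == int(k):
        return np.rot90(plane, int(k))
    return _sk_rotate(plane.astype(np.float64), angle, order=order, mode="edge",
                      preserve_range=True)


def augment_chip(chip: SeedChip, op, rng: np.random.Generator = None) -> SeedChip:
    """Apply one augmentation ``(kind, value)``; label and shape are preserved."""
    kind, value = op
    px = chip.pixels.astype(np.float64)
    mask = chip.mask
    if kind == "brightness":
        px = px * float(value)
    elif kind == "rotate":
        px = np.stack([_rotate_plane(px[:, :, c], value, order=1) for c in range(4)], axis=2)
        if mask is not None:
            mask = _rotate_plane(mask.astype(float), value, order=0) > 0.5
    elif kind == "noise":
        if rng is None:
            raise ValueError("noise augmentation requires an rng")
        if value > 0:
            px = px + rng.normal(0.0, float(value), px.shape)
    else:
        raise ValueError(f"unknown augmentation op {kind!r}; expected one of {VALID_OPS}")
    px = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    return SeedChip(px, label=chip.label, mask=mask,
                    instance_id=chip.instance_id, source=chip.source)


def build_augmented_dataset(chips, spec: AugmentationSpec = None):
    """Grow each class to ``target_per_class`` chips (originals always kept).

    Without a target, every single-op augmentation is applied to every chip
    once.  With a target, (chip, op) pairs are sampled deterministically
    under ``rng_seed`` until each class reaches the target; a target at or
    below the existing class size returns the originals unchanged (never
    subsamples).
    """
    spec = spec or AugmentationSpec()
    rng = np.random.default_rng(spec.rng_seed)
    ops = spec.single_ops()
    out = list(chips)
    if spec.target_per_class is None:
        for chip in chips:
            for op in ops:
                out.append(augment_chip(chip, op, rng))
        return out
    by_class = {}
    for chip in chips:
        by_class.setdefault(chip.label, []).append(chip)
    for label in sorted(by_class):
        pool = by_class[label]
        need = spec.target_per_class - len(pool)
        for _ in range(max(0, need)):
            chip = pool[int(rng.integers(len(pool)))]
            op = ops[int(rng.integers(len(ops)))]
            out.append(augment_chip(chip, op, rng))
    for label, pool in by_class.items():
        if not pool and spec.target_per_class > 0:
            raise ValueError(f"class {label!r} is empty but target_per_class is set")
    return out


def split_dataset(chips, test_fraction: float = 0.25, rng_seed: int = 0):
    """Stratified, deterministic train/test split.

    The total test size is round(n x test_fraction) (half away from zero),
    distributed over classes by largest remainder, so per-class sizes are
    within one chip of the exact fractions.  Default 0.25 matches printed
    whole-dataset counts of 5,869 train / 1,957 test out of 7,826.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    by_class = {}
    for chip in chips:
        by_class.setdefault(chip.label, []).append(chip)
    for label, pool in by_class.items():
        if len(pool) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 chips; cannot split")
    labels = sorted(by_class)
    n_total = len(chips)
    n_test_total = int(np.floor(n_total * test_fraction + 0.5))
    exact = {lab: len(by_class[lab]) * test_fraction for lab in labels}
    n_test = {lab: int(np.floor(exact[lab])) for lab in labels}
    remainder = n_test_total - sum(n_test.values())
    # distribute leftover test slots by largest fractional part (ties: label order)
    order = sorted(labels, key=lambda lab: (-(exact[lab] - n_test[lab]), lab))
    for lab in order[:max(0, remainder)]:
        n_test[lab] += 1
    rng = np.random.default_rng(rng_seed)
    train, test = [], []
    for lab in labels:
        pool = by_class[lab]
        perm = rng.permutation(len(pool))
        k = min(n_test[lab], len(pool) - 1)
        test += [pool[i] for i in perm[:k]]
        train += [pool[i] for i in perm[k:]]
    return train, test
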