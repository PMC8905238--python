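"""Synthetic backlit corn-seed scenes with exact per-seed ground truth.

Real corn-seed scenes are captured on a white backlit panel with front
lighting: a bright background, dozens of yellow-orange kernels, occasional
adhesion (seeds touching), and defect seeds carrying dark mold/damage
blotches.  No public dataset of such scenes exists, so this module generates
scenes with the same structure and full ground truth (per-seed masks, class
labels, centroids), which makes the segmentation, classification and
evaluation stages testable end to end.

What the generator emulates — and what it does not — is documented in
``docs/methods.md``.  Briefly: seeds are truncated ellipses (convex, so the
distance-transform marker construction is exact), defects are dark blotches
plus an optional boundary notch, and the NIR channel is a deterministic RGB
mixture that is *additionally* attenuated inside blotches, so the fourth
channel carries class signal beyond what RGB contains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage as ndi

from .msimage import (
    DatasetManifest,
    ManifestEntry,
    MultispectralImage,
    write_manifest,
    write_multispectral,
)
from .segmentation import SeedChip, resize_chip

# NIR = clip(0.45 R + 0.1 G + 0.45 B) inside seed masks, then darkened by a
# defect-specific factor in blotch areas.
NIR_WEIGHTS = (0.45, 0.10, 0.45)


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene (defaults emulate the imaging rig)."""

    width: int = 1296
    height: int = 964
    n_seeds: int = 20
    defect_fraction: float = 0.5
    adhesion_prob: float = 0.3
    seed_axis_range: tuple = (22, 40)      # semi-axis length range, px
    background_level: int = 230            # bright backlit panel
    noise_sigma: float = 3.0               # 8-bit Gaussian noise std
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_seeds < 0:
            raise ValueError("n_seeds must be >= 0")
        lo, hi = self.seed_axis_range
        if not (2 <= lo <= hi):
            raise ValueError(f"seed_axis_range must satisfy 2 <= min <= max, got {self.seed_axis_range}")
        for name in ("defect_fraction", "adhesion_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0 <= self.background_level <= 255):
            raise ValueError("background_level must be an 8-bit intensity")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class SceneGroundTruth:
    """Per-seed scene-sized masks, class labels and centroids of one scene."""

    masks: list = field(default_factory=list)
    labels: list = field(default_factory=list)
    centroids: list = field(default_factory=list)

    def __len__(self):
        return len(self.masks)

    def label_image(self) -> np.ndarray:
        """0 = background, k = seed k (later-placed seeds win overlap pixels)."""
        if not self.masks:
            raise ValueError("empty ground truth")
        out = np.zeros(self.masks[0].shape, dtype=np.uint16)
        for k, m in enumerate(self.masks, start=1):
            out[m] = k
        return out


def render_seed(axis_a: float, axis_b: float, orientation: float, defect: bool,
                rng: np.random.Generator):
    """Render one seed as (mask, 4-channel patch).

    The mask is a filled ellipse with semi-axes ``axis_a >= axis_b``,
    truncated by a chord at one end to mimic the flat kernel tip (the shape
    stays convex).  RGB inside the mask is a smoothly textured yellow-orange;
    defect seeds get 1-3 dark blotches (and sometimes a boundary notch), and
    the NIR mixture is further attenuated inside blotches.
    """
    if not (axis_a >= axis_b >= 2):
        raise ValueError(f"axes must satisfy a >= b >= 2, got a={axis_a}, b={axis_b}")
    half = int(math.ceil(axis_a)) + 3
    size = 2 * half + 1
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(np.float64)
    ct, st = math.cos(orientation), math.sin(orientation)
    u = ct * xx + st * yy
    v = -st * xx + ct * yy
    rho2 = (u / axis_a) ** 2 + (v / axis_b) ** 2
    tip = rng.uniform(0.75, 0.95)
    mask = (rho2 <= 1.0) & (u >= -tip * axis_a)

    base = np.array([rng.uniform(195, 225), rng.uniform(150, 185), rng.uniform(75, 105)])
    texture = ndi.gaussian_filter(rng.standard_normal((size, size)), sigma=3.0)
    tmax = np.abs(texture).max()
    if tmax > 0:
        texture = texture / tmax * 8.0
    shade = 1.0 - 0.15 * np.clip(rho2, 0.0, 1.0)
    rgb = base[None, None, :] * shade[:, :, None] + texture[:, :, None]

    blotch = np.zeros((size, size), dtype=bool)
    if defect:
        n_blotch = int(rng.integers(1, 4))
        for _ in range(n_blotch):
            u0 = rng.uniform(-0.55, 0.55) * axis_a
            v0 = rng.uniform(-0.55, 0.55) * axis_b
            r = rng.uniform(0.18, 0.32) * axis_b
            blotch |= ((u - u0) ** 2 + (v - v0) ** 2) <= r ** 2
        blotch &= mask
        delta = rng.uniform(85, 120)
        rgb[blotch] -= delta
        if rng.random() < 0.4:
            # boundary notch: shallow bite at the mask edge (kept small so
            # the seed remains effectively convex for marker extraction)
            phi = rng.uniform(0.0, 2.0 * math.pi)
            nu, nv = axis_a * math.cos(phi), axis_b * math.sin(phi)
            nr = rng.uniform(0.08, 0.12) * axis_b
            mask &= ((u - nu) ** 2 + (v - nv) ** 2) > nr ** 2
            blotch &= mask

    rgb = np.clip(rgb, 1.0, 255.0)
    nir = NIR_WEIGHTS[0] * rgb[:, :, 0] + NIR_WEIGHTS[1] * rgb[:, :, 1] + NIR_WEIGHTS[2] * rgb[:, :, 2]
    if defect:
        nir[blotch] *= rng.uniform(0.5, 0.7)
    patch = np.concatenate([rgb, np.clip(nir, 0, 255)[:, :, None]], axis=2)
    patch[~mask] = 0.0
    return mask, np.clip(np.rint(patch), 0, 255).astype(np.uint8)


_ADJ = np.ones((3, 3), dtype=bool)


def _touches(window: np.ndarray, dmask: np.ndarray) -> bool:
    return bool(np.any(window[dmask]))


def generate_scene(spec: SceneSpec):
    """Generate one scene; returns (MultispectralImage, SceneGroundTruth).

    Seeds are placed by rejection sampling (budget 1,000 attempts per seed).
    Non-adherent seeds are pairwise disjoint and not touching; with
    probability ``adhesion_prob`` a seed is instead slid along a random
    direction towards a previously placed seed until their masks share an
    8-connected border, with mask overlap below 10% of the new seed's area.
    Gaussian noise is added last and clipped to [0, 255].
    """
    rng = np.random.default_rng(spec.rng_seed)
    H, W = spec.height, spec.width
    scene = np.full((H, W, 4), float(spec.background_level), dtype=np.float64)
    occ = np.zeros((H, W), dtype=np.uint16)
    truth = SceneGroundTruth()
    placed = []  # (centroid_row, centroid_col, max_axis)

    lo, hi = spec.seed_axis_range
    for i in range(spec.n_seeds):
        a = rng.uniform(lo, hi)
        b = float(np.clip(a * rng.uniform(0.55, 0.85), 2.0, a))
        orientation = rng.uniform(0.0, math.pi)
        defect = bool(rng.random() < spec.defect_fraction)
        mask, patch = render_seed(a, b, orientation, defect, rng)
        dmask = ndi.binary_dilation(mask, structure=_ADJ)
        ph, pw = mask.shape
        area = int(mask.sum())

        attempts = 0
        pos = None
        adhere = i > 0 and rng.random() < spec.adhesion_prob
        while pos is None:
            attempts += 1
            if attempts > 1000:
                raise RuntimeError(
                    f"failed to place seed {i + 1}/{spec.n_seeds} within 1,000 attempts; "
                    "scene too crowded"
                )
            if adhere:
                j = int(rng.integers(len(placed)))
                ar, ac, amax = placed[j]
                theta = rng.uniform(0.0, 2.0 * math.pi)
                dy, dx = math.sin(theta), math.cos(theta)
                found = None
                for d in range(int(math.ceil(amax + a + 4)), 0, -1):
                    cr, cc = ar + d * dy, ac + d * dx
                    r0 = int(round(cr)) - ph // 2
                    c0 = int(round(cc)) - pw // 2
                    if r0 < 1 or c0 < 1 or r0 + ph > H - 1 or c0 + pw > W - 1:
                        continue
                    window = occ[r0:r0 + ph, c0:c0 + pw]
                    if _touches(window, dmask):
                        overlap = np.count_nonzero(window[mask])
                        if overlap < 0.10 * area:
                            found = (r0, c0)
                        break
                if found is not None:
                    pos = found
            else:
                if ph >= H - 2 or pw >= W - 2:
                    raise RuntimeError("seed patch larger than scene")
                r0 = int(rng.integers(1, H - ph - 1))
                c0 = int(rng.integers(1, W - pw - 1))
                window = occ[r0:r0 + ph, c0:c0 + pw]
                if not _touches(window, dmask):
                    pos = (r0, c0)

        r0, c0 = pos
        region = scene[r0:r0 + ph, c0:c0 + pw]
        region[mask] = patch[mask]
        occ[r0:r0 + ph, c0:c0 + pw][mask] = i + 1
        full_mask = np.zeros((H, W), dtype=bool)
        full_mask[r0:r0 + ph, c0:c0 + pw] = mask
        rows, cols = np.nonzero(full_mask)
        truth.masks.append(full_mask)
        truth.labels.append("bad" if defect else "good")
        truth.centroids.append((float(rows.mean()), float(cols.mean())))
        placed.append((rows.mean(), cols.mean(), a))

    if spec.noise_sigma > 0:
        scene = scene + rng.normal(0.0, spec.noise_sigma, scene.shape)
    img = MultispectralImage(np.clip(np.rint(scene), 0, 255).astype(np.uint8))
    return img, truth


def generate_chips(n_chips: int, defect_fraction: float = 0.5, rng_seed: int = 0,
                   size: int = 224, seed_axis_range=(22, 40),
                   background_level: int = 230, noise_sigma: float = 3.0):
    """Render single-seed chips directly (no scene compositing).

    Convenience generator for classifier experiments: each chip is one seed
    on a background-level fill, noised, bilinearly resized to ``size`` with
    its mask and label attached.
    """
    rng = np.random.default_rng(rng_seed)
    lo, hi = seed_axis_range
    chips = []
    for _ in range(n_chips):
        a = rng.uniform(lo, hi)
        b = float(np.clip(a * rng.uniform(0.55, 0.85), 2.0, a))
        defect = bool(rng.random() < defect_fraction)
        mask, patch = render_seed(a, b, rng.uniform(0.0, math.pi), defect, rng)
        canvas = patch.astype(np.float64)
        canvas[~mask] = background_level
        if noise_sigma > 0:
            canvas = canvas + rng.normal(0.0, noise_sigma, canvas.shape)
        canvas = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
        px = resize_chip(canvas, size)
        from skimage.transform import resize as _resize
        cmask = _resize(mask.astype(float), (size, size), order=0,
                        mode="edge", anti_aliasing=False) > 0.5
        chips.append(SeedChip(px, label="bad" if defect else "good", mask=cmask))
    return chips


def truth_instances(truth: SceneGroundTruth):
    """View each ground-truth mask as a :class:`SeedInstance` (ids 1..n)."""
    from .segmentation import SeedInstance

    instances = []
    for k, m in enumerate(truth.masks, start=1):
        rows, cols = np.nonzero(m)
        bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
        instances.append(SeedInstance(k, m, bbox, (float(rows.mean()), float(cols.mean()))))
    return instances


def chips_from_scene(img, truth: SceneGroundTruth, size: int = 224):
    """Labelled chips cut from a scene along its ground-truth masks.

    Uses the same bbox-crop / background-fill / bilinear-resize processing as
    the segmentation stage's chip extractor, so classifiers trained on these
    chips see the distribution the detection pipeline produces.
    """
    from .segmentation import extract_chips

    chips = extract_chips(img, truth_instances(truth), size=size)
    for chip, label in zip(chips, truth.labels):
        chip.label = label
    return chips


def generate_scene_chips(n_chips: int, spec: SceneSpec = None, size: int = 224):
    """Generate scenes and harvest ground-truth-labelled chips until
    ``n_chips`` are collected.  Scene i uses rng_seed = spec.rng_seed + i."""
    spec = spec or SceneSpec()
    chips = []
    i = 0
    while len(chips) < n_chips:
        img, truth = generate_scene(replace(spec, rng_seed=spec.rng_seed + i))
        chips.extend(chips_from_scene(img, truth, size=size))
        i += 1
    return chips[:n_chips]


def write_ground_truth(truth: SceneGroundTruth, label_png, csv_path) -> None:
    """Write truth as a 16-bit label PNG plus a (seed id, label, centroid) CSV."""
    Image.fromarray(truth.label_image()).save(label_png)
    with open(csv_path, "w") as fh:
        fh.write("seed_id,label,row,col\n")
        for k, (lab, (r, c)) in enumerate(zip(truth.labels, truth.centroids), start=1):
            fh.write(f"{k},{lab},{r:.2f},{c:.2f}\n")


def read_ground_truth(label_png, csv_path) -> SceneGroundTruth:
    """Load truth written by :func:`write_ground_truth` (overlap pixels go to
    the later-placed seed, so reloaded masks are disjoint)."""
    import pandas as pd

    lab_img = np.asarray(Image.open(label_png), dtype=np.uint16)
    df = pd.read_csv(csv_path)
    truth = SceneGroundTruth()
    for _, row in df.iterrows():
        k = int(row["seed_id"])
        truth.masks.append(lab_img == k)
        truth.labels.append(str(row["label"]))
        truth.centroids.append((float(row["row"]), float(row["col"])))
    return truth


def generate_dataset(spec: SceneSpec, n_scenes: int, out_dir) -> DatasetManifest:
    """Write ``n_scenes`` scenes + ground truth + a manifest CSV to ``out_dir``.

    Scene ``i`` uses ``rng_seed = spec.rng_seed + i``, so the dataset is fully
    reproducible from the spec.
    """
    out_dir = Path(out_dir)
    if not out_dir.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {out_dir}")
    entries = []
    for i in range(n_scenes):
        img, truth = generate_scene(replace(spec, rng_seed=spec.rng_seed + i))
        stem = f"scene_{i:03d}"
        write_multispectral(img, out_dir / f"{stem}.tiff")
        if len(truth):
            write_ground_truth(truth, out_dir / f"{stem}_truth.png", out_dir / f"{stem}_truth.csv")
            truth_ref = f"{stem}_truth.png"
        else:
            truth_ref = None
        entries.append(ManifestEntry(image=f"{stem}.tiff", truth=truth_ref))
    manifest = DatasetManifest(entries=entries, root=str(out_dir))
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
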