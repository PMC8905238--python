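"""Marker-based watershed segmentation of touching seeds.

Seeds are imaged on a bright backlit panel, so they appear dark against the
background.  The pipeline follows the classic marker-controlled watershed
recipe for touching convex objects:

1. Otsu-binarize the blue channel (the channel with the strongest
   seed/background contrast in backlit corn-seed scenes).
2. Remove speck noise with a morphological opening.
3. Dilate the cleaned mask; its complement is sure background.
4. Threshold the Euclidean distance transform at a fraction of each seed's
   own distance maximum to obtain one sure-foreground marker per seed
   (per-seed maxima are h-maxima of the distance transform, since touching
   seeds share one connected component; the superlevel set of the distance
   transform of a convex region is connected, so a lone seed always yields
   exactly one marker, while two touching seeds pinch apart into two).
5. Flood the inverted distance transform from the markers; the watershed
   ridge splits merged components at the adhesion line.

Each instance is reported with its scene-sized mask, tight bounding box
(0-based, half-open) and centroid, so the NIR plane can be cropped with the
same coordinates as the RGB planes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk, h_maxima
from skimage.segmentation import watershed
from skimage.transform import resize

from .msimage import NOMINAL_HEIGHT, NOMINAL_WIDTH, MultispectralImage, channel


@dataclass
class SegmentationParams:
    """Knobs of the watershed pipeline.

    ``min_area`` is expressed at the nominal 1296 x 964 scene scale and is
    rescaled by the actual scene area, so the same parameter set works on
    downscaled scenes.
    """

    open_kernel: int = 3          # structuring-element radius, px (elliptical/disk)
    open_iterations: int = 2      # erosions then dilations, cv2-style opening
    dilate_iterations: int = 3
    dist_frac: float = 0.5        # fraction of per-seed EDT maximum
    marker_depth: float = 2.0     # h-maxima depth separating seed centres, px
    valley_depth: float = 1.75    # 8-bit intensity dip marking a seed-seed contact
    min_area: int = 200           # px at nominal scene scale
    invert: bool = True           # seeds darker than background

    def __post_init__(self):
        if not (0.0 < self.dist_frac < 1.0):
            raise ValueError(f"dist_frac must be in (0, 1), got {self.dist_frac}")
        if self.marker_depth <= 0:
            raise ValueError(f"marker_depth must be > 0, got {self.marker_depth}")
        for name in ("open_kernel", "open_iterations", "dilate_iterations", "min_area"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SeedInstance:
    """One segmented seed: label id, scene-sized mask, bbox and centroid."""

    instance_id: int
    mask: np.ndarray                       # scene-sized bool
    bbox: tuple                            # (row_min, col_min, row_max, col_max), half-open
    centroid: tuple                        # (row, col) floats

    @property
    def area(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass
class SeedChip:
    """A single-seed 4-channel chip (default 224 x 224) plus its class label."""

    pixels: np.ndarray                     # size x size x 4 uint8
    label: Optional[str] = None            # "good" | "bad"
    mask: Optional[np.ndarray] = None      # size x size bool, seed support
    instance_id: Optional[int] = None
    source: Optional[str] = None

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 4:
            raise ValueError(f"chip must be H x W x 4, got {px.shape}")
        self.pixels = px.astype(np.uint8)
        if self.label is not None and self.label not in ("good", "bad"):
            raise ValueError(f"label must be 'good' or 'bad', got {self.label!r}")


def binarize(img: MultispectralImage, params: SegmentationParams = None) -> np.ndarray:
    """Otsu-threshold the B channel; foreground (seed) pixels become True."""
    params = params or SegmentationParams()
    b = channel(img, "B")
    if b.min() == b.max():
        raise ValueError("constant-intensity B channel: Otsu threshold is undefined")
    thr = threshold_otsu(b)
    return (b <= thr) if params.invert else (b > thr)


def clean_mask(mask: np.ndarray, params: SegmentationParams = None) -> np.ndarray:
    """Morphological opening (n erosions then n dilations) to remove specks."""
    params = params or SegmentationParams()
    if params.open_kernel == 0 or params.open_iterations == 0:
        return mask.astype(bool).copy()
    selem = disk(params.open_kernel)
    out = ndi.binary_erosion(mask.astype(bool), structure=selem,
                             iterations=params.open_iterations)
    return ndi.binary_dilation(out, structure=selem, iterations=params.open_iterations)


def _dilate(mask: np.ndarray, params: SegmentationParams) -> np.ndarray:
    if params.dilate_iterations == 0:
        return mask.astype(bool).copy()
    selem = disk(params.open_kernel) if params.open_kernel else disk(1)
    return ndi.binary_dilation(mask.astype(bool), structure=selem,
                               iterations=params.dilate_iterations)


_SHIFTS = ((0, 1), (1, 0), (1, 1), (1, -1))


def _boundary_pairs(basins: np.ndarray):
    """Adjacent-pixel pairs (8-connectivity) straddling two different basins.

    Yields per shift direction: basin ids (lo, hi) and the flat coordinates
    of the two pixels of each pair.
    """
    H, W = basins.shape
    for dr, dc in _SHIFTS:
        r0a, r1a = max(0, -dr), H - max(0, dr)
        c0a, c1a = max(0, -dc), W - max(0, dc)
        a = basins[r0a:r1a, c0a:c1a]
        b = basins[r0a + dr:r1a + dr, c0a + dc:c1a + dc]
        m = (a > 0) & (b > 0) & (a != b)
        if not m.any():
            continue
        ys, xs = np.nonzero(m)
        ya, xa = ys + r0a, xs + c0a
        yb, xb = ya + dr, xa + dc
        lo = np.minimum(a[m], b[m])
        hi = np.maximum(a[m], b[m])
        yield lo, hi, (ya, xa), (yb, xb)


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def compute_markers(mask: np.ndarray, params: SegmentationParams = None,
                    intensity: np.ndarray = None):
    """Derive (sure-foreground labels, sure-background mask, unknown mask).

    The central region of each seed is the distance transform thresholded at
    ``dist_frac`` x that seed's own distance maximum.  Because touching
    seeds merge into one connected component, per-seed maxima are located as
    h-maxima of the distance transform (depth ``marker_depth``: a seed's
    inradius towers over the shallow neck at an adhesion point, while
    fluctuations inside one convex seed stay below the depth), a
    preliminary watershed carves the component into one basin per maximum,
    and the threshold is applied per basin.  This per-seed normalisation
    keeps small seeds from being suppressed by a large touching neighbour.

    A distance maximum can also sit on the locally thickened junction of two
    deeply touching seeds; such spurious basins are absorbed by merging any
    two basins whose threshold cores meet at their shared boundary (the
    saddle rises above both core thresholds).  When ``intensity`` (the B
    channel) is given, the decision uses the image as well: a merge is
    vetoed if the shared boundary is at least ``valley_depth`` levels darker
    than the two basin cores along most of its length (75th percentile) —
    seeds darken toward their boundary, so a true seed-seed contact leaves a
    consistent dark valley, whereas a dark patch on a boundary inside one
    seed is a localised defect blotch and the rest of the boundary stays
    bright.  With the veto available, cores are also allowed to miss each
    other by up to ``marker_depth`` at the saddle before a merge is ruled
    out on geometry alone.

    Sure background is the complement of the dilated mask; the unknown band
    between it and the markers is what the final watershed flood assigns.
    The three regions partition the scene.
    """
    params = params or SegmentationParams()
    mask = mask.astype(bool)
    dilated = _dilate(mask, params)
    sure_bg = ~dilated
    sure_fg = np.zeros_like(mask)
    markers = np.zeros(mask.shape, dtype=np.int32)
    if mask.any():
        dist = ndi.distance_transform_edt(mask)
        peaks = h_maxima(dist, params.marker_depth, footprint=np.ones((3, 3), dtype=bool))
        peak_labels, n_peaks = ndi.label(peaks & mask, structure=np.ones((3, 3)))
        if n_peaks:
            basins = watershed(-dist, markers=peak_labels, mask=mask, connectivity=2)
            basin_max = ndi.maximum(dist, labels=basins, index=np.arange(1, n_peaks + 1))
            thr_map = np.zeros(n_peaks + 1)
            thr_map[1:] = params.dist_frac * np.asarray(basin_max)
            sure_fg = mask & (dist > thr_map[basins])

            # basin adjacency: do the two cores meet at the shared boundary,
            # and how dark is the boundary relative to the cores?
            touch = {}
            bnd_px = {}
            for lo, hi, (ya, xa), (yb, xb) in _boundary_pairs(basins):
                da = dist[ya, xa] - thr_map[basins[ya, xa]]
                db = dist[yb, xb] - thr_map[basins[yb, xb]]
                depth = np.minimum(da, db)
                for k in range(len(lo)):
                    key = (int(lo[k]), int(hi[k]))
                    if depth[k] > touch.get(key, -np.inf):
                        touch[key] = depth[k]
                if intensity is not None:
                    for k in range(len(lo)):
                        key = (int(lo[k]), int(hi[k]))
                        bnd_px.setdefault(key, []).append(
                            (intensity[ya[k], xa[k]] + intensity[yb[k], xb[k]]) / 2.0)

            uf = _UnionFind(n_peaks + 1)
            if intensity is not None:
                core_lab = np.where(sure_fg, basins, 0)
                core_med = ndi.median(intensity.astype(np.float64), labels=core_lab,
                                      index=np.arange(1, n_peaks + 1))
            for (i, j), depth in touch.items():
                if intensity is None:
                    if depth <= 0:
                        continue
                else:
                    if depth <= -params.marker_depth:
                        continue
                    dip = (0.5 * (core_med[i - 1] + core_med[j - 1])
                           - np.percentile(bnd_px[(i, j)], 75))
                    if dip >= params.valley_depth:
                        continue
                uf.union(i, j)
            relabel = np.zeros(n_peaks + 1, dtype=np.int32)
            next_id = 0
            roots = {}
            for i in range(1, n_peaks + 1):
                r = uf.find(i)
                if r not in roots:
                    next_id += 1
                    roots[r] = next_id
                relabel[i] = roots[r]
            markers = np.where(sure_fg, relabel[basins], 0).astype(np.int32)
    unknown = dilated & ~sure_fg
    return markers, sure_bg, unknown


def _scaled_min_area(params: SegmentationParams, shape) -> float:
    return params.min_area * (shape[0] * shape[1]) / (NOMINAL_HEIGHT * NOMINAL_WIDTH)


def watershed_segment(img: MultispectralImage, params: SegmentationParams = None):
    """Segment a scene into one :class:`SeedInstance` per seed.

    Floods the inverted distance transform from the sure-foreground markers
    over the dilated-foreground region, then restricts each basin to the
    cleaned mask so instance masks are pairwise disjoint seed pixels with no
    unlabeled foreground left.  Instances smaller than the (scene-scaled)
    ``min_area`` are dropped; ids are assigned in (row, col) centroid order.
    """
    params = params or SegmentationParams()
    mask = clean_mask(binarize(img, params), params)
    markers, sure_bg, unknown = compute_markers(mask, params, intensity=channel(img, "B"))
    instances = []
    if markers.max() > 0:
        dist = ndi.distance_transform_edt(mask)
        flood_region = ~sure_bg  # unknown + sure foreground
        labels = watershed(-dist, markers=markers, mask=flood_region, connectivity=2)
        min_area = _scaled_min_area(params, mask.shape)
        objects = ndi.find_objects(labels)
        for k, sl in enumerate(objects, start=1):
            if sl is None:
                continue
            inst_mask = np.zeros_like(mask)
            inst_mask[sl] = (labels[sl] == k) & mask[sl]
            area = np.count_nonzero(inst_mask)
            if area == 0 or area < min_area:
                continue
            rows, cols = np.nonzero(inst_mask)
            bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
            centroid = (float(rows.mean()), float(cols.mean()))
            instances.append(SeedInstance(0, inst_mask, bbox, centroid))
    instances.sort(key=lambda s: s.centroid)
    for i, inst in enumerate(instances, start=1):
        inst.instance_id = i
    return instances


def resize_chip(patch: np.ndarray, size: int) -> np.ndarray:
    """Bilinear per-channel resize of an H x W x C uint8 patch to size x size."""
    if patch.shape[0] == size and patch.shape[1] == size:
        return patch.copy()
    out = resize(
        patch.astype(np.float64),
        (size, size),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _background_median(img: MultispectralImage, instances) -> np.ndarray:
    bg = np.ones(img.pixels.shape[:2], dtype=bool)
    for inst in instances:
        bg &= ~inst.mask
    if not bg.any():
        bg[:] = True
    return np.median(img.pixels[bg], axis=0)


def extract_chips(img: MultispectralImage, instances, size: int = 224,
                  mask_background: bool = True):
    """Crop each instance's bbox from all 4 channels and resize to a chip.

    The NIR plane is cropped with the same coordinates as RGB.  Pixels inside
    the bbox but outside the instance mask are replaced by the scene
    background median (per channel) so that a neighbouring seed sharing the
    bbox cannot leak into the chip; set ``mask_background=False`` for raw
    crops.
    """
    chips = []
    if not instances:
        return chips
    fill = _background_median(img, instances) if mask_background else None
    for inst in instances:
        r0, c0, r1, c1 = inst.bbox
        assert 0 <= r0 < r1 <= img.height and 0 <= c0 < c1 <= img.width, "bbox outside image"
        patch = img.pixels[r0:r1, c0:c1].astype(np.float64)
        m = inst.mask[r0:r1, c0:c1]
        if mask_background:
            patch[~m] = fill
        chip_px = resize_chip(patch, size)
        chip_mask = resize(m.astype(float), (size, size), order=0,
                           mode="edge", anti_aliasing=False) > 0.5
        chips.append(
            SeedChip(chip_px, mask=chip_mask, instance_id=inst.instance_id,
                     source=img.source_path)
        )
    return chips
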