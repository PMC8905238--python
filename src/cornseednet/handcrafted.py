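"""Hand-crafted feature extractors and the SVM baseline classifier.

Five classical descriptors of a single-seed chip, used as baselines against
the two-pathway CNN:

* morphological characteristics (MC) of the seed mask — 5 values;
* RGB colour histogram over mask pixels — 3 x 16 bins;
* histogram of oriented gradients (HOG) of the grayscale chip;
* gray-level co-occurrence matrix (GLCM) statistics — contrast,
  dissimilarity, homogeneity, energy, correlation and angular second moment
  at distance 1 for 4 angles — 24 values;
* rotation-invariant uniform local binary patterns (LBP, P=8, R=1)
  histogrammed over mask pixels — 10 bins.

Geometry choices the source method leaves open (GLCM levels/angles, HOG cell
layout, LBP neighbourhood, bin counts, SVM kernel) are centralised in the
module-level constants below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix, graycoprops, hog, local_binary_pattern
from skimage.measure import regionprops
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .segmentation import SeedChip

COLOR_BINS = 16
GLCM_LEVELS = 32
GLCM_DISTANCES = (1,)
GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
GLCM_STATS = ("contrast", "dissimilarity", "homogeneity", "energy", "correlation", "ASM")
HOG_ORIENTATIONS = 9
HOG_CELL = (8, 8)
HOG_BLOCK = (2, 2)
LBP_P, LBP_R = 8, 1

METHODS = ("mc", "color", "hog", "glcm", "lbp")

# ITU-R 709 luminance of the RGB planes, rounded to uint8
_LUMA = np.array([0.2125, 0.7154, 0.0721])


@dataclass
class FeatureVector:
    values: np.ndarray
    method: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.method} features contain non-finite values")

    def __len__(self):
        return len(self.values)


def _gray(chip: SeedChip) -> np.ndarray:
    g = chip.pixels[:, :, :3].astype(np.float64) @ _LUMA
    return np.clip(np.rint(g), 0, 255).astype(np.uint8)


def _mask(chip: SeedChip) -> np.ndarray:
    if chip.mask is not None:
        if not chip.mask.any():
            raise ValueError("chip mask is empty")
        return chip.mask
    return np.ones(chip.pixels.shape[:2], dtype=bool)


def mc_features(chip: SeedChip) -> FeatureVector:
    """Five shape features of the seed mask.

    In order: perimeter / equivalent-circle diameter (pi for a perfect
    circle), equivalent-circle diameter sqrt(4 area / pi), eccentricity of
    the area-moment ellipse, major/minor axis ratio, and extent
    (area / bounding-box area).
    """
    mask = _mask(chip)
    rp = regionprops(mask.astype(np.uint8))[0]
    eq_diam = rp.equivalent_diameter_area
    minor = rp.axis_minor_length
    ratio = rp.axis_major_length / minor if minor > 0 else 1.0
    # Crofton perimeter: much smaller rasterisation bias than edge counting
    values = [rp.perimeter_crofton / eq_diam, eq_diam, rp.eccentricity, ratio, rp.extent]
    return FeatureVector(values, "mc")


def color_histogram(chip: SeedChip) -> FeatureVector:
    """Concatenated 16-bin R, G, B histograms over mask pixels, each sum-1."""
    mask = _mask(chip)
    feats = []
    for c in range(3):
        h, _ = np.histogram(chip.pixels[:, :, c][mask], bins=COLOR_BINS, range=(0, 256))
        feats.append(h / h.sum())
    return FeatureVector(np.concatenate(feats), "color")


def hog_features(chip: SeedChip) -> FeatureVector:
    """HOG of the grayscale chip: 9 orientations, 8x8 cells, 2x2 L2-Hys blocks."""
    g = _gray(chip)
    if g.shape[0] < 2 * HOG_CELL[0] or g.shape[1] < 2 * HOG_CELL[1]:
        raise ValueError(f"chip too small for HOG: {g.shape}")
    values = hog(g, orientations=HOG_ORIENTATIONS, pixels_per_cell=HOG_CELL,
                 cells_per_block=HOG_BLOCK, block_norm="L2-Hys", feature_vector=True)
    return FeatureVector(values, "hog")


def glcm_features(chip: SeedChip) -> FeatureVector:
    """24 GLCM statistics: 6 named stats x 4 angles, distance 1, 32 gray levels.

    Computed over the full chip (background pixels of a chip are a constant
    fill, and constant regions contribute only to the diagonal of the
    co-occurrence matrix).
    """
    levels = (_gray(chip).astype(np.int64) * GLCM_LEVELS) // 256
    m = graycomatrix(levels.astype(np.uint8), distances=GLCM_DISTANCES,
                     angles=GLCM_ANGLES, levels=GLCM_LEVELS, symmetric=True, normed=True)
    values = np.concatenate([graycoprops(m, s).ravel() for s in GLCM_STATS])
    return FeatureVector(values, "glcm")


def lbp_histogram(chip: SeedChip) -> FeatureVector:
    """Normalised 10-bin rotation-invariant uniform LBP histogram (P=8, R=1)
    over mask pixels; gray-shift invariant by construction."""
    mask = _mask(chip)
    codes = local_binary_pattern(_gray(chip), LBP_P, LBP_R, method="uniform")
    h, _ = np.histogram(codes[mask], bins=LBP_P + 2, range=(0, LBP_P + 2))
    return FeatureVector(h / h.sum(), "lbp")


_EXTRACTORS = {
    "mc": mc_features,
    "color": color_histogram,
    "hog": hog_features,
    "glcm": glcm_features,
    "lbp": lbp_histogram,
}


def extract_features(chips, method: str) -> np.ndarray:
    """Feature matrix (n_chips x d) for one named method."""
    if method not in _EXTRACTORS:
        raise KeyError(f"unknown method {method!r}; expected one of {METHODS}")
    return np.vstack([_EXTRACTORS[method](c).values for c in chips])


def train_svm_baseline(features: np.ndarray, labels, C: float = 1.0):
    """Fit a standardize + RBF-SVM pipeline (gamma = 1/(d * var), i.e. 'scale')."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    clf = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="rbf", C=C, gamma="scale", random_state=0)),
    ])
    clf.fit(np.asarray(features, dtype=np.float64), labels)
    return clf


def predict_svm(classifier, features: np.ndarray):
    """Predict "good"/"bad" labels for a feature matrix."""
    return classifier.predict(np.asarray(features, dtype=np.float64))
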