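"""4-channel (RGB + NIR) multispectral image I/O and dataset manifests.

Seed scenes are captured by a 4-channel multispectral camera (8 bits per
channel, nominal resolution 1296 x 964).  On disk a scene is stored either as
a paired ``<stem>.png`` (RGB) + ``<stem>_nir.png`` (single-channel NIR), or as
a single 4-sample-per-pixel 8-bit TIFF.  In memory the channel order is always
(R, G, B, NIR); BGR-style source orderings are normalised at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

CHANNEL_ROLES = ("R", "G", "B", "NIR")

NOMINAL_WIDTH = 1296
NOMINAL_HEIGHT = 964

VALID_LABELS = ("good", "bad")


@dataclass
class MultispectralImage:
    """An H x W x 4 unsigned 8-bit raster with fixed channel roles (R,G,B,NIR)."""

    pixels: np.ndarray
    channel_roles: tuple = CHANNEL_ROLES
    source_path: Optional[str] = None

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 4:
            raise ValueError(f"expected H x W x 4 raster, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have H >= 1 and W >= 1")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if tuple(self.channel_roles) != CHANNEL_ROLES:
            raise ValueError(f"channel_roles must be {CHANNEL_ROLES}")
        self.channel_roles = CHANNEL_ROLES

    @property
    def shape(self):
        return self.pixels.shape

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def channel(img: MultispectralImage, role: str) -> np.ndarray:
    """Return a copy of one channel plane; ``role`` is one of R, G, B, NIR."""
    if role not in CHANNEL_ROLES:
        raise KeyError(f"unknown channel role {role!r}; expected one of {CHANNEL_ROLES}")
    return img.pixels[:, :, CHANNEL_ROLES.index(role)].copy()


def _read_plane(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(str(path)))
    return np.asarray(Image.open(path))


def read_multispectral(rgb_path, nir_path=None) -> MultispectralImage:
    """Load a multispectral image from a paired RGB+NIR file or a 4-channel TIFF.

    ``rgb_path`` must be a 3-channel image accompanied by a single-channel
    ``nir_path`` of identical size, or a 4-channel TIFF on its own.  An NIR
    plane is never fabricated: a 3-channel file without ``nir_path`` is an
    error.
    """
    rgb_path = Path(rgb_path)
    arr = _read_plane(rgb_path)
    if arr.ndim == 3 and arr.shape[2] == 4:
        if nir_path is not None:
            raise ValueError("got a 4-channel file together with a separate NIR file")
        return MultispectralImage(arr.astype(np.uint8), source_path=str(rgb_path))
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{rgb_path}: expected a 3-channel image, got shape {arr.shape}")
    if nir_path is None:
        raise ValueError(
            f"{rgb_path} is 3-channel and no NIR source was provided; "
            "refusing to fabricate an NIR channel"
        )
    nir = _read_plane(nir_path)
    if nir.ndim == 3 and nir.shape[2] == 1:
        nir = nir[:, :, 0]
    if nir.ndim != 2:
        raise ValueError(f"{nir_path}: expected a single-channel image, got shape {nir.shape}")
    if nir.shape != arr.shape[:2]:
        raise ValueError(
            f"dimension mismatch: RGB is {arr.shape[:2]}, NIR is {nir.shape}"
        )
    px = np.dstack([arr.astype(np.uint8), nir.astype(np.uint8)])
    return MultispectralImage(px, source_path=str(rgb_path))


def nir_path_for(rgb_path) -> Path:
    """Paired-file naming convention: ``<stem>.png`` + ``<stem>_nir.png``."""
    rgb_path = Path(rgb_path)
    return rgb_path.with_name(rgb_path.stem + "_nir" + rgb_path.suffix)


def write_multispectral(img: MultispectralImage, path) -> None:
    """Write losslessly: 4-sample TIFF for ``.tif``/``.tiff``, else PNG pair."""
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), img.pixels, photometric="rgb", extrasamples=["unspecified"])
    else:
        Image.fromarray(img.pixels[:, :, :3]).save(path)
        Image.fromarray(img.pixels[:, :, 3]).save(nir_path_for(path))


MANIFEST_COLUMNS = ["image", "nir", "label", "truth", "split"]


@dataclass
class ManifestEntry:
    image: str
    nir: Optional[str] = None
    label: Optional[str] = None
    truth: Optional[str] = None
    split: Optional[str] = None


@dataclass
class DatasetManifest:
    """A list of scene/chip records: image path, optional NIR path, label, truth."""

    entries: list = field(default_factory=list)
    root: Optional[str] = None

    def __post_init__(self):
        for e in self.entries:
            if e.label is not None and e.label not in VALID_LABELS:
                raise ValueError(f"label must be one of {VALID_LABELS}, got {e.label!r}")
            if e.split is not None and e.split not in ("train", "test"):
                raise ValueError(f"split must be 'train' or 'test', got {e.split!r}")

    def __len__(self):
        return len(self.entries)

    def resolve(self, ref: str) -> Path:
        return Path(self.root) / ref if self.root else Path(ref)


def write_manifest(manifest: DatasetManifest, path) -> None:
    rows = [
        {c: getattr(e, c) if getattr(e, c) is not None else "" for c in MANIFEST_COLUMNS}
        for e in manifest.entries
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path, check_files: bool = True) -> DatasetManifest:
    """Load a manifest CSV (columns image,nir,label,truth,split).

    Referenced files are resolved relative to the manifest's directory and, by
    default, must exist.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns {missing}")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            ManifestEntry(
                image=row["image"],
                nir=row["nir"] or None,
                label=row["label"] or None,
                truth=row["truth"] or None,
                split=row["split"] or None,
            )
        )
    manifest = DatasetManifest(entries=entries, root=str(path.parent))
    if check_files:
        for e in manifest.entries:
            for ref in (e.image, e.nir, e.truth):
                if ref and not manifest.resolve(ref).exists():
                    raise FileNotFoundError(manifest.resolve(ref))
    return manifest
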