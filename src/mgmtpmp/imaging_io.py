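"""Reading, rescaling, resizing and indexing of 2-D grayscale MRI slices.

The working unit downstream of this module is an ``Image8``: a 2-D uint8
array (values 0..255), resized to 64x64 before feature extraction.  Native
inputs are 8-bit PNG/JPEG; 12-bit DICOM and NIfTI volumes are supported and
are linearly rescaled to 8 bits (full-scale map, not per-image min-max, so
intensities stay comparable across slices).

Datasets are laid out as two class folders::

    root/0/**   MGMT- slices
    root/1/**   MGMT+ slices

``index_dataset`` walks this layout into a :class:`DatasetIndex`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

#: file suffixes recognised as 2-D raster images
IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}
DICOM_SUFFIXES = {".dcm", ".dicom"}

DEFAULT_SIDE = 64


class DecodeError(RuntimeError):
    """Raised when a file cannot be decoded into an image."""


class LayoutError(RuntimeError):
    """Raised when a dataset directory does not follow the 0/1 class layout."""


@dataclass
class DatasetRecord:
    path: str
    label: int
    rejected: bool = False


@dataclass
class DatasetIndex:
    """Labeled inventory of slice files, one record per file.

    Class labels are restricted to {0, 1}; records are kept in deterministic
    lexicographic order so repeated indexing of an unchanged directory yields
    identical inventories.
    """

    records: list[DatasetRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            if rec.label not in (0, 1):
                raise ValueError(f"class label must be 0 or 1, got {rec.label}")
            if rec.path in seen:
                raise ValueError(f"duplicate path in index: {rec.path}")
            seen.add(rec.path)

    def class_counts(self, *, kept_only: bool = False) -> dict[int, int]:
        counts = {0: 0, 1: 0}
        for rec in self.records:
            if kept_only and rec.rejected:
                continue
            counts[rec.label] += 1
        return counts

    def kept(self) -> list[DatasetRecord]:
        return [r for r in self.records if not r.rejected]

    def __len__(self) -> int:
        return len(self.records)

    def to_json(self, path: str | Path) -> None:
        payload = [
            {"path": r.path, "label": r.label, "rejected": r.rejected}
            for r in self.records
        ]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DatasetIndex":
        payload = json.loads(Path(path).read_text())
        return cls([DatasetRecord(**row) for row in payload])


def validate_image8(img: np.ndarray) -> np.ndarray:
    """Check the Image8 contract: 2-D array of integers in [0, 255]."""
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"Image8 must be a non-empty 2-D array, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if np.any(arr < 0) or np.any(arr > 255):
            raise ValueError("Image8 values must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def rescale_to_8bit(raw: np.ndarray, bit_depth: int) -> np.ndarray:
    """Linearly map [0, 2^bit_depth - 1] onto [0, 255] with round-half-up.

    8-bit input is the identity.  Both endpoints map exactly (0 -> 0 and
    full scale -> 255); the map is monotone non-decreasing.
    """
    if bit_depth not in (8, 12, 16):
        raise ValueError(f"bit_depth must be one of 8, 12, 16; got {bit_depth}")
    arr = np.asarray(raw)
    if np.any(arr < 0):
        raise ValueError("pixel values must be non-negative")
    full = (1 << bit_depth) - 1
    if np.any(arr > full):
        raise ValueError(f"pixel value exceeds {bit_depth}-bit range (max {full})")
    if bit_depth == 8:
        return arr.astype(np.uint8)
    scaled = np.floor(arr.astype(np.float64) * 255.0 / full + 0.5)
    return scaled.astype(np.uint8)


def resize_to_input(img: np.ndarray, side: int = DEFAULT_SIDE) -> np.ndarray:
    """Resize to ``side`` x ``side`` by anti-aliased bilinear interpolation.

    Resizing an image already at the target side is the identity, which makes
    the operation idempotent at a fixed side.  Output values are clipped to
    [0, 255] and rounded half-up back to uint8.
    """
    from skimage.transform import resize

    arr = validate_image8(img)
    if side < 8:
        raise ValueError(f"target side must be >= 8, got {side}")
    if arr.shape == (side, side):
        return arr
    out = resize(
        arr.astype(np.float64),
        (side, side),
        order=1,
        anti_aliasing=True,
        preserve_range=True,
    )
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def _to_gray(arr: np.ndarray) -> np.ndarray:
    """Collapse a multi-channel raster to grayscale by unweighted channel mean."""
    if arr.ndim == 3:
        arr = np.floor(arr.astype(np.float64).mean(axis=2) + 0.5)
    if arr.ndim != 2:
        raise ValueError(f"expected 2-D raster, got shape {arr.shape}")
    return arr


def load_image(path: str | Path) -> np.ndarray:
    """Load a single 2-D slice as an Image8.

    PNG/JPEG are read directly; DICOM pixel data is rescaled from its stored
    bit depth; multi-channel rasters are converted by channel mean.
    """
    path = Path(path)
    if not path.exists():
        raise DecodeError(f"no such file: {path}")
    try:
        if path.suffix.lower() in DICOM_SUFFIXES:
            import pydicom

            ds = pydicom.dcmread(str(path))
            raw = ds.pixel_array
            if raw.ndim != 2:
                raise ValueError(f"expected a single-frame DICOM, got shape {raw.shape}")
            bits = int(getattr(ds, "BitsStored", 16))
            depth = 8 if bits <= 8 else (12 if bits <= 12 else 16)
            return rescale_to_8bit(raw, depth)
        arr = iio.imread(path)
    except DecodeError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface the offending path
        raise DecodeError(f"cannot decode image file {path}: {exc}") from exc
    arr = _to_gray(np.asarray(arr))
    if arr.dtype == np.uint8 or arr.max(initial=0) <= 255:
        return validate_image8(arr)
    depth = 12 if arr.max() < (1 << 12) else 16
    return rescale_to_8bit(arr.astype(np.int64), depth)


def load_volume_slices(path: str | Path) -> list[np.ndarray]:
    """Slice a 3-D NIfTI (or multi-frame DICOM) volume along its last axis.

    Returns one Image8 per slice, rescaled from the volume's dynamic range
    treated as 12-bit unless values exceed that range.  Slice ``k`` of
    ``stem.nii`` corresponds to the materialized name ``stem_z<k>.png``.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vol = np.asarray(nib.load(str(path)).dataobj)
    elif path.suffix.lower() in DICOM_SUFFIXES:
        import pydicom

        vol = pydicom.dcmread(str(path)).pixel_array
        vol = np.moveaxis(vol, 0, -1)  # frames-first -> last axis
    else:
        raise DecodeError(f"not a recognised volume format: {path}")
    if vol.ndim != 3:
        raise DecodeError(f"expected a 3-D volume in {path}, got shape {vol.shape}")
    vol = np.clip(np.asarray(vol, dtype=np.float64), 0, None)
    vmax = vol.max()
    depth = 8 if vmax <= 255 else (12 if vmax < (1 << 12) else 16)
    return [
        rescale_to_8bit(np.floor(vol[..., k] + 0.5).astype(np.int64), depth)
        for k in range(vol.shape[-1])
    ]


def index_dataset(root: str | Path) -> DatasetIndex:
    """Index a two-class directory tree into a :class:`DatasetIndex`.

    Every image file under ``root/0`` and ``root/1`` (recursively, so nested
    patient/modality folders are fine) is recorded with its class label.
    Ordering is lexicographic by path, hence reproducible.
    """
    root = Path(root)
    records: list[DatasetRecord] = []
    for label in (0, 1):
        class_dir = root / str(label)
        if not class_dir.is_dir():
            raise LayoutError(
                f"dataset root {root} is missing class folder '{label}'"
            )
        files = sorted(
            p
            for p in class_dir.rglob("*")
            if p.is_file()
            and (p.suffix.lower() in IMAGE_SUFFIXES | DICOM_SUFFIXES)
        )
        if not files:
            warnings.warn(f"class folder {class_dir} contains no images", stacklevel=2)
        records.extend(DatasetRecord(str(p), label) for p in files)
    return DatasetIndex(records)


def write_feature_table(
    path: str | Path,
    paths: list[str],
    labels: np.ndarray,
    features: np.ndarray,
    column_names: list[str],
) -> None:
    """Persist a feature matrix as CSV with header ``path,label,<name>,...``."""
    import pandas as pd

    df = pd.DataFrame(features, columns=column_names)
    df.insert(0, "label", np.asarray(labels, dtype=int))
    df.insert(0, "path", paths)
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path):
    """Inverse of :func:`write_feature_table`: (paths, labels, features, names)."""
    import pandas as pd

    df = pd.read_csv(path)
    names = [c for c in df.columns if c not in ("path", "label")]
    return (
        df["path"].tolist(),
        df["label"].to_numpy(dtype=int),
        df[names].to_numpy(dtype=np.float64),
        names,
    )
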