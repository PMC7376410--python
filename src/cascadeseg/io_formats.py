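"""Reading/writing of the standard formats the pipeline touches.

Volumes and label maps travel as NIfTI-1 (``.nii`` / ``.nii.gz``) or
single-slice grayscale PNG; metric reports go to CSV.  Label maps follow the
BraTS convention: code 2 marks peritumoral edema (ED), 1 the non-enhancing /
necrotic tumor core (NET/NCR), 4 the enhancing core (ET); all other voxels are
background.  The whole tumor — the single foreground class the cascade
segments — is the union of the nonzero codes.

All grids are 0-based with axis order (row, column[, slice]).
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import imageio.v3 as iio
import nibabel as nib
import numpy as np

__all__ = [
    "Modality",
    "LabelScheme",
    "ImageVolume",
    "LabelMap",
    "CaseRecord",
    "BRATS_CODES",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "binarize_whole_tumor",
    "read_case",
    "write_case",
    "write_metrics_csv",
]

#: Valid non-background BraTS label codes (ED=2, NET/NCR=1, ET=4).
BRATS_CODES = frozenset({0, 1, 2, 4})

_MODALITY_SUFFIXES = {
    "t1": "T1",
    "t1ce": "T1CE",
    "t2": "T2",
    "flair": "FLAIR",
}


class Modality(enum.Enum):
    """MRI pulse sequence of a volume."""

    T1 = "T1"
    T1CE = "T1CE"
    T2 = "T2"
    FLAIR = "FLAIR"
    UNKNOWN = "UNKNOWN"


class LabelScheme(enum.Enum):
    BRATS = "BRATS"
    BINARY = "BINARY"


@dataclass
class ImageVolume:
    """A 2-D or 3-D scalar intensity grid with modality tag and voxel spacing."""

    data: np.ndarray
    modality: Modality = Modality.UNKNOWN
    spacing: tuple = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"expected a 2-D or 3-D grid, got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all axes must have length >= 1, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must all be finite")
        if not self.spacing:
            self.spacing = (1.0,) * self.data.ndim

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class LabelMap:
    """Integer label grid aligned with an :class:`ImageVolume`."""

    data: np.ndarray
    scheme: LabelScheme = LabelScheme.BINARY

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            as_int = np.rint(self.data).astype(np.int64)
            if not np.array_equal(as_int, self.data):
                raise ValueError("label map values must be integers")
            self.data = as_int
        self.data = self.data.astype(np.int64, copy=False)
        values = set(np.unique(self.data).tolist())
        if self.scheme is LabelScheme.BRATS and not values <= BRATS_CODES:
            bad = sorted(values - BRATS_CODES)
            raise ValueError(f"invalid BraTS label code(s): {bad}")
        if self.scheme is LabelScheme.BINARY and not values <= {0, 1}:
            bad = sorted(values - {0, 1})
            raise ValueError(f"invalid binary label value(s): {bad}")

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class CaseRecord:
    """One subject: modality → volume, plus (optionally) ground truth."""

    case_id: str
    volumes: Mapping[Modality, ImageVolume] = field(default_factory=dict)
    truth: Optional[LabelMap] = None

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.volumes.values()}
        if self.truth is not None:
            shapes.add(self.truth.shape)
        if len(shapes) > 1:
            raise ValueError(f"volumes/truth shapes disagree: {sorted(shapes)}")

    @property
    def shape(self) -> tuple:
        if self.volumes:
            return next(iter(self.volumes.values())).shape
        if self.truth is not None:
            return self.truth.shape
        raise ValueError("empty case record")


def _strip_nii(name: str) -> str:
    for ext in (".nii.gz", ".nii", ".png"):
        if name.lower().endswith(ext):
            return name[: -len(ext)]
    return name


def _modality_from_name(path: Path) -> Modality:
    stem = _strip_nii(path.name).lower()
    for suffix, mod in _MODALITY_SUFFIXES.items():
        if stem.endswith("_" + suffix):
            return Modality(mod)
    return Modality.UNKNOWN


def read_volume(path) -> ImageVolume:
    """Read a NIfTI volume or a grayscale PNG slice.

    PNGs are treated as single 2-D slices with UNKNOWN modality unless the
    filename carries a BraTS-style modality suffix (``*_t1``, ``*_flair``, ...).
    RGB PNGs are rejected: the pipeline is scalar-intensity only.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
        spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
        return ImageVolume(data=np.squeeze(data), modality=_modality_from_name(path), spacing=spacing)
    if name.endswith(".png"):
        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            raise ValueError(
                f"{path.name}: expected a grayscale PNG, got {arr.shape[-1]} channels"
            )
        return ImageVolume(data=arr.astype(np.float64), modality=_modality_from_name(path))
    raise ValueError(f"unsupported extension: {path.name} (expected .nii/.nii.gz/.png)")


def write_volume(volume: ImageVolume, path) -> None:
    """Write a volume as NIfTI (float64) or 16-bit grayscale PNG."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(volume.spacing) + [1.0] * (4 - len(volume.spacing)))
        nib.save(nib.Nifti1Image(volume.data.astype(np.float64), affine), str(path))
    elif name.endswith(".png"):
        if volume.data.ndim != 2:
            raise ValueError("PNG output supports 2-D slices only")
        lo, hi = float(volume.data.min()), float(volume.data.max())
        scaled = (volume.data - lo) / (hi - lo) if hi > lo else np.zeros_like(volume.data)
        iio.imwrite(path, np.round(scaled * 65535).astype(np.uint16))
    else:
        raise ValueError(f"unsupported extension: {path.name}")


def read_labelmap(path, scheme: Optional[LabelScheme] = None) -> LabelMap:
    """Read an integer label map; scheme inferred from the value set if omitted."""
    vol = read_volume(path)
    data = np.rint(vol.data).astype(np.int64)
    if scheme is None:
        scheme = LabelScheme.BINARY if set(np.unique(data)) <= {0, 1} else LabelScheme.BRATS
    return LabelMap(data=data, scheme=scheme)


def write_labelmap(labelmap: LabelMap, path) -> None:
    """Write a label map losslessly (NIfTI int16, or 8-bit PNG raw codes)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        nib.save(nib.Nifti1Image(labelmap.data.astype(np.int16), np.eye(4)), str(path))
    elif name.endswith(".png"):
        if labelmap.data.ndim != 2:
            raise ValueError("PNG output supports 2-D label maps only")
        iio.imwrite(path, labelmap.data.astype(np.uint8))
    else:
        raise ValueError(f"unsupported extension: {path.name}")


def binarize_whole_tumor(labelmap: LabelMap) -> LabelMap:
    """Collapse BraTS subregion codes to the single whole-tumor foreground.

    ED, NET/NCR and ET voxels (codes 1, 2, 4) all become 1.  Idempotent on
    maps that are already binary.
    """
    if labelmap.scheme is LabelScheme.BINARY:
        return LabelMap(data=labelmap.data.copy(), scheme=LabelScheme.BINARY)
    values = set(np.unique(labelmap.data).tolist())
    if not values <= BRATS_CODES:
        raise ValueError(f"invalid BraTS label code(s): {sorted(values - BRATS_CODES)}")
    return LabelMap(data=(labelmap.data > 0).astype(np.int64), scheme=LabelScheme.BINARY)


def read_case(case_dir) -> CaseRecord:
    """Discover a BraTS-style case directory by filename suffix convention.

    Files named ``<case>_t1``, ``<case>_t1ce``, ``<case>_t2``, ``<case>_flair``
    and ``<case>_seg`` (case-insensitive; ``.nii``/``.nii.gz``/``.png``) are
    collected into one :class:`CaseRecord`.
    """
    case_dir = Path(case_dir)
    if not case_dir.is_dir():
        raise FileNotFoundError(case_dir)
    volumes: dict = {}
    truth = None
    for path in sorted(case_dir.iterdir()):
        if not path.name.lower().endswith((".nii", ".nii.gz", ".png")):
            continue
        stem = _strip_nii(path.name).lower()
        if stem.endswith("_seg"):
            truth = read_labelmap(path)
            continue
        mod = _modality_from_name(path)
        if mod is not Modality.UNKNOWN:
            volumes[mod] = read_volume(path)
    if not volumes and truth is None:
        raise ValueError(f"no recognizable modality/seg files in {case_dir}")
    return CaseRecord(case_id=case_dir.name, volumes=volumes, truth=truth)


def write_case(case: CaseRecord, out_dir) -> Path:
    """Write a case as a BraTS-style NIfTI directory; returns the directory."""
    out_dir = Path(out_dir) / case.case_id
    out_dir.mkdir(parents=True, exist_ok=True)
    for mod, vol in case.volumes.items():
        write_volume(vol, out_dir / f"{case.case_id}_{mod.value.lower()}.nii.gz")
    if case.truth is not None:
        write_labelmap(case.truth, out_dir / f"{case.case_id}_seg.nii.gz")
    return out_dir


def write_metrics_csv(rows, path) -> None:
    """Write per-case metric rows (case_id, dsc, sensitivity, specificity)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "dsc", "sensitivity", "specificity"])
        for row in rows:
            writer.writerow([row[0]] + [("" if v is None else f"{v:.6f}") for v in row[1:]])
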