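"""Volume and mask data model, physical-space conventions, and NIfTI I/O.

Conventions used throughout the package:

* voxel indices are 0-based; index boxes are half-open ``[lo, hi)``;
* physical position of voxel ``(i, j, k)`` is ``origin + index * spacing``;
* only axis-aligned geometry (identity direction cosines) is supported —
  oblique orientations are rejected at read time;
* masks and label maps are stored as unsigned integers, intensity and
  Jacobian volumes as 32-bit floats.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume3D",
    "LungMask",
    "ROILabelMap",
    "read_volume",
    "write_volume",
    "bounding_box_union",
    "bounding_box",
]

INTENSITY_KINDS = ("HU", "normalized", "log2_jacobian", "jacobian", "label")


def _as_triple(x) -> tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (3,))
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclasses.dataclass
class Volume3D:
    """A 3D scalar grid with physical spacing and origin.

    Parameters
    ----------
    data:
        3D array of voxel values.
    spacing:
        Per-axis voxel size in mm (strictly positive).
    origin:
        Physical position (mm) of voxel ``(0, 0, 0)``.
    intensity_kind:
        One of ``HU``, ``normalized``, ``log2_jacobian``, ``jacobian``,
        ``label``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity_kind: str = "HU"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.intensity_kind not in INTENSITY_KINDS:
            raise ValueError(f"unknown intensity_kind {self.intensity_kind!r}")
        if self.intensity_kind == "label":
            if not np.issubdtype(self.data.dtype, np.integer):
                self.data = self.data.astype(np.uint16)
        elif self.data.dtype not in (np.float32, np.float64):
            # float32 is the storage contract; float64 is preserved in memory
            # where numerical fidelity matters (e.g. exact Jacobian checks)
            self.data = self.data.astype(np.float32)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(np.prod(self.spacing))

    def validate_in_mask(self, mask: "LungMask") -> None:
        """Check the intensity-kind invariants on in-mask voxels."""
        vals = self.data[mask.data > 0]
        if self.intensity_kind == "normalized" and vals.size:
            if vals.min() < -1 - 1e-6 or vals.max() > 1 + 1e-6:
                raise ValueError("normalized volume has in-mask values outside [-1, 1]")
        if self.intensity_kind == "jacobian" and vals.size and vals.min() <= 0:
            raise ValueError("jacobian volume has non-positive in-mask values")

    def same_grid(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def copy(self, data: np.ndarray | None = None, intensity_kind: str | None = None):
        return Volume3D(
            data=self.data.copy() if data is None else data,
            spacing=self.spacing,
            origin=self.origin,
            intensity_kind=self.intensity_kind if intensity_kind is None else intensity_kind,
        )

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to physical mm coordinates."""
        return np.asarray(self.origin) + np.asarray(idx) * np.asarray(self.spacing)

    def physical_grid(self) -> np.ndarray:
        """Physical coordinates of every voxel center, shape ``shape + (3,)``."""
        axes = [
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a], dtype=float)
            for a in range(3)
        ]
        g = np.meshgrid(*axes, indexing="ij")
        return np.stack(g, axis=-1)


@dataclasses.dataclass
class LungMask:
    """Binary lung mask on the same grid as its associated volume."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D")
        uniq = np.unique(self.data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        if not np.any(self.data):
            raise ValueError("mask is empty")
        self.data = self.data.astype(np.uint8)
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_mm3(self) -> float:
        """Total mask volume in mm^3."""
        return float(self.data.sum()) * self.voxel_volume

    def as_bool(self) -> np.ndarray:
        return self.data > 0

    def same_grid(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclasses.dataclass
class ROILabelMap:
    """Integer label grid partitioning a lung mask (0 = outside lung)."""

    data: np.ndarray
    label_table: dict[int, str]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D label map, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            self.data = np.rint(self.data).astype(np.uint16)
        self.data = self.data.astype(np.uint16)
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        self.label_table = {int(k): str(v) for k, v in self.label_table.items()}

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def check_partition(self, mask: LungMask) -> None:
        """Every in-mask voxel must carry exactly one nonzero label."""
        inside = mask.as_bool()
        if np.any(self.data[inside] == 0):
            raise ValueError("label map leaves in-mask voxels unlabeled")
        if np.any(self.data[~inside] != 0):
            raise ValueError("label map assigns labels outside the mask")

    def labels_present(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.data) if v != 0)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def read_volume(path, intensity_kind: str = "HU") -> Volume3D:
    """Read a 3D NIfTI volume.

    Rejects non-3D images and oblique (non-axis-aligned) orientations.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path.name}")
    aff = img.affine
    rot = aff[:3, :3]
    offdiag = rot - np.diag(np.diag(rot))
    if np.abs(offdiag).max() > 1e-6 * max(1.0, np.abs(rot).max()):
        raise ValueError(
            f"{path.name}: non-axis-aligned orientation is not supported; "
            "resample to an identity direction-cosine grid first"
        )
    diag = np.diag(rot)
    if np.any(diag <= 0):
        raise ValueError(f"{path.name}: negative or zero scales in affine are not supported")
    return Volume3D(
        data=data,
        spacing=tuple(diag),
        origin=tuple(aff[:3, 3]),
        intensity_kind=intensity_kind,
    )


def write_volume(v: Volume3D | LungMask | ROILabelMap, path) -> Path:
    """Write a volume, mask, or label map as NIfTI.

    Masks and label maps are written with integer dtype, intensity volumes as
    float32.  NaNs are rejected anywhere in the grid.
    """
    path = Path(path)
    data = v.data
    if np.issubdtype(data.dtype, np.floating) and not np.all(np.isfinite(data)):
        raise ValueError("volume contains NaN/Inf values; refusing to write")
    img = nib.Nifti1Image(data, _affine(v.spacing, v.origin))
    img.header.set_zooms(v.spacing)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def read_mask(path) -> LungMask:
    v = read_volume(path, intensity_kind="label")
    return LungMask(data=(v.data > 0).astype(np.uint8), spacing=v.spacing, origin=v.origin)


def read_labelmap(path, label_table: dict[int, str] | None = None) -> ROILabelMap:
    v = read_volume(path, intensity_kind="label")
    if label_table is None:
        label_table = {int(k): f"roi_{int(k)}" for k in np.unique(v.data) if k != 0}
    return ROILabelMap(data=v.data, label_table=label_table, spacing=v.spacing, origin=v.origin)


# ---------------------------------------------------------------------------
# Bounding boxes
# ---------------------------------------------------------------------------


def bounding_box(mask: LungMask) -> np.ndarray:
    """Tightest half-open index box containing all set voxels, shape (3, 2)."""
    if not np.any(mask.data):
        raise ValueError("empty mask has no bounding box")
    box = np.empty((3, 2), dtype=int)
    idx = np.nonzero(mask.data)
    for a in range(3):
        box[a, 0] = idx[a].min()
        box[a, 1] = idx[a].max() + 1
    return box


def bounding_box_union(a: LungMask, b: LungMask) -> np.ndarray:
    """Tightest half-open index box containing every set voxel of ``a | b``."""
    if not a.same_grid(b):
        raise ValueError("masks are not on the same grid")
    union = np.logical_or(a.as_bool(), b.as_bool())
    if not np.any(union):
        raise ValueError("union of masks is empty")
    ba = bounding_box(a)
    bb = bounding_box(b)
    box = np.empty((3, 2), dtype=int)
    box[:, 0] = np.minimum(ba[:, 0], bb[:, 0])
    box[:, 1] = np.maximum(ba[:, 1], bb[:, 1])
    return box


def crop_to_box(arr: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Crop a 3D (or leading-3D) array to a half-open index box."""
    return arr[box[0, 0]:box[0, 1], box[1, 0]:box[1, 1], box[2, 0]:box[2, 1], ...]
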