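"""Image-stack, label-volume and box-annotation I/O.

This module owns the coordinate conventions used everywhere else:

* volumes are ``(Z, Y, X)`` arrays, page order of a multi-page TIFF maps to
  ascending Z;
* pixel/voxel coordinates are 0-based and intervals are half-open;
* intensities are 8-bit (``uint8``); higher bit depths are rejected unless
  explicitly rescaled;
* 2D boxes live on the ``(Y, X)`` plane of a Z-projection.

Box annotations use a plain-text dialect with one box per line::

    class_index cx cy w h [confidence]

where ``cx cy w h`` are the box centre and size normalized to ``[0, 1]``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import tifffile

__all__ = [
    "ROI_CLASSES",
    "CLASS_INDEX",
    "VolumeStack",
    "LabelVolume",
    "BoundingBox2D",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "read_boxes",
    "write_boxes",
]

#: The three ROI classes of the detector, in class-index order.
ROI_CLASSES = ("AL", "MB_CAL", "CX")
CLASS_INDEX = {name: i for i, name in enumerate(ROI_CLASSES)}

#: Reference voxel size (dx, dy, dz) in micrometres.
DEFAULT_VOXEL_SIZE = (0.32, 0.32, 1.0)


@dataclass
class VolumeStack:
    """A 3D intensity stack with voxel-size metadata.

    Parameters
    ----------
    data
        ``(Z, Y, X)`` array with unsigned 8-bit semantics.
    voxel_size
        ``(dx, dy, dz)`` in micrometres, all strictly positive.
    source_id
        Free-form identifier of the stack's origin.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    source_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D (Z, Y, X) array, got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all axes must be >= 1, got shape {self.data.shape}")
        if self.data.dtype != np.uint8:
            lo, hi = self.data.min(), self.data.max()
            if lo < 0 or hi > 255:
                raise ValueError(f"intensities outside [0, 255]: min={lo}, max={hi}")
            self.data = self.data.astype(np.uint8)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be three positive values, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """A voxel-wise class mask aligned to a companion :class:`VolumeStack`.

    ``classes[0]`` is always the background class.
    """

    data: np.ndarray
    classes: tuple[str, ...] = ("background", "neuropil")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D (Z, Y, X) array, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"labels must be integers, got dtype {self.data.dtype}")
        if self.data.size and (self.data.min() < 0 or self.data.max() >= len(self.classes)):
            raise ValueError(
                f"label values must index classes {self.classes}; "
                f"found range [{self.data.min()}, {self.data.max()}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class BoundingBox2D:
    """One detected/annotated ROI on a Z-projection.

    Coordinates are 0-based pixels, half-open ``[x0, x1) x [y0, y1)`` on the
    ``(Y, X)`` plane.
    """

    roi_class: str
    x0: float
    y0: float
    x1: float
    y1: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.roi_class not in ROI_CLASSES:
            raise ValueError(f"unknown ROI class {self.roi_class!r}; expected one of {ROI_CLASSES}")
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"degenerate box: ({self.x0},{self.y0})-({self.x1},{self.y1})")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    def clipped(self, image_shape: tuple[int, int]) -> "BoundingBox2D":
        """Clip to ``(H, W)`` image bounds; raises if the box degenerates."""
        h, w = image_shape
        return replace(
            self,
            x0=min(max(self.x0, 0.0), w),
            x1=min(max(self.x1, 0.0), w),
            y0=min(max(self.y0, 0.0), h),
            y1=min(max(self.y1, 0.0), h),
        )


# ---------------------------------------------------------------------------
# Volumes


def _read_pages(path: str) -> np.ndarray:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:  # single-page TIFF -> Z = 1
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a (multi-)page 2D TIFF, got shape {arr.shape}")
    return arr


def read_volume(
    path: str,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    rescale: bool = False,
    source_id: str | None = None,
) -> VolumeStack:
    """Read a multi-page TIFF into a :class:`VolumeStack`.

    Data wider than 8 bits is rejected unless ``rescale`` is set, in which
    case a min-max map to ``[0, 255]`` is applied (constant input maps to 0).
    """
    arr = _read_pages(path)
    if arr.dtype != np.uint8:
        if not rescale:
            raise ValueError(
                f"{path}: dtype {arr.dtype} is wider than 8 bits; pass rescale=True "
                "to min-max map intensities to [0, 255]"
            )
        arr = arr.astype(np.float64)
        lo, hi = arr.min(), arr.max()
        arr = np.zeros_like(arr) if hi == lo else (arr - lo) * (255.0 / (hi - lo))
        arr = np.rint(arr).astype(np.uint8)
    if source_id is None:
        source_id = os.path.splitext(os.path.basename(path))[0]
    return VolumeStack(arr, voxel_size=voxel_size, source_id=source_id)


def write_volume(vol: VolumeStack, path: str) -> None:
    """Write a stack as an uncompressed multi-page 8-bit TIFF."""
    tifffile.imwrite(path, vol.data, photometric="minisblack")


def read_labels(path: str, classes: tuple[str, ...] = ("background", "neuropil")) -> LabelVolume:
    """Read a class-index TIFF into a :class:`LabelVolume`."""
    arr = _read_pages(path)
    return LabelVolume(arr.astype(np.int64), classes=classes)


def write_labels(labels: LabelVolume, path: str) -> None:
    if len(labels.classes) > 256:
        raise ValueError("more than 256 classes cannot be stored as 8-bit indices")
    tifffile.imwrite(path, labels.data.astype(np.uint8), photometric="minisblack")


# ---------------------------------------------------------------------------
# Boxes


def read_boxes(path: str, image_shape: tuple[int, int]) -> list[BoundingBox2D]:
    """Parse normalized-centre box annotations for an ``(H, W)`` projection."""
    h, w = image_shape
    if h < 1 or w < 1:
        raise ValueError(f"empty image shape {image_shape}")
    boxes: list[BoundingBox2D] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (5, 6):
                raise ValueError(f"{path}:{lineno}: expected 5 or 6 fields, got {len(parts)}")
            try:
                cls = int(parts[0])
                cx, cy, bw, bh = (float(p) for p in parts[1:5])
                conf = float(parts[5]) if len(parts) == 6 else 1.0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line {line!r}") from exc
            if cls not in range(len(ROI_CLASSES)):
                raise ValueError(f"{path}:{lineno}: class index {cls} out of range")
            for v in (cx, cy, bw, bh):
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"{path}:{lineno}: normalized value {v} outside [0, 1]")
            box = BoundingBox2D(
                roi_class=ROI_CLASSES[cls],
                x0=round((cx - bw / 2.0) * w),
                y0=round((cy - bh / 2.0) * h),
                x1=round((cx + bw / 2.0) * w),
                y1=round((cy + bh / 2.0) * h),
                confidence=conf,
            ).clipped((h, w))
            boxes.append(box)
    return boxes


def write_boxes(boxes: list[BoundingBox2D], image_shape: tuple[int, int], path: str) -> None:
    """Write boxes in the normalized-centre dialect (inverse of :func:`read_boxes`)."""
    h, w = image_shape
    if h < 1 or w < 1:
        raise ValueError(f"empty image shape {image_shape}")
    with open(path, "w") as fh:
        for box in boxes:
            cx = (box.x0 + box.x1) / 2.0 / w
            cy = (box.y0 + box.y1) / 2.0 / h
            bw = (box.x1 - box.x0) / w
            bh = (box.y1 - box.y0) / h
            fh.write(
                f"{CLASS_INDEX[box.roi_class]} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f} "
                f"{box.confidence:.4f}\n"
            )
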