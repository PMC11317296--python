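"""From 2D detections to standardized 3D ROIs, training cubes, and back.

The stage-2 model never sees raw stacks.  Each detected box is extruded
through Z, standardized to a fixed 124x168x168 grid (Z zero-padding, XY
resampling), and tiled into overlapping 64x128x128 cubes at stride 20.
Cube predictions are fused by probability averaging and restored to the
original stack geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .io_formats import BoundingBox2D, LabelVolume, VolumeStack

__all__ = [
    "STD_SHAPE",
    "CUBE_SHAPE",
    "DEFAULT_STRIDE",
    "Region3D",
    "ROIGeometry",
    "StandardizedROI",
    "Cube",
    "box_to_roi3d",
    "standardize",
    "sliding_windows",
    "build_training_cubes",
    "stitch",
    "restore",
]

#: Standardized ROI grid (Z, Y, X).
STD_SHAPE = (124, 168, 168)
#: Sliding-window size (Z, Y, X).
CUBE_SHAPE = (64, 128, 128)
#: Default sliding distance on every axis.
DEFAULT_STRIDE = 20


@dataclass
class Region3D:
    """A raw 3D crop: the detected XY box extruded through the full Z range."""

    data: np.ndarray  # (Z, h, w) uint8
    mask: np.ndarray | None  # (Z, h, w) int, aligned, or None
    box: tuple[int, int, int, int]  # (y0, y1, x0, x1) in the original stack
    full_shape: tuple[int, int, int]
    source_id: str = ""


@dataclass(frozen=True)
class ROIGeometry:
    """Everything needed to invert :func:`standardize`."""

    box: tuple[int, int, int, int]  # (y0, y1, x0, x1)
    full_shape: tuple[int, int, int]
    roi_shape: tuple[int, int, int]  # (Z, h, w) before padding/resampling
    pad_before: int
    pad_after: int


@dataclass
class StandardizedROI:
    """A 124x168x168 standardized region, optionally with an aligned mask."""

    data: np.ndarray
    geometry: ROIGeometry
    mask: np.ndarray | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if tuple(self.data.shape) != STD_SHAPE:
            raise ValueError(f"standardized ROI must be {STD_SHAPE}, got {self.data.shape}")
        if self.mask is not None and tuple(self.mask.shape) != STD_SHAPE:
            raise ValueError(f"standardized mask must be {STD_SHAPE}, got {self.mask.shape}")


@dataclass
class Cube:
    """One 64x128x128 training/inference window placed inside a standardized ROI."""

    data: np.ndarray
    offset: tuple[int, int, int]
    mirrored: bool = False
    mask: np.ndarray | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if tuple(self.data.shape) != CUBE_SHAPE:
            raise ValueError(f"cube must be {CUBE_SHAPE}, got {self.data.shape}")
        for o, c, s in zip(self.offset, CUBE_SHAPE, STD_SHAPE):
            if o < 0 or o + c > s:
                raise ValueError(f"cube at offset {self.offset} exceeds {STD_SHAPE}")


# ---------------------------------------------------------------------------


def box_to_roi3d(
    box: BoundingBox2D,
    vol: VolumeStack,
    margin_frac: float = 0.05,
    mask: LabelVolume | None = None,
) -> Region3D:
    """Extrude a 2D box through Z into a raw 3D region.

    The box is dilated by ``margin_frac`` of its size per side (insurance
    against tight detections), then clipped to the image.  The Z extent is
    always the full stack depth.
    """
    Z, Y, X = vol.shape
    mx = round(margin_frac * (box.x1 - box.x0))
    my = round(margin_frac * (box.y1 - box.y0))
    x0 = max(0, int(round(box.x0)) - mx)
    x1 = min(X, int(round(box.x1)) + mx)
    y0 = max(0, int(round(box.y0)) - my)
    y1 = min(Y, int(round(box.y1)) + my)
    if x0 >= x1 or y0 >= y1:
        raise ValueError(f"box {box} degenerates after clipping to image {Y}x{X}")
    data = vol.data[:, y0:y1, x0:x1]
    m = mask.data[:, y0:y1, x0:x1] if mask is not None else None
    return Region3D(
        data=data,
        mask=m,
        box=(y0, y1, x0, x1),
        full_shape=(Z, Y, X),
        source_id=vol.source_id,
    )


def standardize(region: Region3D) -> StandardizedROI:
    """Map a raw region onto the fixed 124x168x168 grid.

    Z is zero-padded symmetrically (extra layer at the far end when odd);
    XY is resampled to 168x168 — linear interpolation for intensities,
    nearest neighbour for masks.  Regions deeper than 124 are rejected.
    """
    Z, h, w = region.data.shape
    zt, yt, xt = STD_SHAPE
    if Z > zt:
        raise ValueError(
            f"stack depth {Z} exceeds the standardized depth {zt}; "
            "deeper stacks are not supported"
        )
    pad_before = (zt - Z) // 2
    pad_after = zt - Z - pad_before

    img = resize(
        region.data.astype(np.float32),
        (Z, yt, xt),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    data = np.zeros(STD_SHAPE, dtype=np.uint8)
    data[pad_before : pad_before + Z] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    std_mask = None
    if region.mask is not None:
        m = resize(
            region.mask.astype(np.float32),
            (Z, yt, xt),
            order=0,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
        std_mask = np.zeros(STD_SHAPE, dtype=np.int64)
        std_mask[pad_before : pad_before + Z] = np.rint(m).astype(np.int64)

    geometry = ROIGeometry(
        box=region.box,
        full_shape=region.full_shape,
        roi_shape=(Z, h, w),
        pad_before=pad_before,
        pad_after=pad_after,
    )
    return StandardizedROI(data=data, geometry=geometry, mask=std_mask, source_id=region.source_id)


def _axis_offsets(std: int, cube: int, stride: int) -> list[int]:
    if stride < 1:
        raise ValueError("stride must be >= 1")
    span = std - cube
    if span % stride != 0:
        raise ValueError(
            f"stride {stride} does not tile the {std} axis with {cube} windows "
            f"({std}-{cube} not divisible by {stride})"
        )
    return list(range(0, span + 1, stride))


def sliding_windows(
    roi: StandardizedROI,
    stride: int | tuple[int, int, int] = DEFAULT_STRIDE,
    mirror: bool = False,
) -> list[Cube]:
    """Enumerate every fitting 64x128x128 window at the given stride.

    At the default stride 20 this yields 4*3*3 = 36 placements; with
    ``mirror`` each cube is followed by its Z-flipped copy (72 cubes).
    """
    if isinstance(stride, int):
        stride = (stride, stride, stride)
    offs = [_axis_offsets(s, c, st) for s, c, st in zip(STD_SHAPE, CUBE_SHAPE, stride)]
    cubes: list[Cube] = []
    for z in offs[0]:
        for y in offs[1]:
            for x in offs[2]:
                sl = (
                    slice(z, z + CUBE_SHAPE[0]),
                    slice(y, y + CUBE_SHAPE[1]),
                    slice(x, x + CUBE_SHAPE[2]),
                )
                data = roi.data[sl]
                m = roi.mask[sl] if roi.mask is not None else None
                cubes.append(Cube(data, (z, y, x), mirrored=False, mask=m, source_id=roi.source_id))
                if mirror:
                    mm = m[::-1] if m is not None else None
                    cubes.append(
                        Cube(data[::-1], (z, y, x), mirrored=True, mask=mm, source_id=roi.source_id)
                    )
    return cubes


def build_training_cubes(
    brains: list[tuple[VolumeStack, dict[str, LabelVolume], list[BoundingBox2D]]],
    structure: str,
    margin_frac: float = 0.05,
    stride: int | tuple[int, int, int] = DEFAULT_STRIDE,
) -> list[Cube]:
    """Concatenate mirrored sliding windows over every ROI of one structure.

    A bilateral structure contributes two ROIs per brain (144 cubes at the
    defaults), a midline structure one (72 cubes).
    """
    cubes: list[Cube] = []
    for vol, masks, boxes in brains:
        struct_boxes = [b for b in boxes if b.roi_class == structure]
        if not struct_boxes:
            raise ValueError(f"brain {vol.source_id!r} has no box for structure {structure!r}")
        if structure not in masks:
            raise ValueError(f"brain {vol.source_id!r} has no mask for structure {structure!r}")
        for box in struct_boxes:
            region = box_to_roi3d(box, vol, margin_frac=margin_frac, mask=masks[structure])
            roi = standardize(region)
            cubes.extend(sliding_windows(roi, stride=stride, mirror=True))
    return cubes


def stitch(cube_probs: list[tuple[Cube, np.ndarray]]) -> np.ndarray:
    """Fuse per-cube class probabilities into a 124x168x168x2 volume.

    Mirrored cubes are un-flipped first; overlapping voxels take the mean
    probability over all covering cubes.  Every voxel must be covered.
    """
    n_classes = None
    accum = None
    count = np.zeros(STD_SHAPE, dtype=np.int32)
    for cube, probs in cube_probs:
        probs = np.asarray(probs, dtype=np.float64)
        if probs.shape[:3] != CUBE_SHAPE:
            raise ValueError(f"probability block must be {CUBE_SHAPE}+(C,), got {probs.shape}")
        if n_classes is None:
            n_classes = probs.shape[3]
            accum = np.zeros(STD_SHAPE + (n_classes,), dtype=np.float64)
        if cube.mirrored:
            probs = probs[::-1]
        z, y, x = cube.offset
        sl = (
            slice(z, z + CUBE_SHAPE[0]),
            slice(y, y + CUBE_SHAPE[1]),
            slice(x, x + CUBE_SHAPE[2]),
        )
        accum[sl] += probs
        count[sl] += 1
    if accum is None:
        raise ValueError("no cubes to stitch")
    if (count == 0).any():
        raise ValueError(f"{int((count == 0).sum())} voxels covered by zero cubes")
    return accum / count[..., None]


def restore(
    prob_volume: np.ndarray,
    geometry: ROIGeometry,
    original_shape: tuple[int, int, int],
    classes: tuple[str, ...] = ("background", "neuropil"),
) -> LabelVolume:
    """Map a standardized probability volume back to original-stack labels.

    Argmax labels (exact probability ties go to background), Z padding
    stripped, nearest-neighbour XY resampling back to the raw ROI size, then
    placement into a full-size zero background.
    """
    if tuple(original_shape) != tuple(geometry.full_shape):
        raise ValueError(
            f"original shape {original_shape} does not match geometry {geometry.full_shape}"
        )
    if prob_volume.shape[:3] != STD_SHAPE:
        raise ValueError(f"probability volume must be {STD_SHAPE}+(C,), got {prob_volume.shape}")
    # strict argmax with ties resolved toward the lowest (background) index
    labels_std = np.zeros(STD_SHAPE, dtype=np.int64)
    best = prob_volume[..., 0].copy()
    for c in range(1, prob_volume.shape[3]):
        better = prob_volume[..., c] > best
        labels_std[better] = c
        best[better] = prob_volume[..., c][better]

    Z, h, w = geometry.roi_shape
    core = labels_std[geometry.pad_before : geometry.pad_before + Z]
    roi_labels = resize(
        core.astype(np.float32),
        (Z, h, w),
        order=0,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    roi_labels = np.rint(roi_labels).astype(np.int64)

    out = np.zeros(original_shape, dtype=np.int64)
    y0, y1, x0, x1 = geometry.box
    out[:, y0:y1, x0:x1] = roi_labels
    return LabelVolume(out, classes=classes)
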