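"""Z-axis projections of 3D stacks onto the (Y, X) plane."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import VolumeStack

__all__ = ["Projection2D", "project", "projection_pair"]


@dataclass
class Projection2D:
    """A 2D (Y, X) projection of a stack, 8-bit semantics."""

    data: np.ndarray
    mode: str
    source_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"expected a 2D (Y, X) array, got ndim={self.data.ndim}")
        if self.mode not in ("max", "mean"):
            raise ValueError(f"mode must be 'max' or 'mean', got {self.mode!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def _rescale_u8(img: np.ndarray) -> np.ndarray:
    # degenerate (constant) range maps to 0 by convention
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros(img.shape, dtype=np.uint8)
    return np.rint((img - lo) * (255.0 / (hi - lo))).astype(np.uint8)


def project(vol: VolumeStack, mode: str) -> Projection2D:
    """Collapse a stack along Z.

    ``max`` keeps the per-pixel maximum (already in [0, 255]).  ``mean``
    takes the per-pixel average over Z and then min-max rescales to
    [0, 255]; after rescaling this is identical to a summed projection.
    """
    if vol.data.size == 0:
        raise ValueError("empty volume")
    if mode == "max":
        data = vol.data.max(axis=0)
    elif mode == "mean":
        data = _rescale_u8(vol.data.mean(axis=0, dtype=np.float64))
    else:
        raise ValueError(f"mode must be 'max' or 'mean', got {mode!r}")
    return Projection2D(data, mode=mode, source_id=vol.source_id)


def projection_pair(vol: VolumeStack) -> tuple[Projection2D, Projection2D]:
    """Both detector inputs (max and mean projection) from one stack."""
    return project(vol, "max"), project(vol, "mean")
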