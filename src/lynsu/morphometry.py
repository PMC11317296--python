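"""Cohort filtering and bilateral volume asymmetry analysis.

A segmented cohort is filtered to masks with exactly two closed 3D
components (26-connectivity) where the largest is at most twice the second
largest; bilateral volumes are voxel counts per hemisphere component and
the signed percent difference is normalized by the mean of the two
volumes (negative = left larger).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .io_formats import LabelVolume

__all__ = [
    "remove_small_components",
    "FilterDecision",
    "BilateralVolumes",
    "CohortSummary",
    "component_filter",
    "bilateral_volumes",
    "hemisphere_difference",
    "cohort_summary",
    "estimate_valid_population",
    "verification_success_rate",
    "annotation_effort_hours",
    "cross_model_consistency",
]


@dataclass
class FilterDecision:
    """Outcome of the two-component screen for one segmented mask."""

    n_components: int
    volumes: tuple[int, ...]  # descending component voxel counts
    passed: bool


@dataclass
class BilateralVolumes:
    """Left/right structure volumes and their signed percent difference."""

    v_left: int
    v_right: int
    voxel_size: tuple[float, float, float] | None = None
    side_assignment_ambiguous: bool = False

    @property
    def percent_diff(self) -> float:
        """``100 * (V_R - V_L) / mean(V_L, V_R)``; negative = left larger."""
        mean = (self.v_left + self.v_right) / 2.0
        return 100.0 * (self.v_right - self.v_left) / mean

    @property
    def volumes_um3(self) -> tuple[float, float] | None:
        if self.voxel_size is None:
            return None
        dv = self.voxel_size[0] * self.voxel_size[1] * self.voxel_size[2]
        return (self.v_left * dv, self.v_right * dv)


def _binary(mask: LabelVolume | np.ndarray) -> np.ndarray:
    data = mask.data if isinstance(mask, LabelVolume) else np.asarray(mask)
    return data > 0


def remove_small_components(
    mask: LabelVolume | np.ndarray, min_size: int = 64
) -> np.ndarray:
    """Drop 26-connected components smaller than ``min_size`` voxels.

    Standard speckle cleanup between voxel-wise prediction and the
    two-component screen; genuine structures are orders of magnitude
    larger than prediction speckles.
    """
    b = _binary(mask)
    if min_size <= 1:
        return b.astype(np.int64)
    labelled = measure.label(b, connectivity=3)
    counts = np.bincount(labelled.ravel())
    keep = counts >= min_size
    keep[0] = False
    return keep[labelled].astype(np.int64)


def component_filter(mask: LabelVolume | np.ndarray) -> FilterDecision:
    """Screen a binary mask for exactly two components with volume ratio <= 2.

    Components are labelled under full 26-connectivity.  An empty mask
    fails with ``n_components = 0``.
    """
    b = _binary(mask)
    if not b.any():
        return FilterDecision(n_components=0, volumes=(), passed=False)
    labelled, n = measure.label(b, connectivity=3, return_num=True)
    volumes = tuple(
        sorted((int(v) for v in np.bincount(labelled.ravel())[1:]), reverse=True)
    )
    passed = n == 2 and volumes[0] <= 2 * volumes[1]
    return FilterDecision(n_components=n, volumes=volumes, passed=passed)


def bilateral_volumes(
    mask: LabelVolume | np.ndarray,
    midline_x: int,
    voxel_size: tuple[float, float, float] | None = None,
) -> BilateralVolumes:
    """Assign the two components of a filtered mask to hemispheres and measure.

    The component whose centroid X lies left of ``midline_x`` is the left
    structure.  If both centroids fall on the same side the assignment
    falls back to relative centroid order and is flagged.
    """
    b = _binary(mask)
    labelled, n = measure.label(b, connectivity=3, return_num=True)
    if n != 2:
        raise ValueError(f"expected exactly 2 components (run component_filter first), got {n}")
    counts = np.bincount(labelled.ravel())[1:]
    centroids_x = [c[2] for c in ndimage.center_of_mass(b, labelled, [1, 2])]
    sides = [x >= midline_x for x in centroids_x]  # False = left
    ambiguous = sides[0] == sides[1]
    if ambiguous:
        order = np.argsort(centroids_x)  # fall back to relative order
    else:
        order = np.argsort(sides)  # left (False) first
    v_left = int(counts[order[0]])
    v_right = int(counts[order[1]])
    return BilateralVolumes(
        v_left=v_left,
        v_right=v_right,
        voxel_size=voxel_size,
        side_assignment_ambiguous=bool(ambiguous),
    )


def hemisphere_difference(brain_mask: LabelVolume | np.ndarray, midline_x: int) -> float:
    """Signed percent volume difference of tissue right vs left of the midline."""
    b = _binary(brain_mask)
    if not (0 < midline_x < b.shape[2]):
        raise ValueError(f"midline column {midline_x} leaves an empty side in width {b.shape[2]}")
    v_left = int(np.count_nonzero(b[:, :, :midline_x]))
    v_right = int(np.count_nonzero(b[:, :, midline_x:]))
    if v_left == 0 or v_right == 0:
        raise ValueError(f"empty hemisphere (left={v_left}, right={v_right})")
    return 100.0 * (v_right - v_left) / ((v_left + v_right) / 2.0)


# ---------------------------------------------------------------------------
# Cohort statistics


@dataclass
class CohortSummary:
    """Exceedance statistics of signed percent differences over a cohort."""

    n: int
    threshold_pct: float
    n_exceeding: int
    fraction_exceeding: float
    histogram_counts: np.ndarray = field(repr=False, default=None)
    histogram_edges: np.ndarray = field(repr=False, default=None)
    estimated_valid_n: int | None = None
    extrapolated_fraction_pct: float | None = None


def estimate_valid_population(validity_rate: float, population: int) -> int:
    """Truncated product ``floor(r * N)`` — the estimated number of valid samples."""
    if not (0.0 < validity_rate <= 1.0):
        raise ValueError("validity_rate must be in (0, 1]")
    return int(math.floor(validity_rate * population))


def cohort_summary(
    results: list[BilateralVolumes] | list[float],
    threshold_pct: float = 10.0,
    n_bins: int = 20,
    validity_rate: float | None = None,
    population: int | None = None,
    n_valid_exceeding: int | None = None,
) -> CohortSummary:
    """Count cohort members whose |percent difference| exceeds a threshold.

    ``results`` may be :class:`BilateralVolumes` or raw signed percent
    differences.  When a sample ``validity_rate`` and a filtered
    ``population`` are given, the valid population is estimated as
    ``floor(r * N)`` and the reported extrapolated fraction is
    ``100 * k / floor(r * N)`` with ``k`` the (manually verified) number of
    valid exceedances — by default the cohort's own exceedance count.
    """
    if len(results) == 0:
        raise ValueError("empty cohort")
    diffs = np.array(
        [r.percent_diff if isinstance(r, BilateralVolumes) else float(r) for r in results]
    )
    exceeding = np.abs(diffs) > threshold_pct
    counts, edges = np.histogram(diffs, bins=n_bins)

    est_n = None
    extrap = None
    if validity_rate is not None and population is not None:
        est_n = estimate_valid_population(validity_rate, population)
        k = int(exceeding.sum()) if n_valid_exceeding is None else int(n_valid_exceeding)
        extrap = 100.0 * k / est_n
    return CohortSummary(
        n=len(diffs),
        threshold_pct=threshold_pct,
        n_exceeding=int(exceeding.sum()),
        fraction_exceeding=float(exceeding.mean()),
        histogram_counts=counts,
        histogram_edges=edges,
        estimated_valid_n=est_n,
        extrapolated_fraction_pct=extrap,
    )


def verification_success_rate(n_inspected: int, n_failures: int) -> float:
    """Percent of inspected segmentations that passed manual verification."""
    if n_inspected < 1 or not (0 <= n_failures <= n_inspected):
        raise ValueError("need 0 <= n_failures <= n_inspected, n_inspected >= 1")
    return 100.0 * (n_inspected - n_failures) / n_inspected


def annotation_effort_hours(n_brains: int, n_structures: int, hours_per_structure: float) -> float:
    """Total manual annotation effort for a full labelling campaign."""
    if n_brains < 0 or n_structures < 0 or hours_per_structure < 0:
        raise ValueError("inputs must be non-negative")
    return float(n_brains * n_structures * hours_per_structure)


def cross_model_consistency(
    diffs_a: list[float] | np.ndarray, diffs_b: list[float] | np.ndarray
) -> tuple[float, float, float]:
    """OLS regression of model B's percent differences on model A's.

    Returns ``(slope, intercept, correlation)``.
    """
    a = np.asarray(diffs_a, dtype=np.float64)
    b = np.asarray(diffs_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"paired lists must have equal length: {a.shape} vs {b.shape}")
    if a.size < 3:
        raise ValueError(f"need at least 3 pairs, got {a.size}")
    va = a.var()
    if va == 0:
        raise ValueError("zero variance in the reference differences")
    cov = np.mean((a - a.mean()) * (b - b.mean()))
    slope = float(cov / va)
    intercept = float(b.mean() - slope * a.mean())
    sb = b.std()
    corr = 0.0 if sb == 0 else float(cov / (a.std() * sb))
    return slope, intercept, corr
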