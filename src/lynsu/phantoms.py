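"""Synthetic phantom brains with known ground truth.

A phantom is a 3D stack containing bright multi-lobed ellipsoid composites
("neuropils") on a noisy textured background.  Bilateral structures are
placed mirror-symmetrically about a sagittal midline column and the right
component is rescaled to plant a controllable signed volume asymmetry.
Every phantom carries its exact voxel masks, tight projection bounding
boxes and midline, so detector and segmenter stages can be trained and
scored without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_formats import BoundingBox2D, LabelVolume, VolumeStack

__all__ = [
    "StructureSpec",
    "PhantomSpec",
    "PhantomTruth",
    "default_structures",
    "generate_phantom",
    "generate_cohort",
]


@dataclass(frozen=True)
class StructureSpec:
    """Geometry of one phantom structure.

    ``laterality`` is ``"bilateral"`` (two mirrored components) or
    ``"midline"`` (a single component straddling the midline).
    ``center_frac`` is the (z, y, x-offset) placement: z and y are fractions
    of the volume shape, x-offset is the fraction of X separating a
    bilateral component's centre from the midline (ignored for midline
    structures).
    """

    laterality: str
    base_radii: tuple[float, float, float]  # (rz, ry, rx) voxels
    lobe_count: int = 1
    center_frac: tuple[float, float, float] = (0.5, 0.5, 0.25)
    intensity_boost: float = 110.0

    def __post_init__(self) -> None:
        if self.laterality not in ("bilateral", "midline"):
            raise ValueError(f"laterality must be bilateral|midline, got {self.laterality!r}")
        if self.lobe_count < 1 or self.lobe_count > 3:
            raise ValueError("lobe_count must be 1..3")
        if any(r <= 0 for r in self.base_radii):
            raise ValueError("radii must be positive")


def default_structures(shape: tuple[int, int, int]) -> dict[str, StructureSpec]:
    """Three structures (two bilateral, one midline) scaled to ``shape``."""
    s = min(shape[1], shape[2]) / 256.0
    sz = shape[0] / 64.0
    return {
        "AL": StructureSpec(
            laterality="bilateral",
            base_radii=(7 * sz, 11 * s, 11 * s),
            lobe_count=1,
            center_frac=(0.52, 0.72, 0.29),
            intensity_boost=115.0,
        ),
        "MB_CAL": StructureSpec(
            laterality="bilateral",
            base_radii=(9 * sz, 13 * s, 11 * s),
            lobe_count=2,
            center_frac=(0.48, 0.38, 0.21),
            intensity_boost=105.0,
        ),
        "CX": StructureSpec(
            laterality="midline",
            base_radii=(7 * sz, 10 * s, 17 * s),
            lobe_count=1,
            center_frac=(0.50, 0.55, 0.0),
            intensity_boost=110.0,
        ),
    }


@dataclass
class PhantomSpec:
    """Full description of one synthetic brain."""

    shape: tuple[int, int, int] = (64, 256, 256)
    structures: dict[str, StructureSpec] | None = None
    asymmetry: float = 0.0  # signed fractional right-vs-left volume difference
    noise_sd: float = 8.0
    background_level: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.structures is None:
            self.structures = default_structures(self.shape)
        if abs(self.asymmetry) >= 1.0:
            raise ValueError(f"|asymmetry| must be < 1, got {self.asymmetry}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name, st in self.structures.items():
            if any(2 * r >= dim for r, dim in zip(st.base_radii, self.shape)):
                raise ValueError(f"structure {name}: radii {st.base_radii} exceed volume {self.shape}")


@dataclass
class PhantomTruth:
    """A generated phantom with its complete ground truth."""

    volume: VolumeStack
    masks: dict[str, LabelVolume]
    boxes: list[BoundingBox2D]
    midline_x: int
    spec: PhantomSpec
    component_volumes: dict[str, tuple[int, ...]] = field(default_factory=dict)
    """Voxel counts per structure component, left-to-right order."""

    def measured_asymmetry(self, structure: str) -> float:
        """Signed percent volume difference (right vs left) from the true masks."""
        vols = self.component_volumes[structure]
        if len(vols) != 2:
            raise ValueError(f"{structure} is not bilateral")
        v_l, v_r = vols
        return 100.0 * (v_r - v_l) / ((v_l + v_r) / 2.0)


# ---------------------------------------------------------------------------


def _lobe_layout(st: StructureSpec, rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    """Relative lobe centres and radii for one structure component.

    Offsets stay below ~0.8 of the radii so the union is connected.
    """
    rz, ry, rx = st.base_radii
    lobes = []
    for i in range(st.lobe_count):
        if i == 0:
            off = np.zeros(3)
            scale = 1.0
        else:
            direction = np.array([(-1) ** i * 0.4, 0.7 if i == 1 else -0.7, 0.3])
            off = direction * np.array([rz, ry, rx]) + rng.uniform(-1.0, 1.0, size=3)
            scale = 0.75
        radii = np.array([rz, ry, rx]) * scale * rng.uniform(0.92, 1.0)
        lobes.append((off, radii))
    return lobes


def _rasterize_lobes(
    shape: tuple[int, int, int],
    center: np.ndarray,
    lobes: list[tuple[np.ndarray, np.ndarray]],
    radius_scale: float = 1.0,
    mirror_x: int | None = None,
) -> np.ndarray:
    """Union-of-ellipsoids boolean mask; optionally x-mirrored about a column.

    ``mirror_x`` reflects lobe centres through ``x -> 2*mirror_x - 1 - x`` so a
    bilateral pair is voxel-exact mirror symmetric at ``radius_scale == 1``.
    """
    mask = np.zeros(shape, dtype=bool)
    for off, radii in lobes:
        c = center + off
        r = radii * radius_scale
        if mirror_x is not None:
            c = c.copy()
            c[2] = 2 * mirror_x - 1 - c[2]
        z0 = max(0, int(math.floor(c[0] - r[0])))
        z1 = min(shape[0], int(math.ceil(c[0] + r[0])) + 1)
        y0 = max(0, int(math.floor(c[1] - r[1])))
        y1 = min(shape[1], int(math.ceil(c[1] + r[1])) + 1)
        x0 = max(0, int(math.floor(c[2] - r[2])))
        x1 = min(shape[2], int(math.ceil(c[2] + r[2])) + 1)
        if z0 >= z1 or y0 >= y1 or x0 >= x1:
            continue
        zz, yy, xx = np.ogrid[z0:z1, y0:y1, x0:x1]
        inside = (
            ((zz - c[0]) / r[0]) ** 2 + ((yy - c[1]) / r[1]) ** 2 + ((xx - c[2]) / r[2]) ** 2
        ) <= 1.0
        mask[z0:z1, y0:y1, x0:x1] |= inside
    return mask


def _fit_right_scale(
    shape: tuple[int, int, int],
    center: np.ndarray,
    lobes: list[tuple[np.ndarray, np.ndarray]],
    midline_x: int,
    target_volume: int,
) -> np.ndarray:
    """Bisect the radius scale of the mirrored component to hit a voxel count."""
    lo, hi = 0.6, 1.5
    cache: dict[float, int] = {}

    def vol(s: float) -> int:
        if s not in cache:
            cache[s] = int(_rasterize_lobes(shape, center, lobes, s, mirror_x=midline_x).sum())
        return cache[s]

    if not (vol(lo) <= target_volume <= vol(hi)):
        raise ValueError("requested asymmetry is outside the attainable range for this geometry")
    for _ in range(22):
        mid = 0.5 * (lo + hi)
        if vol(mid) < target_volume:
            lo = mid
        else:
            hi = mid
    best = min((lo, hi), key=lambda s: abs(vol(s) - target_volume))
    return _rasterize_lobes(shape, center, lobes, best, mirror_x=midline_x)


def _tight_box(mask: np.ndarray, roi_class: str) -> BoundingBox2D:
    proj = mask.any(axis=0)
    ys, xs = np.nonzero(proj)
    return BoundingBox2D(
        roi_class=roi_class,
        x0=int(xs.min()),
        y0=int(ys.min()),
        x1=int(xs.max()) + 1,
        y1=int(ys.max()) + 1,
        confidence=1.0,
    )


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Deterministically generate one phantom from its spec.

    Bilateral structures are mirror symmetric about the midline column; the
    right component is then rescaled so the signed percent volume difference
    matches ``spec.asymmetry`` up to voxel discretization (within ~2%%).
    """
    rng = np.random.default_rng(spec.seed)
    Z, Y, X = spec.shape
    midline_x = X // 2
    a = spec.asymmetry

    occupancy = np.zeros(spec.shape, dtype=bool)
    masks: dict[str, LabelVolume] = {}
    boxes: list[BoundingBox2D] = []
    component_volumes: dict[str, tuple[int, ...]] = {}
    intensity = np.full(spec.shape, spec.background_level, dtype=np.float32)

    for name, st in spec.structures.items():
        fz, fy, fx = st.center_frac
        jitter = rng.uniform(-2.0, 2.0, size=3)
        lobes = _lobe_layout(st, rng)
        if st.laterality == "bilateral":
            center_l = np.array([fz * Z, fy * Y, midline_x - fx * X]) + jitter
            rx_max = max(o[2] + r[2] * 1.5 for o, r in lobes)
            if center_l[2] + rx_max >= midline_x:
                raise ValueError(f"structure {name}: bilateral component would cross the midline")
            left = _rasterize_lobes(spec.shape, center_l, lobes)
            v_left = int(left.sum())
            if v_left == 0:
                raise ValueError(f"structure {name}: empty mask after rasterization")
            # target V_R from percent-difference a: V_R/V_L = (2 + a) / (2 - a)
            target = int(round(v_left * (2.0 + a) / (2.0 - a)))
            if a == 0.0:
                right = _rasterize_lobes(spec.shape, center_l, lobes, mirror_x=midline_x)
            else:
                right = _fit_right_scale(spec.shape, center_l, lobes, midline_x, target)
            mask = left | right
            component_volumes[name] = (v_left, int(right.sum()))
            per_component = [left, right]
        else:
            center = np.array([fz * Z, fy * Y, float(midline_x)]) + jitter
            mask = _rasterize_lobes(spec.shape, center, lobes)
            if not mask.any():
                raise ValueError(f"structure {name}: empty mask after rasterization")
            component_volumes[name] = (int(mask.sum()),)
            per_component = [mask]

        if (occupancy & mask).any():
            raise ValueError(f"structure {name} overlaps a previously placed structure")
        occupancy |= mask
        masks[name] = LabelVolume(mask.astype(np.uint8), classes=("background", name))
        boxes.extend(_tight_box(m, name) for m in per_component)
        intensity[mask] += st.intensity_boost

    # mild blur for soft edges, then texture noise; masks stay exact
    intensity = gaussian_filter(intensity, sigma=(0.5, 0.8, 0.8))
    if spec.noise_sd > 0:
        intensity += rng.normal(0.0, spec.noise_sd, size=spec.shape).astype(np.float32)
    data = np.clip(np.rint(intensity), 0, 255).astype(np.uint8)

    volume = VolumeStack(data, source_id=f"phantom-{spec.seed:06d}")
    return PhantomTruth(
        volume=volume,
        masks=masks,
        boxes=boxes,
        midline_x=midline_x,
        spec=spec,
        component_volumes=component_volumes,
    )


# ---------------------------------------------------------------------------


def _make_sampler(asymmetry_sampler):
    """Normalize a sampler spec to a callable ``f(rng, i) -> float``.

    Accepts a constant, a callable ``f(rng) -> float``, a sequence cycled by
    phantom index, or a dict ``{"kind": constant|uniform|normal|choice, ...}``.
    """
    if callable(asymmetry_sampler):
        return lambda rng, i: float(asymmetry_sampler(rng))
    if isinstance(asymmetry_sampler, (int, float)):
        return lambda rng, i: float(asymmetry_sampler)
    if isinstance(asymmetry_sampler, (list, tuple)):
        values = [float(v) for v in asymmetry_sampler]
        return lambda rng, i: values[i % len(values)]
    if isinstance(asymmetry_sampler, dict):
        kind = asymmetry_sampler.get("kind")
        if kind == "constant":
            v = float(asymmetry_sampler["value"])
            return lambda rng, i: v
        if kind == "uniform":
            lo, hi = float(asymmetry_sampler["low"]), float(asymmetry_sampler["high"])
            if hi < lo:
                raise ValueError("uniform sampler requires low <= high")
            return lambda rng, i: float(rng.uniform(lo, hi))
        if kind == "normal":
            mu, sd = float(asymmetry_sampler["mean"]), float(asymmetry_sampler["sd"])
            if sd < 0:
                raise ValueError("normal sampler requires sd >= 0")
            return lambda rng, i: float(np.clip(rng.normal(mu, sd), -0.9, 0.9))
        if kind == "choice":
            values = [float(v) for v in asymmetry_sampler["values"]]
            probs = asymmetry_sampler.get("probs")
            return lambda rng, i: float(rng.choice(values, p=probs))
        raise ValueError(f"unknown sampler kind {kind!r}")
    raise ValueError(f"cannot interpret asymmetry sampler {asymmetry_sampler!r}")


def generate_cohort(
    n: int,
    asymmetry_sampler=0.0,
    seed: int = 0,
    shape: tuple[int, int, int] = (64, 256, 256),
    noise_sd: float = 8.0,
) -> list[PhantomTruth]:
    """Generate ``n`` independent phantoms with sampled asymmetries."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sample = _make_sampler(asymmetry_sampler)
    cohort = []
    for i in range(n):
        child_seed = int(rng.integers(0, 2**31 - 1))
        a = sample(rng, i)
        spec = PhantomSpec(shape=shape, asymmetry=a, noise_sd=noise_sd, seed=child_seed)
        cohort.append(generate_phantom(spec))
    return cohort
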