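"""Synthetic 3D head-like phantom and acquisition simulator.

A piecewise-constant stack of nested ellipsoids standing in for a head
acquisition: a bright outer shell (skull), uniform brain matter, a few
internal structures of differing intensity (ventricle-like lobes), and a
handful of 1–3 voxel high-contrast details that probe detail preservation.
The default geometry is 27 slices of 128 x 128 voxels. Intensities are
additive per ellipsoid (later structures add to earlier ones) and live in
roughly [20, 100] arbitrary units, so noise scales in [0.5, 8] sweep the
image from nearly clean to heavily degraded.

The simulator corrupts the phantom with additive Rayleigh noise — the
low-SNR limit of the Rice law for magnitude MR data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import binary_erosion, binary_fill_holes

from .noise import add_noise
from .volume import ImageStack

__all__ = [
    "Ellipsoid",
    "PhantomSpec",
    "generate_head_phantom",
    "simulate_acquisition",
    "brain_mask",
]


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-angle ellipsoid with an additive intensity contribution.

    center and semi_axes are in voxel-index units (row, column, slice);
    angle_deg rotates the ellipsoid in the slice plane.
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    intensity: float
    angle_deg: float = 0.0


@dataclass
class PhantomSpec:
    """Geometry and content of the synthetic phantom.

    With ``ellipsoids=None`` the default head-like layout for ``dims`` is
    used; an explicit empty list produces an all-zero volume. ``texture``
    adds a low-amplitude smooth modulation inside the brain so that not
    every region is perfectly flat.
    """

    dims: tuple[int, int, int] = (128, 128, 27)
    spacing: tuple[float, float, float] = (1.8, 1.8, 5.0)
    ellipsoids: list | None = None
    n_details: int = 6
    texture: bool = True
    texture_amplitude: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dims):
            raise ValueError(f"dims must be positive, got {self.dims}")


def _default_ellipsoids(dims: tuple[int, int, int]) -> list[Ellipsoid]:
    """Nested head-like layout scaled to the volume dimensions.

    The slice semi-axis exceeds the slab half-depth, so the first and last
    slices cut through the head — as in a real axial acquisition, where the
    imaged slab truncates the anatomy. Voxels on those faces therefore
    carry signal while having clipped neighborhoods.
    """
    cu, cv, cs = (d / 2.0 - 0.5 for d in dims)
    ru, rv, rs = dims[0] * 0.42, dims[1] * 0.36, dims[2] * 0.62
    return [
        # outer skull shell: bright ellipsoid ...
        Ellipsoid((cu, cv, cs), (ru, rv, rs), 90.0),
        # ... hollowed by a slightly smaller one down to brain-matter level
        Ellipsoid((cu, cv, cs), (ru * 0.90, rv * 0.88, rs * 0.92), -50.0),
        # ventricle-like darker lobes
        Ellipsoid(
            (cu - dims[0] * 0.06, cv - dims[1] * 0.08, cs),
            (dims[0] * 0.05, dims[1] * 0.14, dims[2] * 0.25),
            -12.0,
            angle_deg=20.0,
        ),
        Ellipsoid(
            (cu - dims[0] * 0.06, cv + dims[1] * 0.08, cs),
            (dims[0] * 0.05, dims[1] * 0.14, dims[2] * 0.25),
            -12.0,
            angle_deg=-20.0,
        ),
        # brighter deep structure
        Ellipsoid(
            (cu + dims[0] * 0.14, cv, cs),
            (dims[0] * 0.10, dims[1] * 0.08, dims[2] * 0.20),
            25.0,
        ),
        # small low-intensity lesion-like inclusion
        Ellipsoid(
            (cu + dims[0] * 0.02, cv - dims[1] * 0.20, cs + dims[2] * 0.1),
            (dims[0] * 0.04, dims[1] * 0.04, dims[2] * 0.10),
            18.0,
        ),
    ]


def _ellipsoid_mask(dims, e: Ellipsoid) -> np.ndarray:
    ii, jj, kk = np.meshgrid(
        np.arange(dims[0], dtype=np.float64),
        np.arange(dims[1], dtype=np.float64),
        np.arange(dims[2], dtype=np.float64),
        indexing="ij",
    )
    di = ii - e.center[0]
    dj = jj - e.center[1]
    dk = kk - e.center[2]
    th = np.deg2rad(e.angle_deg)
    ri = di * np.cos(th) + dj * np.sin(th)
    rj = -di * np.sin(th) + dj * np.cos(th)
    q = (
        (ri / e.semi_axes[0]) ** 2
        + (rj / e.semi_axes[1]) ** 2
        + (dk / e.semi_axes[2]) ** 2
    )
    return q <= 1.0


def generate_head_phantom(spec: PhantomSpec | None = None) -> ImageStack:
    """Deterministic piecewise-constant ground-truth volume.

    The returned stack's ``meta`` records the spec, the brain mask (inside
    the outermost ellipsoid), a large flat-region mask, and the positions
    of the small high-contrast details, so downstream adaptivity and
    boundary analyses need no re-segmentation.
    """
    spec = spec or PhantomSpec()
    dims = spec.dims
    ellipsoids = (
        _default_ellipsoids(dims) if spec.ellipsoids is None else list(spec.ellipsoids)
    )
    vol = np.zeros(dims, dtype=np.float64)
    outer_mask = None
    for e in ellipsoids:
        m = _ellipsoid_mask(dims, e)
        if not m.any():
            warnings.warn(f"ellipsoid {e} lies entirely outside the volume; clipped")
        vol[m] += e.intensity
        if outer_mask is None:
            outer_mask = m
    if outer_mask is None:
        outer_mask = np.zeros(dims, dtype=bool)

    rng = np.random.default_rng(spec.seed)

    # interior of the brain: strictly inside the shell hollow
    interior = _ellipsoid_mask(
        dims,
        Ellipsoid(
            ellipsoids[0].center if ellipsoids else (0, 0, 0),
            tuple(s * 0.80 for s in (ellipsoids[0].semi_axes if ellipsoids else (1, 1, 1))),
            0.0,
        ),
    ) if ellipsoids else np.zeros(dims, dtype=bool)

    texture_mask = np.zeros(dims, dtype=bool)
    if spec.texture and ellipsoids and interior.any():
        # low-amplitude smooth modulation in one brain octant
        ii, jj, kk = np.meshgrid(
            np.arange(dims[0]), np.arange(dims[1]), np.arange(dims[2]), indexing="ij"
        )
        octant = (ii > dims[0] / 2) & (jj > dims[1] / 2)
        texture_mask = interior & octant
        wave = np.sin(2 * np.pi * ii / 9.0) * np.sin(2 * np.pi * jj / 11.0)
        vol[texture_mask] += spec.texture_amplitude * wave[texture_mask]

    details: list[tuple[int, int, int]] = []
    if ellipsoids and interior.any() and spec.n_details > 0:
        # erode so each detail's in-plane surroundings are themselves flat
        flat_candidates = binary_erosion(
            interior & ~texture_mask, structure=np.ones((9, 9, 3), dtype=bool)
        )
        coords = np.argwhere(flat_candidates)
        picks = rng.choice(len(coords), size=min(spec.n_details * 4, len(coords)), replace=False)
        for p in picks:
            if len(details) >= spec.n_details:
                break
            c = tuple(int(x) for x in coords[p])
            # keep details separated so each stays a <=3 voxel feature
            if any(sum(abs(c[i] - d[i]) for i in range(3)) < 6 for d in details):
                continue
            size = 1 + len(details) % 3  # 1, 2 or 3 voxels, in-plane
            for t in range(size):
                jt = min(c[1] + t, dims[1] - 1)
                vol[c[0], jt, c[2]] += 40.0
            details.append(c)

    vol = np.clip(vol, 0.0, None)

    head = binary_fill_holes(outer_mask)
    flat_region = interior & ~texture_mask
    for c in details:
        # exclude a small halo around each detail from the flat region
        lo = [max(0, c[i] - 3) for i in range(3)]
        hi = [min(dims[i], c[i] + 4) for i in range(3)]
        flat_region[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = False

    meta = {
        "phantom": {
            "dims": tuple(dims),
            "seed": spec.seed,
            "n_details": len(details),
            "detail_locations": details,
        },
        "brain_mask": head,
        "flat_region_mask": flat_region,
        "texture_mask": texture_mask,
    }
    return ImageStack(vol, spec.spacing, meta)


def simulate_acquisition(b: ImageStack, sigma: float, seed: int) -> ImageStack:
    """Noisy acquisition of ground truth ``b``: additive Rayleigh(sigma)."""
    return add_noise(b, sigma, seed)


def brain_mask(b: ImageStack) -> np.ndarray:
    """Evaluation region: inside the outermost ellipsoid of the phantom.

    Uses the mask recorded at generation when available; otherwise the
    filled support of the volume (which coincides with the interior of
    the outer shell for any phantom whose shell is closed).
    """
    if "brain_mask" in b.meta:
        return np.asarray(b.meta["brain_mask"], dtype=bool)
    return binary_fill_holes(b.values > 0)
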