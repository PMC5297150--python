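"""Core 3D volume and neighborhood-geometry types.

An :class:`ImageStack` holds a 3D scalar volume — acquired magnitude data,
a denoised estimate, or a synthetic ground truth — together with its voxel
spacing in millimetres. A :class:`NeighborhoodSystem` describes the local
3D connectivity (6, 18 or full 26) and the physical Euclidean distance of
each neighbor offset, which enters the prior as a distance weight: with
anisotropic voxels (slice thickness typically several times the in-plane
spacing) neighbors across slices are physically farther away and should
constrain a voxel less than in-plane neighbors.

Index convention: 0-based ``(row, column, slice)`` triples; the slice axis
is the third array axis. Neighborhoods are clipped at volume faces — no
padding, no wrap-around — so boundary voxels simply have fewer neighbors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "ImageStack",
    "NeighborhoodSystem",
    "neighbors",
    "pair_distance",
]


@dataclass
class ImageStack:
    """A 3D scalar volume with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (U, V, S)
        Nonnegative finite intensities in arbitrary units; axes are
        (rows, columns, slices).
    spacing : tuple of float
        Voxel spacing in mm along (row, column, slice). All entries must
        be strictly positive.
    meta : dict
        Free-form provenance (phantom spec, noise parameters, masks).
        Never required for correctness.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)
    signed: bool = False  # difference images (residual maps) may go negative

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.values.ndim}")
        if any(d <= 0 for d in self.values.shape):
            raise ValueError(f"all dims must be positive, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if not self.signed and np.any(self.values < 0):
            raise ValueError("volume contains negative intensities")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(
            not np.isfinite(s) or s <= 0 for s in self.spacing
        ):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "ImageStack":
        return ImageStack(self.values.copy(), self.spacing, dict(self.meta), self.signed)


def _offsets_for(connectivity: int) -> list[tuple[int, int, int]]:
    """All nonzero offsets in {-1,0,1}^3 at the requested connectivity.

    26 keeps everything, 18 drops the 8 cube corners, 6 keeps only the
    axis-aligned offsets.
    """
    if connectivity not in (6, 18, 26):
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    out = []
    for o in itertools.product((-1, 0, 1), repeat=3):
        if o == (0, 0, 0):
            continue
        order = sum(abs(c) for c in o)
        if connectivity == 6 and order > 1:
            continue
        if connectivity == 18 and order > 2:
            continue
        out.append(o)
    return out


@dataclass(frozen=True)
class NeighborhoodSystem:
    """A clique system: neighbor offsets plus their physical distances.

    ``offsets`` is symmetric (contains -o for every o) and ``distances``
    maps each offset to the Euclidean mm distance implied by ``spacing``.
    """

    offsets: tuple[tuple[int, int, int], ...]
    distances: tuple[float, ...]

    @classmethod
    def create(
        cls,
        spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
        connectivity: int = 26,
    ) -> "NeighborhoodSystem":
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {spacing}")
        offs = _offsets_for(connectivity)
        dists = tuple(
            float(np.sqrt(sum((o[i] * spacing[i]) ** 2 for i in range(3))))
            for o in offs
        )
        return cls(tuple(offs), dists)

    @classmethod
    def for_stack(cls, stack: ImageStack, connectivity: int = 26) -> "NeighborhoodSystem":
        return cls.create(stack.spacing, connectivity)

    @property
    def size(self) -> int:
        return len(self.offsets)

    def distance_of(self, offset: tuple[int, int, int]) -> float:
        try:
            return self.distances[self.offsets.index(tuple(offset))]
        except ValueError:
            raise KeyError(f"{offset} is not an offset of this system") from None

    def iter_offsets(self) -> Iterator[tuple[tuple[int, int, int], float]]:
        return zip(self.offsets, self.distances)


def neighbors(
    k: tuple[int, int, int],
    dims: tuple[int, int, int],
    connectivity: int = 26,
) -> list[tuple[int, int, int]]:
    """In-bounds members of the neighborhood of voxel ``k``.

    The relation is symmetric: ``q in neighbors(k)`` iff ``k in
    neighbors(q)``. An interior voxel has exactly ``connectivity``
    neighbors; voxels on faces, edges and corners have fewer because
    neighborhoods are clipped at the volume boundary.
    """
    k = tuple(int(c) for c in k)
    if len(k) != 3:
        raise IndexError(f"voxel index must be a 3-tuple, got {k}")
    for c, d in zip(k, dims):
        if not (0 <= c < d):
            raise IndexError(f"voxel {k} out of bounds for dims {dims}")
    out = []
    for o in _offsets_for(connectivity):
        q = (k[0] + o[0], k[1] + o[1], k[2] + o[2])
        if all(0 <= q[i] < dims[i] for i in range(3)):
            out.append(q)
    return out


def pair_distance(
    k: tuple[int, int, int],
    q: tuple[int, int, int],
    spacing: tuple[float, float, float],
) -> float:
    """Euclidean mm distance between voxel centers k and q.

    ``sqrt(sum_axis (delta_index * spacing)^2)``; symmetric in its
    arguments. Raises for a degenerate pair (k == q).
    """
    k = tuple(int(c) for c in k)
    q = tuple(int(c) for c in q)
    if k == q:
        raise ValueError(f"invalid pair: k == q == {k}")
    return float(
        np.sqrt(sum(((k[i] - q[i]) * spacing[i]) ** 2 for i in range(3)))
    )


def resolve_spacing(spacing: tuple[float, float, float] | None) -> tuple[float, float, float]:
    """Fall back to unit isotropic spacing when metadata is missing."""
    if spacing is None:
        warnings.warn(
            "voxel spacing missing; assuming unit isotropic spacing "
            "(distance weights will treat all neighbors as equidistant per axis)",
            stacklevel=2,
        )
        return (1.0, 1.0, 1.0)
    return tuple(float(s) for s in spacing)
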