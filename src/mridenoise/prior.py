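"""Local Gaussian Markov random field prior with per-voxel hyperparameters.

The prior is a Gibbs distribution whose energy penalizes squared intensity
differences between each voxel and its 3D neighbors,

    E(b, theta) = sum_k sum_{q in N_k} (b_k - b_q)^2 / (2 theta_kq^2 d_kq^2),

where ``d_kq`` is the physical distance between the voxel centers and
``theta_kq^2`` a pairwise smoothing hyperparameter. The double sum is taken
literally: every unordered pair contributes once from each direction.

What makes the model *local* — and the filter unsupervised — is that the
hyperparameters are re-estimated from the current image estimate at every
iteration: ``theta_k^2`` is the mean squared difference between voxel k and
its neighbors (a local variance proxy), and the pairwise value is the
arithmetic mean of the two voxel values. In flat regions the differences
are small, theta is small, and the quadratic penalty is strong; across an
edge the differences are large, theta is large, and the penalty nearly
vanishes — smoothing strength adapts to local image structure with no
user-set parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import ImageStack, NeighborhoodSystem

__all__ = [
    "HyperparameterField",
    "energy",
    "update_voxel_hyperparameters",
    "pair_hyperparameter",
    "initialize_hyperparameters",
]

#: absolute floor on theta^2, below any data-derived relative floor
ABS_THETA2_FLOOR = 1e-12

#: relative floor: epsilon = REL_FLOOR * var(a)
REL_THETA2_FLOOR = 1e-6

#: "high value" initialization: H = INIT_SCALE * var(a)
INIT_SCALE = 1e6


@dataclass
class HyperparameterField:
    """Per-voxel theta^2 map (intensity^2 units), floored at a small epsilon.

    Pairwise values theta_kq^2 are derived on demand as arithmetic means of
    the two per-voxel entries; they are never stored.
    """

    theta2_voxel: np.ndarray
    theta2_floor: float

    def __post_init__(self) -> None:
        self.theta2_voxel = np.asarray(self.theta2_voxel, dtype=np.float64)
        self.theta2_floor = float(self.theta2_floor)
        if self.theta2_floor <= 0:
            raise ValueError("theta2_floor must be > 0")
        np.maximum(self.theta2_voxel, self.theta2_floor, out=self.theta2_voxel)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.theta2_voxel.shape


def theta2_floor_for(a: ImageStack) -> float:
    """Data-scaled epsilon preventing division by zero in flat regions."""
    return max(ABS_THETA2_FLOOR, REL_THETA2_FLOOR * float(np.var(a.values)))


def pair_hyperparameter(theta2_k, theta2_q):
    """Pairwise hyperparameter: arithmetic mean of the two voxel values."""
    return 0.5 * (np.asarray(theta2_k) + np.asarray(theta2_q))


def _shifted_views(arr: np.ndarray, offset: tuple[int, int, int]):
    """Aligned (center, neighbor) views of ``arr`` for a given offset.

    ``center[idx]`` pairs with ``neighbor[idx]`` = ``arr`` at position
    idx + offset; only in-bounds pairs are represented.
    """
    sc, sn = [], []
    for o, d in zip(offset, arr.shape):
        if o == 0:
            sc.append(slice(None))
            sn.append(slice(None))
        elif o > 0:
            sc.append(slice(0, d - o))
            sn.append(slice(o, d))
        else:
            sc.append(slice(-o, d))
            sn.append(slice(0, d + o))
    return arr[tuple(sc)], arr[tuple(sn)], tuple(sc), tuple(sn)


def energy(b: ImageStack, h: HyperparameterField, nsys: NeighborhoodSystem) -> float:
    """Distance-weighted LGMRF energy of image ``b`` under hyperparameters ``h``.

    Each unordered neighbor pair contributes twice (once from each voxel's
    sum), matching the double sum as written. Zero iff ``b`` is constant.
    """
    if h.dims != b.dims:
        raise ValueError(f"hyperparameter dims {h.dims} != volume dims {b.dims}")
    vals = b.values
    t2 = h.theta2_voxel
    total = 0.0
    for off, dist in nsys.iter_offsets():
        vc, vn, sc, sn = _shifted_views(vals, off)
        t2_kq = pair_hyperparameter(t2[sc], t2[sn])
        diff = vc - vn
        total += float(np.sum(diff * diff / (2.0 * t2_kq * dist * dist)))
    return total


def update_voxel_hyperparameters(
    b_hat: ImageStack,
    nsys: NeighborhoodSystem,
    floor: float | None = None,
) -> HyperparameterField:
    """Re-estimate theta_k^2 as the local mean squared neighbor difference.

    Interior voxels average over the full neighborhood (26 for the full
    system); voxels with a clipped neighborhood average over their
    in-bounds neighbors only, keeping theta^2 an unbiased local variance
    proxy at the faces. The result is floored at epsilon.
    """
    vals = b_hat.values
    sumsq = np.zeros_like(vals)
    count = np.zeros_like(vals)
    for off, _dist in nsys.iter_offsets():
        vc, vn, sc, sn = _shifted_views(vals, off)
        d = vc - vn
        sumsq[sc] += d * d
        count[sc] += 1.0
    if floor is None:
        floor = theta2_floor_for(b_hat)
    theta2 = sumsq / count
    return HyperparameterField(theta2, floor)


def initialize_hyperparameters(a: ImageStack) -> HyperparameterField:
    """Uniform 'prior off' initialization.

    Before the model has been tuned the hyperparameters are set to a high
    value H so the prior term is numerically negligible next to the
    likelihood in the first minimization: H = 1e6 * var(a) (with a floor
    for degenerate constant inputs).
    """
    var = float(np.var(a.values))
    high = max(INIT_SCALE * var, INIT_SCALE * ABS_THETA2_FLOOR, 1.0)
    floor = theta2_floor_for(a)
    return HyperparameterField(np.full(a.dims, high), floor)
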