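"""Rice/Rayleigh noise models for magnitude MR data.

Magnitude MR intensities follow a Rice distribution; as the underlying
signal-to-noise ratio tends to zero the Rice law degenerates to a Rayleigh
law. The denoiser targets the low-SNR regime and therefore works with the
additive model ``a = b + n`` where ``n`` is Rayleigh-distributed with scale
``sigma`` — the same scale parameter that appears in the Rice density.

This module provides the two densities, a reproducible Rayleigh sampler
(inverse-CDF transform so that results are bit-stable given a pinned
generator), the acquisition simulator, and a maximum-likelihood estimator
of ``sigma`` from background (signal-free) voxels.
"""

from __future__ import annotations

import numpy as np
from scipy.special import i0e

from .volume import ImageStack

__all__ = [
    "NoiseModel",
    "rice_pdf",
    "rayleigh_pdf",
    "sample_rayleigh",
    "add_noise",
    "estimate_sigma",
    "estimate_sigma_corners",
]

#: minimum number of background voxels accepted for sigma estimation
MIN_BACKGROUND_VOXELS = 100


def _check_sigma(sigma: float) -> float:
    sigma = float(sigma)
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValueError(f"scale parameter sigma must be finite and > 0, got {sigma}")
    return sigma


class NoiseModel:
    """Rice/Rayleigh noise with scale parameter ``sigma`` (intensity units)."""

    def __init__(self, sigma: float):
        self.sigma = _check_sigma(sigma)

    def rice(self, a, b):
        return rice_pdf(a, b, self.sigma)

    def rayleigh(self, n):
        return rayleigh_pdf(n, self.sigma)

    def __repr__(self) -> str:
        return f"NoiseModel(sigma={self.sigma})"


def rice_pdf(a, b, sigma: float):
    """Rice density of a magnitude observation ``a`` given signal ``b``.

    ``(a/sigma^2) exp(-(a^2+b^2)/(2 sigma^2)) I0(a b / sigma^2)`` for
    ``a >= 0`` and zero otherwise. At ``b = 0`` this is exactly the
    Rayleigh density (``I0(0) = 1``).

    Uses the exponentially scaled Bessel function ``i0e`` so the density
    is computable without overflow for large ``a b / sigma^2``.
    """
    sigma = _check_sigma(sigma)
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    s2 = sigma * sigma
    # i0e(x) = exp(-|x|) I0(x)  =>  exp(-(a-b)^2/(2 s2)) * i0e(ab/s2)
    with np.errstate(invalid="ignore"):
        dens = (a / s2) * np.exp(-((a - b) ** 2) / (2.0 * s2)) * i0e(a * b / s2)
    dens = np.where(a >= 0, dens, 0.0)
    if dens.ndim == 0:
        return float(dens)
    return dens


def rayleigh_pdf(n, sigma: float):
    """Rayleigh density ``(n/sigma^2) exp(-n^2 / (2 sigma^2))`` for n >= 0."""
    sigma = _check_sigma(sigma)
    n = np.asarray(n, dtype=np.float64)
    s2 = sigma * sigma
    dens = np.where(n >= 0, (n / s2) * np.exp(-(n * n) / (2.0 * s2)), 0.0)
    if dens.ndim == 0:
        return float(dens)
    return dens


def sample_rayleigh(dims: tuple[int, int, int], sigma: float, seed: int) -> np.ndarray:
    """I.i.d. Rayleigh(sigma) noise field of the given shape.

    Drawn by the inverse-CDF transform ``n = sigma * sqrt(-2 ln U)`` with
    ``U ~ Uniform(0, 1)`` from a PCG64 generator, so the field is
    bit-identical across runs given the same (dims, sigma, seed).
    """
    sigma = _check_sigma(sigma)
    rng = np.random.default_rng(seed)
    # uniform(0,1] to avoid log(0); 1 - uniform[0,1) is in (0,1]
    u = 1.0 - rng.random(size=tuple(dims))
    return sigma * np.sqrt(-2.0 * np.log(u))


def add_noise(b: ImageStack, sigma: float, seed: int) -> ImageStack:
    """Simulate acquisition: ``a = b + n`` with Rayleigh(sigma) noise.

    Spacing is preserved; the noise parameters are recorded in the
    output's ``meta``. Because Rayleigh noise is nonnegative, ``a >= b``
    everywhere.
    """
    noise = sample_rayleigh(b.dims, sigma, seed)
    meta = dict(b.meta)
    meta.update({"noise": {"model": "rayleigh", "sigma": float(sigma), "seed": int(seed)}})
    return ImageStack(b.values + noise, b.spacing, meta)


def estimate_sigma(a: ImageStack, background_mask: np.ndarray) -> float:
    """Rayleigh ML estimate of sigma from signal-free voxels.

    Where the true signal vanishes the acquired intensity is pure Rayleigh
    noise, and the ML estimator is ``sqrt(sum a^2 / (2 N))``. The mask
    must select at least ``MIN_BACKGROUND_VOXELS`` voxels.
    """
    mask = np.asarray(background_mask, dtype=bool)
    if mask.shape != a.dims:
        raise ValueError(f"mask shape {mask.shape} != volume dims {a.dims}")
    n = int(mask.sum())
    if n < MIN_BACKGROUND_VOXELS:
        raise ValueError(
            f"insufficient background data: mask selects {n} voxels, "
            f"need at least {MIN_BACKGROUND_VOXELS}"
        )
    vals = a.values[mask]
    return float(np.sqrt(np.sum(vals * vals) / (2.0 * n)))


def estimate_sigma_corners(a: ImageStack, fraction: float = 0.1) -> float:
    """Estimate sigma from the eight corner patches of the volume.

    Heuristic for head acquisitions, where the axial corners of the field
    of view contain air (pure noise). Each corner patch spans ``fraction``
    of each dimension; patches grow automatically on small volumes until
    enough background voxels are collected. The union of the eight patches
    is passed to :func:`estimate_sigma`.
    """
    if not (0 < fraction < 0.5):
        raise ValueError(f"fraction must be in (0, 0.5), got {fraction}")
    dims = a.dims
    while True:
        ext = [max(1, int(round(fraction * d))) for d in dims]
        mask = np.zeros(dims, dtype=bool)
        for ci in (slice(0, ext[0]), slice(dims[0] - ext[0], dims[0])):
            for cj in (slice(0, ext[1]), slice(dims[1] - ext[1], dims[1])):
                for ck in (slice(0, ext[2]), slice(dims[2] - ext[2], dims[2])):
                    mask[ci, cj, ck] = True
        if mask.sum() >= MIN_BACKGROUND_VOXELS or fraction >= 0.45:
            return estimate_sigma(a, mask)
        fraction = min(fraction * 1.4, 0.45)
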