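"""Quality indexes for denoising evaluation.

Masked MSE, masked single-scale SSIM (computed slice-wise with the
standard 11-voxel Gaussian window, then averaged over the masked voxels),
signed residual maps, and an SNR-in-dB convenience. The mask restricts
evaluation to the anatomy of interest (e.g. the brain region of the
phantom) so background voxels do not dilute the indexes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from skimage.metrics import structural_similarity

from .volume import ImageStack

__all__ = ["EvaluationReport", "mse", "ssim", "residual_map", "snr_db", "evaluate"]


@dataclass
class EvaluationReport:
    """Quality indexes over a masked region; serializable round-trip JSON."""

    mse: float
    ssim: float
    snr_db: float
    n_voxels: int

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "EvaluationReport":
        return cls(**json.loads(s))


def _check_pair(x: ImageStack, y: ImageStack, mask) -> np.ndarray:
    if x.dims != y.dims:
        raise ValueError(f"shape mismatch: {x.dims} vs {y.dims}")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != x.dims:
        raise ValueError(f"mask shape {mask.shape} != volume dims {x.dims}")
    if not mask.any():
        raise ValueError("mask is empty")
    return mask


def mse(x: ImageStack, y: ImageStack, mask) -> float:
    """Mean squared difference over the masked voxels."""
    mask = _check_pair(x, y, mask)
    d = (x.values - y.values)[mask]
    return float(np.mean(d * d))


def ssim(
    x: ImageStack,
    y: ImageStack,
    mask,
    data_range: float | None = None,
    slice_index: int | None = None,
) -> float:
    """Masked single-scale structural similarity.

    SSIM maps are computed per slice with an 11-voxel Gaussian window
    (sigma 1.5, K1=0.01, K2=0.03) and averaged over the masked voxels of
    every slice (or of ``slice_index`` only). ``data_range`` defaults to
    the peak intensity of ``x``, intended to be the noise-free reference.
    """
    mask = _check_pair(x, y, mask)
    if data_range is None:
        data_range = float(x.values.max())
        if data_range <= 0:
            data_range = 1.0
    slices = range(x.dims[2]) if slice_index is None else [slice_index]
    num = 0.0
    cnt = 0
    for s in slices:
        m = mask[:, :, s]
        if not m.any():
            continue
        _, smap = structural_similarity(
            x.values[:, :, s],
            y.values[:, :, s],
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            K1=0.01,
            K2=0.03,
            use_sample_covariance=False,
            data_range=data_range,
            full=True,
        )
        num += float(smap[m].sum())
        cnt += int(m.sum())
    if cnt == 0:
        raise ValueError("mask is empty on the selected slices")
    return num / cnt


def residual_map(before: ImageStack, after: ImageStack) -> ImageStack:
    """Signed voxelwise difference before - after (the removed component)."""
    if before.dims != after.dims:
        raise ValueError(f"shape mismatch: {before.dims} vs {after.dims}")
    return ImageStack(
        before.values - after.values,
        before.spacing,
        {"residual_of": "before - after"},
        signed=True,
    )


def snr_db(b: ImageStack, sigma: float, mask) -> float:
    """Signal-to-noise ratio in dB: 10 log10( mean(b^2) / (2 sigma^2) ).

    The denominator 2 sigma^2 is the Rayleigh second moment E[n^2], so
    this is the masked mean signal power over the mean noise power. The
    definition is pinned here so figures are comparable across runs of
    this package.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != b.dims:
        raise ValueError(f"mask shape {mask.shape} != volume dims {b.dims}")
    if not mask.any():
        raise ValueError("mask is empty")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    p = float(np.mean(b.values[mask] ** 2))
    return float(10.0 * np.log10(p / (2.0 * sigma * sigma)))


def evaluate(
    truth: ImageStack,
    test: ImageStack,
    mask,
    sigma: float | None = None,
) -> EvaluationReport:
    """Bundle masked MSE, SSIM and (if sigma given) SNR into one report."""
    m = _check_pair(truth, test, mask)
    return EvaluationReport(
        mse=mse(truth, test, m),
        ssim=ssim(truth, test, m),
        snr_db=snr_db(truth, sigma, m) if sigma else float("nan"),
        n_voxels=int(m.sum()),
    )
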