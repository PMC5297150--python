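# Methods

## Model

Acquired magnitude MR intensities follow a Rice law with scale σ. In the
low-SNR limit (signal → 0) the Rice density degenerates to a Rayleigh
density, and the acquisition can be written additively as `a = b + n`,
`n ~ Rayleigh(σ)`, n ≥ 0. The denoiser works exclusively in this low-SNR
approximation: the likelihood of a voxel is

    f(a_k | b_k) = ((a_k − b_k)/σ²) · exp(−(a_k − b_k)²/(2σ²)) · u(a_k − b_k),

which constrains the estimate to `0 < b_k < a_k`. The full Rice density is
implemented for simulation and testing (and to verify the b → 0 limit)
but is never used as an estimator.

The prior on the noise-free image is a Gibbs distribution whose energy is
a distance-weighted local Gaussian MRF:

    E(b, θ) = Σ_k Σ_{q∈N_k} (b_k − b_q)² / (2 θ²_{k,q} d²_{k,q}),

with `N_k` the 26-voxel neighborhood, `d_{k,q}` the Euclidean distance in
mm between voxel centers (computed from the spacing metadata; anisotropic
spacing therefore weakens coupling across slices — no resampling is
performed), and `θ²_{k,q}` pairwise hyperparameters. The double sum is
taken literally, so each unordered pair contributes once from each
direction; the per-voxel conditional objective consequently carries a
factor 2 on its prior term. The Gibbs normalization constant cancels in
the MAP objective and is never computed.

The hyperparameters are what make the filter adaptive and unsupervised.
After each outer iteration they are re-estimated as

    θ̂²_k = (1/|N_k|) Σ_{q∈N_k} (b̂_k − b̂_q)²,   θ̂²_{k,q} = (θ̂²_k + θ̂²_q)/2.

θ̂²_k is a local variance proxy: ≈ 2·(noise variance) in flat regions,
large across edges. Low θ² ⇒ high assumed spatial correlation ⇒ strong
smoothing; high θ² ⇒ an edge is likely ⇒ weak smoothing.

## Optimization

The negative log-posterior is minimized by exact per-voxel coordinate
descent (iterated conditional modes). Holding the neighbors fixed, the
per-voxel objective in `t = a_k − b_k`,

    −log t + t²/(2σ²) + 2 Σ_q w_{k,q} (a_k − t − b_q)²,   w_{k,q} = 1/(2 θ²_{k,q} d²_{k,q}),

is strictly convex on t > 0 (the −log t barrier enforces b < a), and its
stationarity condition multiplied by t is the quadratic

    (1/σ² + W) t² − (W a_k − C) t − 1 = 0,   W = 4 Σ w_{k,q},  C = 4 Σ w_{k,q} b_q,

whose constant term −1 guarantees one positive and one negative root. The
positive root is the unique unconstrained minimizer, so every coordinate
update is available in closed form; no iterative line search is needed.
When the root gives b ≤ 0 the convex objective is increasing on (0, a_k)
and the solution clamps just above 0. With W = C = 0 the root is exactly
t = σ, recovering the prior-free solution b = a − σ.

Sweep order. Two orders are provided. "checkerboard" (the default)
partitions the volume into the 8 parity classes (i mod 2, j mod 2,
k mod 2); voxels in one class are never 26-neighbors of each other, so a
whole class is updated simultaneously with vectorized array arithmetic
(Gauss–Seidel across classes). "raster" is the literal voxel-by-voxel
loop; both are exact coordinate descent and both monotonically decrease
the global objective, but raster is only practical on small volumes and
is kept as a reference implementation. The full 26-neighborhood sweep of
a 128×128×27 volume takes well under a second.

Outer loop. The estimate starts at the prior-free MAP solution
b⁰ = clamp(a − σ), with hyperparameters initialized uniformly to the
"prior off" value H = 1e6 · var(a) so the first minimization is governed
by the likelihood alone (the prior perturbs it by O(1e−5) intensity
units). Each outer iteration runs one ICM sweep (configurable) and then
re-estimates θ. Iteration stops when the mean absolute correction,
normalized by the mean intensity, drops below 1e−3 (default), or after 50
iterations. Because the first iteration's correction is ~0 by
construction (b⁰ already minimizes the prior-free objective), convergence
is only declared from iteration 2 onward. On the reference phantom the
loop converges in 6–8 outer iterations. The solver contains no
randomness: identical inputs give bit-identical results.

Numerical safeguards: θ² is floored at ε = max(1e−12, 1e−6 · var(a)) so
perfectly flat regions never divide by zero; estimates are clamped to the
open box (δ, a_k − δ) with δ = 1e−9 · max(a); voxels with a_k ≤ 2δ (no
feasible interval) are left at a_k/2 and excluded from the correction
statistic. At volume faces the neighborhood is clipped (no padding or
wrap) and the θ̂²_k normalizer is the in-bounds neighbor count rather than
26, keeping it an unbiased local variance proxy; interior voxels use the
full 1/26 (or 1/6, 1/18 for the reduced systems).

## Noise model and σ estimation

Rayleigh sampling uses the inverse-CDF transform n = σ√(−2 ln U) with a
PCG64 generator, so fields are reproducible bit-for-bit from (dims, σ,
seed). σ is treated as known by the estimator; when it is not, the
Rayleigh maximum-likelihood estimate σ̂ = √(Σ a²/(2N)) over a
background (signal-free) mask is provided, plus a corner-patch heuristic
that harvests the air corners of a head acquisition (patches grow
automatically until at least 100 background voxels are collected).

## Synthetic phantom

The simulation phantom is a 128×128×27 stack (default spacing
1.8×1.8×5.0 mm) of nested additive ellipsoids: a bright outer shell
(90 intensity units) hollowed to uniform brain matter (40), two darker
ventricle-like lobes (28), a brighter deep structure (65), a small
lesion-like inclusion (58), an optional low-amplitude (±2) sinusoidal
texture in one brain octant, and six 1–3-voxel high-contrast (+40)
details placed in eroded flat surroundings to probe detail preservation.
Foreground intensities span [20, 100] so the studied noise range
σ ∈ [0.5, 8] sweeps the acquisition from nearly clean to heavily
degraded. The head ellipsoid deliberately extends through the first and
last slices, as a real axial slab truncates the anatomy; face voxels
therefore carry signal while having clipped neighborhoods, which is what
makes boundary-effect analyses meaningful. The generation is
deterministic given the spec seed, and the generated stack carries its
brain mask, flat-region mask and detail locations as metadata.

What the phantom does *not* emulate: MR contrast physics (sequence
dependence, T1/T2 weighting), k-space acquisition and its artifacts,
partial-volume effects, spatially varying or multi-coil (non-central χ)
noise, and anatomical realism beyond "piecewise-constant nested
structures". Passing tests on it demonstrate the estimator's statistical
behavior under the stated noise model, not clinical image quality.

## Evaluation metrics

Masked MSE and masked single-scale SSIM (per-slice 2D Gaussian window of
11 voxels, σ_w = 1.5, K1 = 0.01, K2 = 0.03; the per-slice SSIM maps are
averaged over the masked voxels, with a central-slice-only option) are
computed in the brain region — the interior of the phantom's outer
ellipsoid. The SSIM dynamic range defaults to the peak of the noise-free
reference. SNR is reported as 10·log10(mean(b²)/ (2σ²)), the masked mean
signal power over the Rayleigh second moment E[n²] = 2σ²; this definition
is pinned and printed so values are comparable across runs of this
package (SNR-in-dB conventions vary across the literature).

## Known limitations

- The Rayleigh likelihood is a low-SNR approximation: in nearly noise-free
  images its mode at a − σ biases flat regions by σ(√(π/2) − 1) ≈ 0.25 σ,
  which sets the MSE floor visible in the phantom experiment. High-SNR
  data would need the full Rice likelihood.
- ICM is a local optimizer; it finds a coordinate-wise minimum of a
  nonconvex joint problem (the θ updates change the objective between
  iterations). In practice the alternation settles within a few sweeps.
- Residual error concentrates at volume faces, where clipped
  neighborhoods weaken the prior — quantified by the boundary tests.
- σ is assumed spatially constant; parallel-imaging noise maps are out of
  scope.

## Problem sizes used in the test suite

Unit and property tests run on volumes between 3³ and 8³ with brute-force
triple-loop oracles; the end-to-end suite uses a 48×48×11 and a 64×64×15
phantom; the acceptance script runs the full 128×128×27 reference
experiment. These sizes were chosen so the entire suite re-runs in a
couple of minutes on one CPU while the full-size experiment remains part
of the reproducible record.
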