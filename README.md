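# mridenoise

Unsupervised denoising of 3D magnitude MR image stacks by maximum a
posteriori (MAP) estimation under a **local Gaussian Markov random field
(LGMRF)** prior.

Magnitude MR data are corrupted by Rician noise, which in the low-SNR
regime reduces to an additive Rayleigh model `a = b + n`. Classical
smoothing filters trade noise reduction against edge blur through
user-tuned parameters; this package instead lets the prior adapt itself:
the MRF hyperparameters that control smoothing strength are re-estimated
per voxel from the evolving image, so flat regions are regularized hard
while edges and small details are left nearly untouched — with no
parameter for the user to set beyond the noise scale σ (which can itself
be estimated from the image background).

## The estimator

The noise-free stack `b` is estimated from the acquired stack `a` by
minimizing the negative log-posterior

```
b̂ = argmin_{0<b<a} Σ_k [ −log((a_k−b_k)/σ²) + (a_k−b_k)²/(2σ²) ]
              + Σ_k Σ_{q∈N_k} (b_k−b_q)² / (2 θ²_{k,q} d²_{k,q})
```

where `N_k` is the 26-voxel 3D neighborhood of voxel k, `d_{k,q}` the
physical (mm) distance between voxel centers — so anisotropic voxel
spacing automatically down-weights neighbors across slices — and
`θ²_{k,q}` the pairwise smoothing hyperparameters. These are unknown and
re-estimated at every outer iteration from the current estimate:

```
θ̂²_k = (1/|N_k|) Σ_{q∈N_k} (b̂_k − b̂_q)²,     θ̂²_{k,q} = (θ̂²_k + θ̂²_q)/2
```

Small θ² (flat neighborhood) ⇒ strong quadratic coupling ⇒ heavy
smoothing; large θ² (an edge) ⇒ the penalty nearly vanishes. Minimization
is exact per-voxel coordinate descent (iterated conditional modes): each
one-dimensional subproblem is strictly convex and solved in closed form,
and the volume is swept in eight vectorized parity classes. The loop stops
when the mean per-voxel correction falls below a threshold (default 1e-3
relative); in practice a handful of outer iterations suffice.

## Worked example

```sh
python examples/denoise_phantom.py
```

simulates a 64×64×15 head-like phantom with Rayleigh noise at σ = 4 and
denoises it:

```
converged: True after 6 outer iterations
mean-correction trace: ['0.0000', '0.0386', '0.0123', '0.0044', '0.0018', '0.0010']
MSE  (brain region): noisy  32.22 -> denoised   3.94
SSIM (brain region): noisy 0.8582 -> denoised 0.9786
```

The masked mean-squared error drops roughly eightfold and the structural
similarity index climbs toward 1, i.e. noise is removed while structure is
preserved. `examples/adaptive_smoothing.py` shows the mechanism — after
convergence θ² is orders of magnitude larger at a step edge than inside a
flat region, so the edge survives — and `examples/noise_model.py`
exercises the Rice/Rayleigh model and the blind σ estimator.

The same pipeline is available as a command-line tool:

```sh
mridenoise simulate --dims 128 128 27 --sigma 4 --seed 1 -o sim/
mridenoise denoise  -i sim/noisy.nii.gz --sigma 4 -o denoised.nii.gz
mridenoise evaluate --truth sim/truth.nii.gz --test denoised.nii.gz \
                    --mask sim/mask.nii.gz -o report.json
```

`denoise` accepts NIfTI files or a DICOM series directory, and `--sigma`
may be replaced by `--estimate-sigma` (corner-patch background heuristic)
or `--background-mask mask.nii`. Every run writes a JSON provenance
record and per-iteration diagnostics.

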