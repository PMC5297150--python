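"""End-to-end phantom experiment: simulate, denoise, evaluate.

Generates a 64x64x15 head-like phantom, corrupts it with additive
Rayleigh noise (sigma = 4, the mid-range of the studied [0.5, 8] sweep),
runs the unsupervised MAP denoiser, and prints the masked quality indexes
before and after filtering. Lower MSE and higher SSIM after filtering mean
the method removed noise while preserving structure.
"""

import mridenoise as md

truth = md.generate_head_phantom(md.PhantomSpec(dims=(64, 64, 15)))
noisy = md.simulate_acquisition(truth, sigma=4.0, seed=7)
mask = md.brain_mask(truth)

result = md.run_map_denoise(noisy, sigma=4.0)

print(f"converged: {result.converged} after {result.iterations_run} outer iterations")
print(f"mean-correction trace: {[f'{c:.4f}' for c in result.mean_correction_trace]}")
print(f"MSE  (brain region): noisy {md.mse(noisy, truth, mask):6.2f}"
      f" -> denoised {md.mse(result.b_hat, truth, mask):6.2f}")
print(f"SSIM (brain region): noisy {md.ssim(noisy, truth, mask):6.4f}"
      f" -> denoised {md.ssim(result.b_hat, truth, mask):6.4f}")
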