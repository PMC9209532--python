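# Methods

## Problem and scope

`fmrisr` implements and evaluates a subject-specific super-resolution
scheme for block-design BOLD fMRI. A 2D super-resolution GAN is trained,
per subject, on that subject's own static T2\*-weighted slice pairs
(high-resolution 128×128 vs low-resolution 64×64), then applied frame by
frame to the subject's low-resolution functional series. The question the
evaluation pipeline answers is not "do the frames look sharper" but "does
the *functional resolution* improve": can two spatially adjacent,
functionally distinct responses (thumb vs little-finger tapping in the
motor cortex) be told apart more cleanly on the super-resolved maps?

Everything runs end to end on synthetic phantoms with known ground truth;
no scanner data is required anywhere.

## Activation mapping

For a task *x*, the reference timecourse R_x is the on/off boxcar of the
task's blocks sampled at the TR and convolved with a canonical
double-gamma HRF (response gamma with shape 6, undershoot with shape 16,
peak:undershoot 6:1, 32 s support, unit-sum kernel; peak ≈ 5 s). The
activation score of a pixel with timecourse R_y is

    CC = (R_x · R_y) / (|R_x| |R_y|),

computed after mean-centering both vectors by default (making it the
Pearson correlation; centering is nearly a no-op after detrending, and an
uncentered cosine-similarity route is kept behind a flag). Zero-variance
timecourses get CC = 0 and are flagged rather than propagating NaNs.

The activation-related region is the inclusive superlevel set at the
range threshold

    threshold = maxCC − (maxCC − minCC) / 4,

with max/min taken over the supplied analysis mask (the phantom supplies
a dilated "motor area" mask around the true regions; a whole-grid mask is
the fallback). The region always contains the in-mask argmax, and a
constant map degenerates to the whole mask. Because super-resolved maps
have pixels 4× smaller over the same area, pixel counts are divided by
the squared scale factor before any cross-arm comparison.

## Preprocessing

Order: discard the first 60 frames (magnetization equilibration) →
per-voxel least-squares linear detrend → zero-phase Butterworth low-pass
(order 4, default cutoff 0.1 Hz, `sosfiltfilt`) → in-plane Gaussian
smoothing (σ = 1.5 pixels of the grid being smoothed, reflective
boundary, 4σ truncation). In the super-resolution arm, frames are
upscaled immediately after the discard step and the temporal/spatial
filters run on the high-resolution grid; the analysis mask is
nearest-neighbour upsampled. Detrending is an orthogonal projection
(idempotent); the low-pass preserves DC exactly; σ = 0 smoothing is the
identity.

## The modified SRGAN

The generator takes a Lanczos-3 pre-upscaled frame (so input and output
share the target matrix size; no learned upsampling block) and refines it
residually: one 3×3 conv + PReLU, then n residual blocks
(conv–PReLU–conv with skip), a mid conv with a skip from the first
feature map, and a final 3×3 conv back to one channel added to the input.
The final conv is **zero-initialized**, so an untrained generator is
exactly the Lanczos interpolant — training can only move away from a
sensible baseline, and the "does training destroy the interpolation
baseline" check is meaningful. There is no batch normalization anywhere.
The discriminator has 10 convolutional layers (3×3, stride 2 on every
second layer, channel width doubling and capped at 8× base, LeakyReLU
0.2) and a dense head producing one logit.

Losses: pixel-MSE content loss plus 10⁻³ × non-saturating adversarial
loss for the generator; standard binary cross-entropy for the
discriminator. Optimizer: Adam (β₁ = 0.9, β₂ = 0.999, lr 10⁻⁴), batch 2,
patch 64, one optimizer step per iteration on freshly sampled aligned
random crops of the (upscaled-LR, HR) slice pairs. Intensities are
normalised to [0, 1] by robust (1st/99th percentile) scaling recorded in
the checkpoint and inverted at inference; training structural data is
first affinely matched to the fMRI intensity range the generator will see
at test time. Training is fully deterministic given the seed. A
non-finite loss aborts with a diagnostic rather than silently producing a
broken model.

The networks are implemented in NumPy with explicit im2col convolutions
and hand-written backpropagation, verified against central finite
differences in the test suite. The reference recipe's 100 000 iterations
remain the config default; tests and the desk-scale acceptance runs use
200 iterations with a 4-resblock, 16-feature generator and an 8-base
discriminator — sizes chosen so a full training run takes about a minute
on one CPU core while still exercising every code path.

The perceptual (pretrained-VGG) loss of the original SRGAN is
deliberately absent: it would import external trained weights, and the
scheme under study specifies pixel content loss plus the adversarial
term only.

## The phantom

`PhantomSpec` describes a 128×128 high-resolution single-slice scene
(analysis is slice-wise; the structural stack for GAN training carries 30
slices) with two elliptical active regions whose centres are placed
symmetrically so the rasterised overlap matches a requested
`overlap_fraction` (solved through the exact two-ellipse lens-area
formula). Each active voxel modulates a tissue-like baseline (sum of
random Gaussian blobs inside an elliptical head, mean 500) by
`1 + 0.03 × (HRF-convolved boxcar)`; voxels in the intersection carry
both task responses additively. A linear drift (0.02 intensity units per
volume) and two noise terms are added on the high-resolution grid, and
every frame is block-averaged 2×2 to produce the 64×64 series the
pipeline sees — so the HR→LR operator is exactly known, preserves frame
means, and the noise-free LR series is exactly the block mean of the
noise-free HR series.

Noise model. Two components:

* i.i.d. Gaussian noise (`noise_sd`, default 5) — thermal noise;
* a structured component (`structured_noise_sd`, default 10): a low-rank
  sum of spatially smooth random fields (Gaussian-filtered, scale 4 HR
  pixels) times temporally band-limited random timecourses (< 0.08 Hz),
  standing in for physiological fluctuations.

The structured term is essential, not decorative. Purely white noise is
almost entirely removed by the σ = 1.5 smoothing and the 0.1 Hz low-pass,
leaving in-mask CC maps with maxima ≥ 0.9 no matter how large the white
sd is; the range threshold then always selects small disjoint "purest
pixel" islands for the two tasks and the between-task Dice is identically
zero in both arms — a regime real fMRI never shows. One can also show in
closed form that when pure-task pixels set both extremes of the CC range,
a both-task pixel at CC ≈ √((1+ρ)/2)·maxCC (ρ ≤ 0 the boxcar
correlation) can never clear the max − range/4 threshold. Slow, smooth
noise survives both filters, caps the attainable CC around 0.6–0.8, and
reproduces the fuzzy, partially overlapping activation maps that motivate
the study. Default amplitudes put single-voxel (unsmoothed) CCs near
0.4–0.6 and post-smoothing in-mask maxima near 0.6–0.8.

Task design. 20 s task blocks with 40 s rests, alternating thumb /
little finger, after a 30 s lead-in rest covering the discarded frames.
The sparse duty cycle keeps the two references only weakly
anti-correlated (ρ ≈ −0.2); with dense alternation the anti-correlation
suppresses both-task pixels so strongly that no geometry produces
overlapping regions.

Named configurations. Two factory functions freeze the two experiments:

* `separability_spec()` — the default conditions: small regions
  (semi-axes 5 × 3.5 HR px) with overlap fraction 0.45. At low
  resolution these regions are unresolvable (their cores blur together
  under the 1.5-LR-pixel smoothing), at high resolution they partially
  separate — the premise of the study, stated as a construction.
* `recovery_spec()` — well-separated larger regions (semi-axes 12 × 8,
  centres 44 HR px apart, reduced structured noise 6) used to check
  geometric fidelity: the native arm's extracted regions should coincide
  with the ground-truth LR masks.

What the phantom does **not** model: T2\* decay or any MR physics,
k-space sampling, motion, spatially varying HRFs, temporally
autocorrelated thermal noise. Consequently, passing tests demonstrate
the *pipeline logic* (mapping, thresholding, statistics, training
mechanics and the resolution-vs-overlap geometry), not in-vivo efficacy.

## Evaluation

Functional resolution is operationalised as the Dice coefficient
2|A∩B|/(|A|+|B|) between the two tasks' regions — *lower* is better.
Dice is computed on each arm's native grid (it is scale-free, so no
resampling). Arms are compared per subject with the two-sided Wilcoxon
signed-rank test (zeros dropped; exact null for n ≤ 25 without ties,
normal approximation with tie correction otherwise; the implementation
delegates to `scipy.stats.wilcoxon` and is checked in the tests against a
full 2ⁿ sign-flip enumeration written independently). Summaries are
median (IQR) with linear-interpolation (type 7) quantiles. Two-sided
p-values throughout; 0.05 is echoed in reports but gates nothing.

The cohort-level benchmark substitutes the phantom's true noisy
high-resolution series for the GAN output ("perfect super-resolver").
This isolates the resolution effect from GAN fidelity: it bounds what any
super-resolver could achieve under the scheme, and it is the level at
which the directional claim (high-resolution arm ⇒ lower between-task
Dice) is asserted across 10 simulated subjects. The GAN-based arm runs
through exactly the same code path (`run_arm(..., generator=model)`).

## Numerical choices and degenerate inputs

* Lanczos-3 resampling: separable windowed-sinc matrix with
  centre-aligned sampling, edge-clamped taps, rows renormalised to unit
  sum; scale 1 is the exact identity, constants map to constants. The
  kernel is cross-checked against Pillow's LANCZOS resampler in a test.
* PSNR: 10·log₁₀(range²/MSE) with the reference's range by default;
  identical images report a capped sentinel of 300 dB.
* CC values are clipped to [−1, 1] to absorb float round-off; the
  threshold comparison is inclusive ("equal to or above").
* Ties in Wilcoxon ranks switch the implementation to the tie-corrected
  normal approximation; all-zero difference vectors raise.
* Empty masks, constant structural images, mismatched geometries, designs
  longer than the series, and discards that would empty the series all
  raise `ValueError` with specific messages before any heavy compute.

## Known limitations

* The GAN is deliberately tiny at test scale; nothing here demonstrates
  perceptual quality at the reference recipe's 100k iterations.
* Training-batch loss is recorded per iteration; its trend is assessed on
  window averages because per-crop variance dominates adjacent samples.
* The phantom's structured noise is stationary and task-independent;
  real physiological noise is neither.
* Bit-level training reproducibility is guaranteed on a fixed BLAS/thread
  configuration (one device), not across platforms.
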