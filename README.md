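# fmrisr

Subject-specific super-resolution of fMRI time series, with an
evaluation pipeline for *functional resolution* — the ability to tell
two spatially adjacent, functionally different brain responses apart.

## The problem

Block-design BOLD fMRI is acquired at low spatial resolution (here
64×64 in-plane at TR = 0.5 s), while static T2\*-weighted structural
images of the same anatomy — with very similar contrast, since both
ride on T2\* relaxation — can be acquired at twice the matrix size
(128×128). `fmrisr` trains a small super-resolution GAN **per subject**
on that subject's own paired high/low-resolution structural slices and
applies the trained generator frame by frame to the functional series.
Training per subject avoids importing other people's anatomy into the
reconstruction.

Whether the scheme helps is judged functionally. For each task *x*
(thumb tapping, little-finger tapping) the pipeline computes a
cross-correlation map

    CC = (R_x · R_y) / (|R_x| |R_y|)

between each pixel's timecourse R_y and the HRF-convolved task
reference R_x, thresholds it at

    threshold = maxCC − (maxCC − minCC) / 4

(inclusive superlevel set within an analysis mask), and measures the
Dice overlap between the two tasks' regions. Since the thumb and
little-finger motor areas are genuinely distinct, **lower between-task
Dice means better functional resolution**. Arms are compared per
subject with the two-sided Wilcoxon signed-rank test; pixel counts from
the super-resolved maps are divided by 4 to be comparable across grids.

Everything runs on synthetic phantoms with known ground truth — paired
structural stacks, a 900-volume functional series with two partially
overlapping elliptical active regions, realistic structured
(physiological-like) plus white noise — so every claim is testable
without any scanner data. The GAN itself is a compact NumPy
implementation (im2col convolutions with hand-written backpropagation,
Adam), with no batch normalization, a 10-conv-layer discriminator, and
a generator that refines Lanczos-3 pre-upscaled input residually.

See `docs/methods.md` for the model, the phantom's noise design, and
all numerical choices.

## Worked example

```python
from fmrisr.activation import run_arm
from fmrisr.evaluation import dice
from fmrisr.phantom import (default_task_design, hr_series,
                            make_functional_series, separability_spec)
from fmrisr.preprocess import PreprocessConfig

spec = separability_spec(seed=3)
design = default_task_design(spec.n_volumes, spec.tr)
series, truth = make_functional_series(spec, design)   # 64x64, 900 frames

pre = PreprocessConfig()                               # discard 60, detrend,
raw = run_arm(series, design, truth.analysis_mask_lr, pre)  # 0.1 Hz, sigma 1.5
d_raw = dice(raw["thumb"]["region"].mask,
             raw["little_finger"]["region"].mask).dice

hires = run_arm(hr_series(truth, spec), design, truth.analysis_mask_hr, pre)
d_hr = dice(hires["thumb"]["region"].mask,
            hires["little_finger"]["region"].mask).dice

print(f"between-task Dice: raw {d_raw:.3f} vs high-res {d_hr:.3f}")
```

Output:

```
between-task Dice: raw 0.370 vs high-res 0.128
```

At native resolution the two tapping tasks' regions overlap heavily
(Dice 0.370) because the adjacent patches blur together under the
coarse grid and the 1.5-pixel smoothing; with access to the true
high-resolution series the same pipeline separates them much more
cleanly (Dice 0.128). Across a 10-subject phantom cohort this direction
holds for every subject (Wilcoxon p ≈ 0.008).

Training and applying the GAN itself:

```python
from fmrisr.phantom import make_structural_pair
from fmrisr.sr import GanConfig, match_intensity, train_subject_model

hi, lo = make_structural_pair(spec)
cfg = GanConfig(n_resblocks=4, n_features=16, disc_base_channels=8,
                iterations=200, seed=3)          # desk-scale; default 100k
model = train_subject_model(match_intensity(hi, series),
                            match_intensity(lo, series), cfg)
stss = run_arm(series, design, truth.analysis_mask_lr, pre, generator=model)
```

## Command line

The same stages are exposed as a CLI:

```sh
fmrisr simulate   --config phantom.yaml --out subj01 --seed 1
fmrisr preprocess --in subj01/func_lr.nii.gz --config pre.yaml --out pp.nii.gz
fmrisr train      --hi subj01/t2s_hr.nii.gz --lo subj01/t2s_lr.nii.gz \
                  --ref subj01/func_lr.nii.gz --out model.npz --seed 1
fmrisr superres   --in subj01/func_lr.nii.gz --model model.npz --out sr.nii.gz
fmrisr analyze    --in subj01/func_lr.nii.gz --design subj01/design.yaml \
                  --mask subj01/analysis_mask_lr.nii.gz --out analysis/
fmrisr run-all    --config pipeline.yaml --out study/ --seed 1
```

Volumes are NIfTI-1; task designs and configs are YAML. Exit codes:
0 success, 2 configuration error, 3 stage failure.

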