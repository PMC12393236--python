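# svfatlas

Spatiotemporal brain atlas construction and segmentation tools built on
stationary-velocity-field (SVF) diffeomorphisms.

The developing fetal brain changes shape and size so quickly that a single 3-D
template cannot represent it: researchers instead build *spatiotemporal (4-D)
atlases* — families of average anatomical templates indexed by continuous
gestational age (GA, weeks) — and use them for spatial normalization,
automatic segmentation and groupwise analysis. `svfatlas` implements such an
atlas-construction framework end to end, together with multi-atlas
segmentation via probabilistic STAPLE label fusion, the evaluation metrics
used to assess atlas and segmentation quality, and the computational blocks
of a lightweight 3-D segmentation network. Everything runs on synthetic
age-parameterized brain phantoms with known ground truth, so every stage can
be validated quantitatively without any scan data.

Intended users: researchers in medical image analysis who want a transparent,
NumPy/SciPy-based reference implementation of kernel-regressed diffeomorphic
template building and its downstream segmentation tooling.

## The model

Each subject image `I_i` (age `t_i`) is related to the atlas space at age `t`
through a total diffeomorphism

```
T_{k,i}(t) = phibar_k(t) ∘ psi_{k-1,i}(t) ∘ phi_{k,i}
```

maintained entirely in the Lie algebra: every factor is the exponential
`exp(v)` of a stationary velocity field, computed by scaling and squaring;
compositions use the Baker–Campbell–Hausdorff (BCH) expansion
`log(exp(v) ∘ exp(w)) ≈ v + w + ½[v, w]`; inverses are `exp(-v)`.

Per iteration `k`, at every age `t`:

1. **Template.** `Ibar_k(t) = Σ_i w_i(t) · I_i ∘ T_{k,i}(t)^{-1}`, where the
   `w_i(t)` are normalized Gaussian kernel-regression weights in age,
   truncated to zero beyond one week and renormalized; the bandwidth adapts
   so that every timepoint has a minimum effective sample size.
2. **Registration.** Each subject is registered to the template at its own
   age, giving `phi_{k,i} = exp(v_{k,i})` as the minimizer of an SSD or
   local-normalized-cross-correlation energy with diffusion regularization.
3. **Longitudinal transport.** The coordinate map
   `psi_{k,i}(t) = [Π_s phibar_s(t)] ∘ [Π_s phibar_s(t_i)]^{-1}` relates the
   observed age to any other age, so each subject's map can be *age-adjusted*:
   `phi_{k,i}(t) = psi_{k-1,i}(t) ∘ phi_{k,i}`.
4. **Re-centering.** The residual atlas deformation is the weighted
   Log-Euclidean mean of the inverse age-adjusted maps,
   `phibar_k(t) = exp(-Σ_i w_i(t) log phi_{k,i}(t))`, which removes the drift
   of the atlas space toward the sampled cohort. The drift norm
   `‖Σ_i w_i(t) log phi_{k,i}(t)‖` over the template foreground is reported
   per iteration and decays as the atlas converges to the cohort barycenter.

Downstream, multi-atlas segmentation registers the age-matched templates
(within one week of the query's GA) to a query image, propagates their labels
and fuses them with multi-category STAPLE — an EM algorithm that jointly
estimates the consensus segmentation, per-atlas confusion matrices and class
prevalences. Quality metrics include the Dice coefficient, (percentile)
Hausdorff distance, and a median edge-sharpness score for template crispness.

## Worked example

```python
import numpy as np
from svfatlas import (RegistrationConfig, Subject, build_atlas, make_cohort,
                      normalize_global)
from svfatlas.phantom import scaled_params

params = scaled_params((32, 32, 32))            # phantom geometry at 32^3
ages = np.array([25.0] * 3 + [28.0] * 3 + [31.0] * 3)
subjects, labels = make_cohort(9, params=params, seed=5, ages=ages)
subjects = [Subject(s.id, normalize_global(s.image), s.age) for s in subjects]

cfg = RegistrationConfig(similarity="ssd", levels=2, iters_per_level=60,
                         smooth_update_sigma=2.0, reg_weight=0.01,
                         step_size=0.3)
result = build_atlas(subjects, target_ages=[25.0, 28.0, 31.0],
                     n_iter=4, reg_config=cfg)
for it in result.diagnostics["iterations"]:
    print(it["iteration"], {k: round(v, 4) for k, v in it["drift"].items()})
```

prints the per-age drift norm (voxels) per iteration:

```
1 {'25': 0.1861, '28': 0.1607, '31': 0.078}
2 {'25': 0.0352, '28': 0.0193, '31': 0.013}
3 {'25': 0.0191, '28': 0.0138, '31': 0.012}
4 {'25': 0.0172, '28': 0.0138, '31': 0.0124}
```

The iteration-1 values reflect the bias of registering against the blurry
unregistered average; by iteration 4 the drift has fallen roughly tenfold —
the Log-Euclidean correction has re-centered the atlas. `result.timepoints`
holds the template image and residual deformation per age,
`result.transforms` the per-subject maps.

The same pipeline is available from the shell:

```bash
svfatlas simulate cohort --out cohort/ --n 9 --size 32 --seed 5
svfatlas build-atlas --cohort cohort/cohort.csv --ages 25:31:3 --iters 4 --out atlas/
svfatlas segment --query query.nii.gz --age 28 --atlas-dir atlas/ --out seg.nii.gz
svfatlas evaluate --pred seg.nii.gz --truth truth.nii.gz --out report.csv
```

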