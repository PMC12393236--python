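# Methods

This note documents the models and numerical choices behind `svfatlas`: what
each component computes, the defaults and why, what the synthetic phantoms do
and do not emulate, and known limitations.

## Deformation model

All deformations are diffeomorphisms parameterized by stationary velocity
fields (SVFs) on the image grid, in voxel units. A dense displacement
representation was chosen over spline parameterizations for transparency:
smoothness is enforced by the registration regularizer and by Gaussian
smoothing of updates rather than by a basis.

**Exponential.** `exp_svf` uses scaling and squaring: the field is divided by
`2^N` with the smallest `N` such that the scaled field's maximum displacement
is at most 0.5 voxel (capped at 10 squarings), then self-composed `N` times.
The base step is the second-order Taylor expansion
`exp(u) ≈ Id + u + ½ Ju·u`; with the first-order step the endpoint error on
smooth 2-voxel fields is ~7·10⁻³ voxels (median) against a 1000-step Euler
flow integration, with the second-order step it is ~4·10⁻⁴ — below the
linear-interpolation noise of the squarings. Vector fields are sampled with
edge replication outside the domain so a constant field integrates exactly to
a translation.

**Inverse and composition.** The inverse is exact in the algebra
(`exp(v)⁻¹ ≈ exp(−v)`); compositions use the BCH expansion, default order 2
(`v + w + ½[v,w]`, central-difference Jacobians, one-sided at boundaries).
Order 1 is available; order 2 roughly halves the median composition error on
smooth unit-magnitude fields and is exact for commuting fields at either
order. No logarithm of an arbitrary dense map is ever computed: every
deformation entering a mean carries the SVF that generated it.

**Image resampling.** Pullback interpolation is linear for intensities
(cubic available), nearest for labels, with a continuous constant-fill
boundary (`grid-constant`): the plain constant mode of `scipy.ndimage` jumps
discontinuously to the fill value at the domain edge, which makes
similarity energies non-differentiable exactly where registration needs
them.

## Registration

`register` minimizes `Sim(moving ∘ exp(v), fixed) + λ‖∇v‖²` by
multiresolution gradient descent (default 3 levels). The similarity is SSD
or squared local normalized cross-correlation (LNCC, window half-width 2).
The LNCC gradient is the exact window-summed derivative accumulated with box
filters — every voxel collects the contribution of all windows containing
it — and was verified against finite differences. A variance floor of
`(10⁻³ · dynamic range)²` per voxel enters the LNCC denominator: windows with
less local structure than that are treated as uninformative, which keeps the
energy numerically stable over flat backgrounds.

Descent details: the force is approximated demons-style (`dW/dv ≈ ∇W`),
smoothed with a Gaussian (default σ = 1.5 voxels), normalized so one update
moves at most `step_size` voxels (default 0.4), and accepted only if the
energy decreases — the step halves on increase (up to 10 times), so the
recorded energy trace is non-increasing within each level. Velocities are
upsampled (and rescaled to the finer voxel units) between levels. Identical
inputs yield an exactly zero field from zero initialization because the
force vanishes.

Defaults recover a known smooth warp of 3-voxel magnitude on a 64³ phantom
with a grid-median endpoint error of 0.16–0.19 voxels (0.38–0.54 within the
brain) in ~40 s on one CPU.

## Kernel regression on age

Weights at target age `t` are normalized Gaussians in `t_i − t`, truncated to
exactly zero beyond one week and renormalized (truncate-then-normalize, so
realized weights always sum to 1). The bandwidth `σ_t` is the smallest value
in [0.25, 1.0] weeks whose effective sample size `(Σg)²/Σg²` over the window
reaches 5, found by bisection (the ESS is monotone in σ); the caps always
apply. This adaptation rule guarantees a minimum effective cohort per
timepoint in sparsely sampled age ranges.

## Atlas construction

The iterative procedure is described in the README. Implementation choices:

- The first-iteration template is the weighted intensity mean under identity
  transforms.
- `register` returns `v` with `moving ∘ exp(v) ≈ fixed`, i.e. `exp(v)` is the
  atlas-to-subject pullback map; the subject-to-atlas log is `−v`.
- Warm start: iteration `k` initializes each registration from the inverse
  log of the previous *total* transform at the subject's own age, so the
  Log-Euclidean correction applied at iteration `k−1` is part of the starting
  point and the refinement only has to track the residual.
- `T⁻¹` is always realized as `exp` of the negated BCH-composed SVF, never by
  numeric inversion of a dense map.
- Default iteration count 4; templates can be rendered at any continuous age
  (weights are recomputed per age).
- Subjects contributing multiple scans are treated as independent images.

**Drift diagnostic.** `‖Σ_i w_i(t) log φ_{k,i}(t)‖` is reported as the mean
voxelwise magnitude over the template foreground (intensity > 0.1 after
normalization). The restriction matters: outside the anatomy the velocity is
unconstrained by any image term, so the whole-grid norm saturates at a
floor of frozen extrapolation values and hides the convergence of the
anatomy itself.

**Similarity choice for cohort experiments.** The phantom cohorts share
tissue intensity distributions by construction, so the atlas experiments use
SSD, which is smoother and more reproducible at sub-voxel scales; LNCC
remains the library default for data with intensity differences across
subjects or scanners.

**Intensity normalization.** `normalize_global` maps the robust 1st–99th
percentile range to [0, 1] (affine, so any rescaled input normalizes
identically); with a reference image it matches median and IQR instead.

## Multi-atlas segmentation and STAPLE

Atlases within one week of the query's age are registered to the query,
their labels propagated by nearest-neighbor resampling, and fused with
multi-category STAPLE (a single selected atlas is propagated directly). The
EM treats the true voxel label as hidden: E-step posterior
`∝ prior(l) Π_j θ_j(l, d_j)`, M-step re-estimates each rater's L×L
row-stochastic confusion matrix, and — importantly — the class prevalences
are re-estimated from the posterior as well. A fixed prior taken from pooled
observed frequencies systematically overestimates rare-class prevalence
whenever raters are imperfect and provably biases the confusion estimates
(we reproduce the effect on iid draws); joint EM removes it. Initialization:
0.9 diagonals; ties at the argmax go to the smallest label id; default
tolerance `max|Δθ| < 10⁻⁵`, up to 200 iterations (the 64³ recovery problem
needs ~150). The observed-data log-likelihood is non-decreasing at every
iteration and is asserted in the tests.

Confusion-matrix recovery to ±0.05 is demonstrated for binary (brain-mask)
raters; with a 4-label phantom the rare ventricle class (~1% of voxels) is
not identifiable to that tolerance at realistic error rates — a property of
the estimation problem, not of the implementation.

## Metrics

- **Dice**: `2|A∩B|/(|A|+|B|)`; two empty masks are defined as 1 (logged).
- **Hausdorff**: distances between the voxel point sets of a label via
  KD-trees, symmetrized by max, exact against an all-pairs oracle;
  percentile variant available; voxel units by default, mm on request.
  Default percentile 100.
- **Edge sharpness**: gradient magnitude by central differences scaled by
  spacing; edges are voxels at or above the 90th percentile of nonzero
  gradient magnitudes (configurable, or a custom detector); the score is the
  median gradient magnitude over edge voxels. An ideal unit step scores
  exactly 0.5 under central differences, and any Gaussian blur strictly
  lowers the score.

## Segmentation building blocks

Pure-NumPy reference implementations with hand-derived gradients:

- **Depthwise convolution**: per-channel correlation with zero padding.
- **Parameter accounting**: separable `C_in·k² + C_in·C_out` versus standard
  `C_in·C_out·k²`, exactly as conventionally quoted with a squared spatial
  factor; a `cubic=True` flag switches to `k³` for fully 3-D kernels.
- **Residual self-similarity mixing**: `F′ = LayerNorm(F) + W₁F + b₁`;
  `S = softmax(F Fᵀ/√d)` rowwise; output `F′ + S·F′`. Norm is instantiated as
  layer normalization over features; the mixing operator is realized as the
  attention-weighted product `S·F′`.
- **Decoder softmax**, **trilinear skip addition** (2× per axis with edge
  clamping and an exact adjoint for backpropagation), and the **hybrid loss**
  `L_CE + ε·L_Dice` (ε default 1; soft Dice smoothed so classes absent from
  both prediction and truth score 1, making a perfect one-hot prediction
  score exactly 0).

A two-level toy network (pointwise → depthwise → pool → mixing block →
upsample + skip → softmax; ~1.5k parameters) assembled from these blocks is
trained with Adam (lr 2·10⁻³) on a single 16³ phantom; the hybrid loss falls
below 5% of its initial value within 500 steps. All gradients are verified
against central finite differences in the test suite.

## Synthetic phantoms

Phantoms are ellipsoids (semi-axes `r`, `0.9r`, `0.8r`) whose radius grows
linearly with age (0.7 voxels/week at 64³ scale from a 16-voxel base at 21
weeks), with an inner ventricle ellipsoid (30% of radius), a cortical ribbon
(outer 18%), and sinusoidal surface folding whose amplitude grows linearly
from zero at 21 weeks (gyrification onset). Tissue classes take distinct
mean intensities with additive Gaussian noise (sd 0.02). Cohort members get
a random smooth anatomical jitter — magnitude 30% of the base radius,
correlation length a fifth of the grid, modeling smooth brain-scale
inter-subject shape variability — plus a 3% multiplicative intensity
perturbation. Random test SVFs are Gaussian-filtered white noise tapered to
zero at the grid boundary (deformations are compactly supported in the field
of view, and flows must not leave the domain). All generators are pure
functions of (parameters, seed).

What the phantoms do **not** emulate: MRI physics (bias fields, partial
voluming beyond interpolation, motion artifacts), real cortical folding
topology, tissue-contrast changes with maturation, or multi-scanner
intensity variation. Passing tests therefore demonstrate the correctness and
convergence behavior of the algorithms under known ground truth, not
clinical-grade accuracy on fetal MRI.

## Problem sizes

The validation experiments use 32³ grids for the atlas cohort studies
(9 subjects, 3 ages, 4 iterations), 64³ for single-registration recovery and
STAPLE recovery, and 16³ for the network overfit — sizes at which every
experiment has comfortable ground-truth margins while the full suite runs on
a single CPU in minutes.

## Known limitations

- BCH order 2 degrades for fields beyond a few voxels of magnitude; the
  atlas machinery assumes moderate per-iteration deformations.
- The registration is first-order (demons-style gradient); it recovers
  smooth warps well but not sharp or large-rotation deformations, and there
  is no affine/rigid pre-alignment stage (cohorts are generated
  pre-aligned).
- STAPLE confusion recovery is limited by class prevalence (see above).
- Edge sharpness depends on the edge detector; the percentile rule is a
  concrete, configurable choice rather than a canonical definition.
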