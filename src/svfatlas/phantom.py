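"""Synthetic age-parameterized brain phantoms.

Stand-in for a fetal MRI cohort: each phantom is an ellipsoidal "brain" whose
radius grows linearly with gestational age and whose surface is perturbed by
sinusoidal folding whose amplitude also grows with age (gyrification onset),
with an inner "ventricle" ellipsoid and a cortical ribbon. Tissue classes get
distinct mean intensities plus additive Gaussian noise. Generators also
produce known ground-truth warps between images and simulated raters with
known confusion matrices, so registration, atlas construction and label
fusion can all be validated against a known truth.

All generators are pure functions of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .fields import Image3D, InvalidInputError, LabelMap3D, VelocityField
from .diffeo import exp_svf, warp

__all__ = [
    "PhantomParams",
    "Subject",
    "make_phantom",
    "make_warped_pair",
    "make_cohort",
    "simulate_raters",
    "random_smooth_svf",
    "LABEL_BACKGROUND",
    "LABEL_WM",
    "LABEL_CORTEX",
    "LABEL_VENTRICLE",
]

LABEL_BACKGROUND = 0
LABEL_WM = 1
LABEL_CORTEX = 2
LABEL_VENTRICLE = 3

AGE_MIN = 21.0
AGE_MAX = 37.0


@dataclass
class Subject:
    """One cohort member: a (normalized) image and its gestational age in weeks."""

    id: str
    image: Image3D
    age: float


@dataclass
class PhantomParams:
    """Geometry and intensity model of the phantom cohort.

    Units: radii and amplitudes in voxels, ages in weeks. Folding amplitude is
    ``folding_amp_rate * (age - 21)`` so folding is zero at 21 weeks and grows
    linearly, mimicking gyrification onset. Defaults emulate a 21-37 week
    cohort on a 64^3 grid.
    """

    grid_shape: tuple = (64, 64, 64)
    base_radius: float = 16.0        # outer semi-axis at 21 weeks (voxels)
    growth_rate: float = 0.7         # voxels per week
    folding_amp_rate: float = 0.12   # voxels of folding per week past 21
    folding_freq: float = 6.0        # angular cycles per radian (dimensionless)
    ventricle_frac: float = 0.30     # inner ellipsoid, fraction of outer radius
    cortex_frac: float = 0.82        # cortical ribbon starts at this fraction
    tissue_means: dict = field(default_factory=lambda: {
        LABEL_BACKGROUND: 0.0, LABEL_WM: 0.5, LABEL_CORTEX: 0.8, LABEL_VENTRICLE: 0.95})
    noise_sd: float = 0.02
    age_range: tuple = (AGE_MIN, AGE_MAX)

    def radius(self, age: float) -> float:
        return self.base_radius + self.growth_rate * (age - self.age_range[0])

    def folding_amp(self, age: float) -> float:
        return self.folding_amp_rate * max(0.0, age - self.age_range[0])


def scaled_params(grid_shape: Sequence[int], params: PhantomParams | None = None) -> PhantomParams:
    """Rescale the default geometry to a different grid size (radii and growth
    scale with the linear grid dimension)."""
    base = params or PhantomParams()
    factor = min(grid_shape) / min(base.grid_shape)
    return replace(base, grid_shape=tuple(grid_shape),
                   base_radius=base.base_radius * factor,
                   growth_rate=base.growth_rate * factor,
                   folding_amp_rate=base.folding_amp_rate * factor)


def _effective_radial_coord(params: PhantomParams, age: float) -> np.ndarray:
    """Normalized radial coordinate with the folded surface at 1."""
    shape = params.grid_shape
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    r = params.radius(age)
    semi = np.array([r, 0.9 * r, 0.8 * r])
    coords = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    rel = [(coords[i] - center[i]) / semi[i] for i in range(3)]
    s = np.sqrt(rel[0] ** 2 + rel[1] ** 2 + rel[2] ** 2)
    # folding: angular perturbation of the surface, apodized at the poles
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(s > 0, rel[2] / np.maximum(s, 1e-12), 1.0), -1, 1))
        phi = np.arctan2(rel[1], rel[0])
    amp = params.folding_amp(age) / r
    pert = amp * np.sin(params.folding_freq * theta) * np.cos(params.folding_freq * phi) * np.sin(theta)
    return s / (1.0 + pert)


def make_phantom(age: float, params: PhantomParams | None = None, seed: int = 0,
                 subject_id: str | None = None) -> tuple[Subject, LabelMap3D]:
    """Generate one phantom and its ground-truth label map.

    Returns (Subject, LabelMap3D); seeded runs are bit-reproducible.
    """
    params = params or PhantomParams()
    lo, hi = params.age_range
    if not (lo <= age <= hi):
        raise InvalidInputError(f"age {age} outside configured range [{lo}, {hi}]")
    s_eff = _effective_radial_coord(params, age)
    labels = np.full(params.grid_shape, LABEL_BACKGROUND, dtype=np.int32)
    labels[s_eff < 1.0] = LABEL_WM
    labels[(s_eff >= params.cortex_frac) & (s_eff < 1.0)] = LABEL_CORTEX
    labels[s_eff < params.ventricle_frac] = LABEL_VENTRICLE
    means = np.zeros(max(params.tissue_means) + 1)
    for k, v in params.tissue_means.items():
        means[k] = v
    image = means[labels]
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, params.noise_sd, size=image.shape)
    sid = subject_id or f"phantom_age{age:g}_seed{seed}"
    return (Subject(sid, Image3D(image), float(age)),
            LabelMap3D(labels, key={LABEL_WM: "white_matter", LABEL_CORTEX: "cortex",
                                    LABEL_VENTRICLE: "ventricles"}))


def _boundary_taper(shape: Sequence[int], width: int) -> np.ndarray:
    """Separable raised-cosine window falling to ~0 at the grid faces."""
    win = np.ones(shape)
    for ax, n in enumerate(shape):
        ramp = np.ones(n)
        w = min(width, n // 2)
        if w > 0:
            x = (np.arange(w) + 0.5) / w
            ramp[:w] = 0.5 * (1.0 - np.cos(np.pi * x))
            ramp[-w:] = ramp[:w][::-1]
        sh = [1, 1, 1]
        sh[ax] = n
        win = win * ramp.reshape(sh)
    return win


def random_smooth_svf(shape: Sequence[int], max_magnitude: float, seed: int,
                      smooth_sigma: float = 4.0, taper_width: int | None = None
                      ) -> VelocityField:
    """Smooth random SVF: Gaussian-filtered white noise, tapered to zero at
    the grid boundary (compact support, so the flow never leaves the domain),
    rescaled so the largest per-voxel magnitude equals ``max_magnitude``."""
    rng = np.random.default_rng(seed)
    vec = rng.standard_normal(tuple(shape) + (3,))
    for c in range(3):
        vec[..., c] = ndimage.gaussian_filter(vec[..., c], smooth_sigma)
    if taper_width is None:
        taper_width = min(8, max(4, min(shape) // 4))
    vec *= _boundary_taper(shape, taper_width)[..., None]
    mag = np.sqrt((vec ** 2).sum(axis=-1)).max()
    if max_magnitude == 0 or mag == 0:
        vec = np.zeros_like(vec)
    else:
        vec *= max_magnitude / mag
    return VelocityField(vec)


def make_warped_pair(age: float, params: PhantomParams | None = None,
                     warp_scale: float = 2.0, seed: int = 0
                     ) -> tuple[Subject, Subject, VelocityField, LabelMap3D, LabelMap3D]:
    """A phantom, the same phantom resampled through exp(u) for a smooth random
    SVF u with max |u| = warp_scale, and u as registration ground truth.

    Returns (subject, warped_subject, u, labels, warped_labels).
    """
    params = params or PhantomParams()
    subj, labels = make_phantom(age, params, seed=seed)
    u = random_smooth_svf(params.grid_shape, warp_scale, seed=seed + 1)
    mapping = exp_svf(u)
    warped = warp(subj.image, mapping, mode="linear")
    warped_labels = warp(labels, mapping, mode="nearest")
    return (subj, Subject(subj.id + "_warped", warped, subj.age), u, labels, warped_labels)


def make_cohort(n: int, age_range: tuple | None = None,
                params: PhantomParams | None = None, seed: int = 0,
                ages: Sequence[float] | None = None,
                age_hist: tuple | None = None,
                jitter_scale: float | None = None, jitter_sigma: float | None = None,
                intensity_jitter_sd: float = 0.03
                ) -> tuple[list[Subject], list[LabelMap3D]]:
    """Cohort of n phantoms with per-subject anatomical jitter.

    Ages are drawn uniformly over ``age_range`` unless ``ages`` fixes them or
    ``age_hist = (bin_centers, probabilities)`` supplies a histogram. Each
    subject additionally receives a random smooth warp and a multiplicative
    intensity perturbation, so cohort members at the same age differ
    anatomically. The jitter models inter-subject variability: its magnitude
    defaults to 30% of the base radius and its correlation length to a fifth
    of the grid (smooth, brain-scale shape differences rather than noise).
    """
    params = params or PhantomParams()
    age_range = age_range or params.age_range
    if jitter_scale is None:
        jitter_scale = 0.3 * params.base_radius
    if jitter_sigma is None:
        jitter_sigma = min(params.grid_shape) / 5.0
    rng = np.random.default_rng(seed)
    if ages is not None:
        ages = np.asarray(ages, dtype=float)
        if ages.shape != (n,):
            raise InvalidInputError(f"expected {n} ages, got {ages.shape}")
    elif age_hist is not None:
        centers, probs = np.asarray(age_hist[0], float), np.asarray(age_hist[1], float)
        probs = probs / probs.sum()
        ages = rng.choice(centers, size=n, p=probs)
    else:
        ages = rng.uniform(age_range[0], age_range[1], size=n)
    subjects, label_maps = [], []
    for i in range(n):
        subj, labels = make_phantom(float(ages[i]), params,
                                    seed=int(rng.integers(0, 2 ** 31 - 1)),
                                    subject_id=f"subj{i:03d}")
        if jitter_scale > 0:
            u = random_smooth_svf(params.grid_shape, jitter_scale,
                                  seed=int(rng.integers(0, 2 ** 31 - 1)),
                                  smooth_sigma=jitter_sigma)
            mapping = exp_svf(u)
            img = warp(subj.image, mapping, mode="linear")
            labels = warp(labels, mapping, mode="nearest")
        else:
            img = subj.image
        scale = 1.0 + rng.normal(0.0, intensity_jitter_sd) if intensity_jitter_sd > 0 else 1.0
        img = Image3D(img.values * scale, img.spacing, img.origin)
        subjects.append(Subject(subj.id, img, subj.age))
        label_maps.append(labels)
    return subjects, label_maps


def simulate_raters(truth: LabelMap3D, confusions: Sequence[np.ndarray], seed: int = 0,
                    label_ids: Sequence[int] | None = None) -> list[LabelMap3D]:
    """Simulate raters with known confusion matrices.

    Each rater's voxel label is drawn independently from the rater's confusion
    row conditioned on the true label: P(observed = m | true = l) = theta[l, m].
    ``label_ids`` gives the label value of each matrix row/column (default: the
    sorted labels present in ``truth``).
    """
    if label_ids is None:
        label_ids = np.unique(truth.labels)
    label_ids = np.asarray(label_ids)
    n_labels = len(label_ids)
    value_to_row = {int(v): r for r, v in enumerate(label_ids)}
    rows = np.vectorize(value_to_row.__getitem__)(truth.labels)
    rng = np.random.default_rng(seed)
    raters = []
    for theta in confusions:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (n_labels, n_labels):
            raise InvalidInputError(f"confusion must be {n_labels}x{n_labels}, got {theta.shape}")
        if np.any(theta < 0) or not np.allclose(theta.sum(axis=1), 1.0, atol=1e-10):
            raise InvalidInputError("confusion rows must be nonnegative and sum to 1")
        cdf = np.cumsum(theta, axis=1)
        u = rng.random(truth.labels.shape)
        drawn_col = (u[..., None] > cdf[rows]).sum(axis=-1)
        raters.append(LabelMap3D(label_ids[drawn_col].astype(np.int32),
                                 truth.spacing.copy(), truth.origin.copy(),
                                 dict(truth.key) if truth.key else None))
    return raters
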